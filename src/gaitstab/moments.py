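"""Frontal-plane moment of the vertical ground reaction force.

Foot placement matters for balance because it sets the center-of-pressure
(CoP) location and thereby the moment that the vertical ground reaction
force exerts about the center of mass (CoM):

    M = F_grf_vert * (CoP_ml - CoM_ml)

with the CoM as pivot and the mediolateral CoP-to-CoM distance as moment
arm. With the CoM midway between the feet, the arm is half the step width;
a foot placed ``fp_error`` too medial shortens the arm by exactly that
much, so the corrective moment another balance mechanism must supply is
``F_grf_vert * fp_error`` — e.g. 1.5 N·m for a 2 mm error under 750 N.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class MomentScenario:
    """One worked moment calculation (forces in N, distances in m)."""

    f_grf_vert: float
    step_width: float
    cop_ml: float = 0.0
    com_ml: float = 0.0
    fp_error: float = 0.0

    def __post_init__(self) -> None:
        if self.f_grf_vert <= 0:
            raise ValueError("vertical ground reaction force must be positive")
        if self.step_width <= 0:
            raise ValueError("step width must be positive")

    @property
    def moment(self) -> float:
        return ground_reaction_moment(self.f_grf_vert, self.cop_ml, self.com_ml)

    @property
    def corrective_moment(self) -> float:
        return corrective_moment_for_error(
            self.f_grf_vert, self.step_width, self.fp_error
        )


def ground_reaction_moment(f_grf_vert: float, cop_ml: float, com_ml: float) -> float:
    """Moment (N·m) of the vertical GRF about the CoM: F * (CoP - CoM)."""
    if f_grf_vert <= 0:
        raise ValueError("vertical ground reaction force must be positive")
    return f_grf_vert * (cop_ml - com_ml)


def moment_arm_midway_com(step_width: float) -> float:
    """Moment arm with the CoM assumed midway between the feet: width / 2."""
    if step_width <= 0:
        raise ValueError("step width must be positive")
    return step_width / 2.0


def corrective_moment_for_error(
    f_grf_vert: float, step_width: float, fp_error: float
) -> float:
    """Moment (N·m) needed to compensate a medial foot-placement error.

    Difference between the nominal moment (arm = step_width / 2, CoM midway
    between the feet) and the moment with the arm shortened by
    ``fp_error``; algebraically ``f_grf_vert * fp_error``.
    """
    if f_grf_vert <= 0:
        raise ValueError("vertical ground reaction force must be positive")
    if step_width <= 0:
        raise ValueError("step width must be positive")
    if fp_error < 0:
        raise ValueError("fp_error must be >= 0")
    arm = moment_arm_midway_com(step_width)
    if fp_error >= arm:
        raise ValueError(
            f"fp_error {fp_error} m must be smaller than half the step "
            f"width ({arm} m)"
        )
    return ground_reaction_moment(f_grf_vert, arm, 0.0) - ground_reaction_moment(
        f_grf_vert, arm - fp_error, 0.0
    )
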