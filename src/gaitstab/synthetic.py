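"""Synthetic treadmill gait with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not the physics of walking. Each step draws a mediolateral CoM
state (position and velocity at terminal swing, expressed relative to the
stance foot and mirrored so both sides share one sign convention) and places
the swing foot according to the linear foot-placement control law

    FP = beta_pos * CoM_pos + beta_vel * CoM_vel + eps,

with i.i.d. Gaussian placement noise ``eps``. The realized step width is
``step_width_mean + FP``. Stride times are Gaussian around
``stride_time_mean``. Because every quantity is drawn explicitly, each
downstream stage (event detection, stride-table construction, model
fitting, divergence estimation) has an exact recovery oracle.

Two layers are provided:

* :func:`simulate_step_table` — the discrete per-step ground truth;
* :func:`render_continuous` — 100 Hz marker trajectories (heels + thorax)
  consistent with that truth, with the true heelstrike times recorded in
  the metadata.

:func:`simulate_reference_series` additionally produces scalar calibration
series (periodic, logistic map, jittered limit cycle) with known divergence
behavior for the LDE estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicHermiteSpline

from .io import MarkerTimeSeries

#: Fraction of a foot's stride spent in swing.
_SWING_FRACTION = 0.40
#: Fraction of the swing during which the mediolateral transition happens
#: (concentrated at the end of swing, so the heel still marks the previous
#: placement at the contralateral midstance).
_ML_TRANSITION_FRACTION = 0.30
#: Heel anteroposterior excursion amplitude relative to the trunk, m.
_AP_AMPLITUDE = 0.30
#: Peak heel lift during swing, m.
_LIFT_HEIGHT = 0.05
#: Lead-in before the first heelstrike / tail after the last one, s.
_PADDING = 1.0


@dataclass
class SyntheticGaitConfig:
    """Ground-truth parameters of one synthetic walking trial.

    Defaults mimic steady treadmill walking: ~1.1 s strides with 0.02 s
    variability, ~0.10 m step width, centimeter-scale lateral CoM sway and
    millimeter-scale foot-placement noise.
    """

    n_strides: int = 100
    stride_time_mean: float = 1.1
    stride_time_sd: float = 0.02
    step_width_mean: float = 0.10
    com_sway_sd: float = 0.01
    com_vel_sd: float = 0.05
    beta_pos: float = 1.5
    beta_vel: float = 0.30
    sigma_eps: float = 0.005
    sample_rate: float = 100.0
    seed: int = 0
    #: "iid" draws the CoM state independently per step; "ar1" makes the
    #: mirrored CoM position an AR(1) sequence with the same stationary sd
    #: (lag coefficient `ar1_coef`), for divergence-sensitivity experiments.
    com_dynamics: str = "iid"
    ar1_coef: float = 0.6

    def __post_init__(self) -> None:
        if self.n_strides < 35:
            raise ValueError("n_strides must be >= 35 for any block analysis")
        for name in ("stride_time_mean", "step_width_mean", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("stride_time_sd", "com_sway_sd", "com_vel_sd", "sigma_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.com_dynamics not in ("iid", "ar1"):
            raise ValueError("com_dynamics must be 'iid' or 'ar1'")


def simulate_step_table(config: SyntheticGaitConfig) -> pd.DataFrame:
    """Draw the discrete per-step ground truth.

    Returns one row per step (``2 * n_strides`` rows, alternating sides,
    starting left) with columns:

    ``step, side, heelstrike_time, com_pos, com_vel, fp, step_width,
    stride_time``

    ``com_pos``/``com_vel``/``fp`` are in the mirrored (side-invariant)
    frame of the control model; ``stride_time`` is the time to the next
    same-side heelstrike (NaN for the final two steps). Heelstrike times are
    built from per-step intervals ~ N(stride_time_mean/2,
    stride_time_sd/sqrt(2)), truncated at a quarter of the mean stride, so
    stride times are marginally N(stride_time_mean, stride_time_sd).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_steps = 2 * cfg.n_strides

    intervals = rng.normal(cfg.stride_time_mean / 2.0,
                           cfg.stride_time_sd / np.sqrt(2.0), n_steps - 1)
    intervals = np.maximum(intervals, 0.25 * cfg.stride_time_mean)
    times = _PADDING + np.concatenate([[0.0], np.cumsum(intervals)])

    if cfg.com_dynamics == "ar1":
        innov_sd = cfg.com_sway_sd * np.sqrt(1.0 - cfg.ar1_coef**2)
        com_pos = np.empty(n_steps)
        com_pos[0] = rng.normal(0.0, cfg.com_sway_sd)
        for k in range(1, n_steps):
            com_pos[k] = cfg.ar1_coef * com_pos[k - 1] + rng.normal(0.0, innov_sd)
    else:
        com_pos = rng.normal(0.0, cfg.com_sway_sd, n_steps)
    com_vel = rng.normal(0.0, cfg.com_vel_sd, n_steps)
    eps = rng.normal(0.0, cfg.sigma_eps, n_steps)

    fp = cfg.beta_pos * com_pos + cfg.beta_vel * com_vel + eps
    step_width = cfg.step_width_mean + fp

    stride_time = np.full(n_steps, np.nan)
    stride_time[:-2] = times[2:] - times[:-2]

    return pd.DataFrame(
        {
            "step": np.arange(n_steps),
            "side": np.where(np.arange(n_steps) % 2 == 0, "L", "R"),
            "heelstrike_time": times,
            "com_pos": com_pos,
            "com_vel": com_vel,
            "fp": fp,
            "step_width": step_width,
            "stride_time": stride_time,
        }
    )


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """C1 ramp from 0 to 1 on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def render_continuous(truth: pd.DataFrame, config: SyntheticGaitConfig) -> MarkerTimeSeries:
    """Render 100 Hz heel and thorax trajectories consistent with `truth`.

    Lab-frame construction (treadmill frame: the trunk stays near AP = 0):

    * Foot lateral placements form an alternating sequence: when side ``s``
      lands, its heel takes the stance heel's position plus the signed step
      width. During stance the heel ML position is constant; the transition
      to the next placement is a smoothstep confined to the last part of the
      swing, so the heel still marks the previous placement at the
      contralateral midstance.
    * Heel AP relative to the trunk follows half-cosine arcs: forward
      extreme exactly at each heelstrike, rearward extreme at lift-off —
      giving the event detector an unambiguous per-cycle maximum.
    * Heel height is zero in stance with a half-sine lift in swing.
    * Thorax ML is a cubic Hermite spline whose knots are the terminal-swing
      instants (= heelstrike times), with value stance_heel + signed
      CoM_pos and derivative = signed CoM_vel, so the drawn CoM state is
      embedded exactly in the rendered signal.

    Ground-truth heelstrike times are stored in
    ``metadata["truth_heelstrikes_L"/"truth_heelstrikes_R"]`` as
    comma-separated seconds.
    """
    cfg = config
    if len(truth) == 0:
        raise ValueError("empty step table")
    times = truth["heelstrike_time"].to_numpy(float)
    sides = truth["side"].to_numpy()
    widths = truth["step_width"].to_numpy(float)
    com_pos = truth["com_pos"].to_numpy(float)
    com_vel = truth["com_vel"].to_numpy(float)
    n_steps = len(truth)

    # Lab-frame lateral placements. side_sign: right = +1, left = -1; the
    # landing foot goes to stance + side_sign * width.
    side_sign = np.where(sides == "R", 1.0, -1.0)
    foot_pos = {"L": cfg.step_width_mean / 2.0, "R": cfg.step_width_mean / 2.0}
    # initial stance foot is the opposite of the first landing side
    first = sides[0]
    other = "R" if first == "L" else "L"
    foot_pos[other] = 0.0
    placements = np.empty(n_steps)
    thorax_knot = np.empty(n_steps)
    landings = {"L": [], "R": []}  # (time, ml_position)
    # The initial stance foot is on the ground from t = 0 at its starting
    # position; model that as a landing at t = 0 so the generic stance/swing
    # rendering covers the lead-in (an AP maximum at sample 0 is never a
    # detectable peak, so no spurious event results).
    landings[other].append((0.0, foot_pos[other]))
    for k in range(n_steps):
        s = sides[k]
        stance = "R" if s == "L" else "L"
        placements[k] = foot_pos[stance] + side_sign[k] * widths[k]
        thorax_knot[k] = foot_pos[stance] + side_sign[k] * com_pos[k]
        foot_pos[s] = placements[k]
        landings[s].append((times[k], placements[k]))

    t_end = times[-1] + _PADDING
    n = int(round(t_end * cfg.sample_rate)) + 1
    t = np.arange(n) / cfg.sample_rate

    markers = {}
    for s in ("L", "R"):
        ml = np.empty(n)
        ap = np.empty(n)
        vert = np.zeros(n)
        ev = landings[s]
        if not ev:
            raise ValueError(f"no landings for side {s}")
        t_land = np.array([e[0] for e in ev])
        p_land = np.array([e[1] for e in ev])

        # before first landing: rise from the rear extreme over half a
        # nominal cycle, heel on the ground; no forward maximum precedes the
        # first true heelstrike
        half0 = 0.5 * cfg.stride_time_mean
        pre = t < t_land[0]
        ml[pre] = p_land[0]
        u = np.clip((t[pre] - (t_land[0] - half0)) / half0, 0.0, 1.0)
        ap[pre] = -_AP_AMPLITUDE * np.cos(np.pi * u)

        for i in range(len(ev)):
            t0 = t_land[i]
            t1 = t_land[i + 1] if i + 1 < len(ev) else None
            if t1 is None:
                seg = t >= t0
                ml[seg] = p_land[i]
                # descent to the rear extreme over half a nominal cycle, hold
                half = 0.5 * cfg.stride_time_mean
                u = np.clip((t[seg] - t0) / half, 0.0, 1.0)
                ap[seg] = _AP_AMPLITUDE * np.cos(np.pi * u)
                vert[seg] = 0.0
                break
            seg = (t >= t0) & (t < t1)
            ts = t[seg]
            cycle = t1 - t0
            t_lo = t1 - _SWING_FRACTION * cycle  # lift-off
            swing = ts >= t_lo
            # AP: one full cosine per cycle — forward extreme exactly at each
            # heelstrike, locally symmetric around it so zero-phase smoothing
            # does not bias the peak time
            ap[seg] = _AP_AMPLITUDE * np.cos(2.0 * np.pi * (ts - t0) / cycle)
            # vertical: half-sine lift during swing
            vseg = np.zeros(ts.size)
            vseg[swing] = _LIFT_HEIGHT * np.sin(np.pi * (ts[swing] - t_lo) / (t1 - t_lo))
            vert[seg] = vseg
            # ML: hold previous placement; smoothstep in the last part of swing
            t_ml0 = t1 - _ML_TRANSITION_FRACTION * (t1 - t_lo)
            mlseg = np.full(ts.size, p_land[i])
            moving = ts >= t_ml0
            mlseg[moving] = p_land[i] + (p_land[i + 1] - p_land[i]) * _smoothstep(
                (ts[moving] - t_ml0) / (t1 - t_ml0)
            )
            ml[seg] = mlseg
        markers[f"heel_{s}"] = np.column_stack([ml, ap, vert])

    # thorax: Hermite spline through (time, knot value, knot slope = signed vel)
    kt = np.concatenate([[0.0], times, [t_end]])
    kv = np.concatenate([[thorax_knot[0]], thorax_knot, [thorax_knot[-1]]])
    kd = np.concatenate([[0.0], side_sign * com_vel, [0.0]])
    thorax_ml = CubicHermiteSpline(kt, kv, kd)(t)
    markers["thorax"] = np.column_stack(
        [thorax_ml, np.zeros(n), np.full(n, 1.0)]
    )

    meta = {
        "truth_heelstrikes_L": ",".join(repr(float(x)) for x in times[sides == "L"]),
        "truth_heelstrikes_R": ",".join(repr(float(x)) for x in times[sides == "R"]),
        "generator": "gaitstab.synthetic",
        "seed": str(cfg.seed),
    }
    return MarkerTimeSeries(sample_rate=cfg.sample_rate, time=t, markers=markers, metadata=meta)


def truth_heelstrikes(ts: MarkerTimeSeries) -> dict[str, np.ndarray]:
    """Recover ground-truth heelstrike times from generator metadata."""
    out = {}
    for s in ("L", "R"):
        key = f"truth_heelstrikes_{s}"
        if key not in ts.metadata:
            raise KeyError(f"no ground-truth events in metadata ({key})")
        out[s] = np.array([float(x) for x in ts.metadata[key].split(",")])
    return out


def simulate_reference_series(kind: str, n_samples: int, params: dict | None = None,
                              seed: int = 0) -> np.ndarray:
    """Scalar calibration series with known divergence behavior.

    kind = "periodic"
        Sum of two harmonics of a base cycle (default period 100 samples):
        zero true divergence.
    kind = "logistic_map"
        Iterates of x <- r x (1 - x) (default r = 4, x0 = 0.3), whose
        largest Lyapunov exponent at r = 4 is ln 2 per iterate. Requires
        n_samples >= 2000.
    kind = "noisy_limit_cycle"
        The periodic waveform with per-cycle phase and amplitude jitter of
        relative sd ``jitter_sd``; jitter 0 reduces exactly to "periodic".
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "periodic":
        period = p.get("period", 100.0)
        k = np.arange(n_samples)
        ph = 2.0 * np.pi * k / period
        return np.sin(ph) + 0.5 * np.sin(2.0 * ph + p.get("phase2", 0.8))
    if kind == "logistic_map":
        if n_samples < 2000:
            raise ValueError("logistic_map needs n_samples >= 2000")
        r = p.get("r", 4.0)
        x = p.get("x0", 0.3)
        out = np.empty(n_samples)
        for i in range(n_samples):
            out[i] = x
            x = r * x * (1.0 - x)
        return out
    if kind == "noisy_limit_cycle":
        period = p.get("period", 100.0)
        jitter = p.get("jitter_sd", 0.05)
        phase2 = p.get("phase2", 0.8)
        out = np.empty(n_samples)
        i = 0
        while i < n_samples:
            amp = 1.0 + jitter * rng.standard_normal()
            per = period * (1.0 + jitter * rng.standard_normal())
            per = max(per, 0.25 * period)
            m = min(int(round(per)), n_samples - i)
            ph = 2.0 * np.pi * np.arange(m) / per
            out[i : i + m] = amp * (np.sin(ph) + 0.5 * np.sin(2.0 * ph + phase2))
            i += m
        return out
    raise ValueError(f"unknown reference-series kind: {kind!r}")
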