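"""The foot-placement control model and its two outcome measures.

Lateral balance in steady gait is maintained largely by where the swing
foot is placed relative to the body's state. The model is a per-block
ordinary least-squares fit of the (demeaned) mediolateral foot placement on
the (demeaned) mediolateral CoM position and velocity at terminal swing:

    FP = beta_pos * CoM_pos + beta_vel * CoM_vel + eps

* the *degree of foot placement control* is the relative explained
  variance R² of this fit — what fraction of step-to-step placement
  variance the preceding CoM state accounts for;
* the *magnitude of foot placement error* is the standard deviation of the
  residual eps (sample convention, n-1 denominator), an absolute precision
  measure in meters.

An intercept is always included even though inputs are demeaned: it is a
no-op when demeaning is exact and keeps the residual-mean-zero /
variance-decomposition invariants when the demeaning grouping differs from
the fit grouping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class SingularFitError(ValueError):
    """Predictors are rank-deficient (e.g. zero variance)."""


@dataclass
class FootPlacementFit:
    """One block's fit of the foot-placement control model.

    beta_pos is dimensionless, beta_vel has units of seconds, fp_error_sd
    is in meters. ``n_strides`` counts the step observations entering the
    fit (each step — left steps mirrored — contributes one FP sample).
    """

    beta_pos: float
    beta_vel: float
    r_squared: float
    fp_error_sd: float
    n_strides: int
    residuals: np.ndarray

    def as_dict(self) -> dict:
        return {
            "beta_pos": self.beta_pos,
            "beta_vel": self.beta_vel,
            "r_squared": self.r_squared,
            "fp_error_sd": self.fp_error_sd,
            "n_strides": self.n_strides,
        }


def fit_foot_placement_model(block) -> FootPlacementFit:
    """OLS fit of demeaned FP on demeaned (CoM_pos, CoM_vel) with intercept.

    ``block`` is a DataFrame with columns ``fp``, ``com_pos``, ``com_vel``
    (one row per step). R² = 1 - SS_res/SS_tot; fp_error_sd = sd of the
    residuals (n-1 denominator).

    Raises
    ------
    ValueError
        Fewer than 10 observations, or non-finite inputs.
    SingularFitError
        A predictor has zero variance (rank-deficient design).
    """
    fp = np.asarray(block["fp"], float)
    com_pos = np.asarray(block["com_pos"], float)
    com_vel = np.asarray(block["com_vel"], float)
    n = fp.size
    if n < 10:
        raise ValueError(f"need >= 10 strides to fit, got {n}")
    if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(com_pos))
            and np.all(np.isfinite(com_vel))):
        raise ValueError("non-finite values in FP or CoM state")

    y = fp - fp.mean()
    x1 = com_pos - com_pos.mean()
    x2 = com_vel - com_vel.mean()
    X = np.column_stack([np.ones(n), x1, x2])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise SingularFitError(
            "rank-deficient predictors (zero-variance CoM position or velocity)"
        )
    resid = y - X @ coef
    ss_tot = float(np.sum(y**2))
    if ss_tot == 0.0:
        raise ValueError("FP has zero variance; R^2 undefined")
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot
    return FootPlacementFit(
        beta_pos=float(coef[1]),
        beta_vel=float(coef[2]),
        r_squared=r_squared,
        fp_error_sd=float(np.std(resid, ddof=1)),
        n_strides=n,
        residuals=resid,
    )


def fit_blocks(stride_table: pd.DataFrame) -> pd.DataFrame:
    """Fit the model per (condition, block) over valid steps.

    Returns a tidy frame with one row per block: condition, block,
    beta_pos, beta_vel, r_squared, fp_error_sd, n_strides.
    """
    rows = []
    valid = stride_table[stride_table["valid"]]
    for (cond, blk), grp in valid.groupby(["condition", "block"], sort=True):
        fit = fit_foot_placement_model(grp)
        rows.append({"condition": cond, "block": int(blk), **fit.as_dict()})
    if not rows:
        raise ValueError("no complete blocks to fit")
    return pd.DataFrame(rows)


_MEASURES = ("beta_pos", "beta_vel", "r_squared", "fp_error_sd")


def summarize_blocks(fits, scheme: str = "mean-over-blocks") -> dict:
    """Condition-level summary of per-block fits.

    scheme = "mean-over-blocks"
        Unweighted mean of each measure over the blocks (the main
        within-condition summary).
    scheme = "first30" / "last30"
        The single fit computed on the first / last 30 strides of the
        condition; the caller passes exactly that fit (used for
        within-session start-vs-end comparisons).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to summarize")
    if scheme == "mean-over-blocks":
        out = {m: float(np.mean([getattr(f, m) for f in fits])) for m in _MEASURES}
        out["n_blocks"] = len(fits)
        return out
    if scheme in ("first30", "last30"):
        if len(fits) != 1:
            raise ValueError(
                f"scheme {scheme!r} expects the single fit of those 30 strides"
            )
        out = {m: getattr(fits[0], m) for m in _MEASURES}
        out["n_blocks"] = 1
        return out
    raise ValueError(f"unknown summary scheme: {scheme!r}")
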