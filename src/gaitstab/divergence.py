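"""Local divergence exponent of a scalar gait signal.

The local divergence exponent (LDE, often written λ_S) quantifies local
dynamic stability of steady-state walking: how fast initially nearby
trajectories in a reconstructed state space separate. The analyzed signal
here is the mediolateral velocity of the trunk (CoM proxy). The procedure:

1. time-normalize the signal so that the *average* stride is exactly
   ``samples_per_stride`` samples long (one global resampling, no
   stride-by-stride warping);
2. delay-embed the normalized signal (default: 6 dimensions, 25-sample
   delay);
3. for every embedded point, find its ``n_neighbors`` nearest neighbors by
   Euclidean distance, excluding temporally close points (Theiler window,
   default half an average stride = 50 samples);
4. track the distance of each reference–neighbor pair for ``horizon``
   samples (default 1000) and average the natural log of those distances
   over all pairs;
5. fit a least-squares line through the first ``fit_range`` samples
   (default 50, i.e. half an average stride) of that averaged log-divergence
   curve. The slope is the LDE, in ln-units per normalized sample.

Lower values mean a more locally stable gait. A convenience conversion to
per-stride units is ``lde * samples_per_stride``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import cdist


@dataclass
class LdeParams:
    """Parameters of the divergence analysis (defaults = standard gait use).

    samples_per_stride : grid length of one average stride after
        time normalization.
    embedding_dim, delay : state-space reconstruction (delay in samples of
        the normalized signal).
    n_neighbors : nearest neighbors tracked per reference point.
    theiler_window : minimum temporal separation |i - j| (samples) between a
        reference point and any of its neighbors; default half an average
        stride.
    horizon : number of samples each pair is tracked for.
    fit_range : number of initial curve samples entering the slope fit.
    min_distance : floor applied to pair distances before the log, so that
        exactly periodic inputs (distance 0) stay finite.
    """

    samples_per_stride: int = 100
    embedding_dim: int = 6
    delay: int = 25
    n_neighbors: int = 5
    theiler_window: int = 50
    horizon: int = 1000
    fit_range: int = 50
    min_distance: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        for name in ("samples_per_stride", "embedding_dim", "delay",
                     "horizon", "fit_range"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.theiler_window < 0:
            raise ValueError("theiler_window must be >= 0")

    @property
    def span(self) -> int:
        """Samples consumed by one embedded point beyond its start index."""
        return self.delay * (self.embedding_dim - 1)


@dataclass
class DivergenceResult:
    """Averaged log-divergence curve and its fitted initial slope.

    ``lde`` is in ln-units per normalized sample; multiply by
    ``samples_per_stride`` for per-stride units.
    """

    mean_log_divergence: np.ndarray
    lde: float
    n_pairs_used: int
    n_refs_skipped: int = 0
    params: LdeParams = field(default_factory=LdeParams)

    @property
    def lde_per_stride(self) -> float:
        return self.lde * self.params.samples_per_stride


def time_normalize(signal, time, ref_heelstrikes, samples_per_stride: int = 100):
    """Resample `signal` so the average stride is `samples_per_stride` long.

    The stretch from the first to the last heelstrike of the reference leg
    (``n_strides`` strides) is resampled in one pass onto a uniform grid of
    ``n_strides * samples_per_stride`` points by cubic interpolation. The
    grid excludes the final heelstrike instant so that each stride occupies
    exactly ``samples_per_stride`` samples on average with no duplicated
    boundary sample.
    """
    signal = np.asarray(signal, float)
    time = np.asarray(time, float)
    hs = np.asarray(ref_heelstrikes, float)
    n_strides = hs.size - 1
    if n_strides < 10:
        raise ValueError(f"need >= 10 strides for time normalization, got {n_strides}")
    if hs[0] < time[0] - 1e-9 or hs[-1] > time[-1] + 1e-9:
        raise ValueError("heelstrikes outside the sampled time range")
    grid = hs[0] + (hs[-1] - hs[0]) * np.arange(n_strides * samples_per_stride) / (
        n_strides * samples_per_stride
    )
    return CubicSpline(time, signal)(grid)


def delay_embed(signal, embedding_dim: int, delay: int) -> np.ndarray:
    """Delay-embed a scalar series into ``embedding_dim`` dimensions.

    Point ``i`` is ``(x[i], x[i+delay], ..., x[i+delay*(dim-1)])``; the
    number of points is ``len(signal) - delay*(dim-1)``.
    """
    x = np.asarray(signal, float)
    span = delay * (embedding_dim - 1)
    n_points = x.size - span
    if n_points < 1:
        raise ValueError(
            f"series of length {x.size} too short for embedding: need at "
            f"least {span + 1} samples (dim {embedding_dim}, delay {delay})"
        )
    return np.column_stack([x[i * delay : i * delay + n_points] for i in range(embedding_dim)])


def _find_neighbors(E: np.ndarray, n_valid: int, params: LdeParams):
    """Nearest admissible neighbors for every valid reference point.

    Both references and neighbors are restricted to indices ``< n_valid``
    (points with a full tracking horizon ahead). Admissibility:
    ``|i - j| >= theiler_window``. Ties in distance are broken towards the
    smaller index (stable sort), so the selection is fully deterministic.

    Returns (ref_idx, nbr_idx) flat pair arrays and the number of reference
    points skipped for lack of admissible neighbors.
    """
    k = params.n_neighbors
    theiler = params.theiler_window
    refs, nbrs = [], []
    skipped = 0
    valid = E[:n_valid]
    chunk = max(1, int(2**22 // max(n_valid, 1)))
    j_idx = np.arange(n_valid)
    for start in range(0, n_valid, chunk):
        stop = min(start + chunk, n_valid)
        d = cdist(valid[start:stop], valid)
        # Theiler exclusion (covers j == i as well for theiler >= 1)
        i_idx = np.arange(start, stop)[:, None]
        d[np.abs(i_idx - j_idx[None, :]) < max(theiler, 1)] = np.inf
        order = np.argsort(d, axis=1, kind="stable")
        for row, i in enumerate(range(start, stop)):
            cand = order[row, :k]
            finite = np.isfinite(d[row, cand])
            if not np.all(finite):
                skipped += 1
                continue
            refs.append(np.full(k, i))
            nbrs.append(cand)
    if not refs:
        raise ValueError("no reference point has enough admissible neighbors")
    ref_idx = np.concatenate(refs)
    nbr_idx = np.concatenate(nbrs)
    assert np.all(np.abs(ref_idx - nbr_idx) >= max(theiler, 1))
    return ref_idx, nbr_idx, skipped


def divergence_exponent(signal, params: LdeParams | None = None) -> DivergenceResult:
    """Divergence analysis of an (already normalized) scalar series.

    Implements steps 2–5 of the module docstring. Reference points are
    restricted to those that can be tracked for the full horizon; a
    reference–neighbor pair is used only if both members have the full
    horizon ahead, so every curve sample averages over the same pair set.
    """
    params = params or LdeParams()
    E = delay_embed(signal, params.embedding_dim, params.delay)
    n_points = E.shape[0]
    n_valid = n_points - params.horizon + 1
    if n_valid < params.n_neighbors + 1:
        raise ValueError(
            f"series too short: {n_points} embedded points leave {n_valid} "
            f"trackable over a {params.horizon}-sample horizon"
        )
    ref_idx, nbr_idx, skipped = _find_neighbors(E, n_valid, params)

    horizon = params.horizon
    n_pairs = ref_idx.size
    curve = np.zeros(horizon)
    chunk = max(1, int(2**20 // horizon))
    k_off = np.arange(horizon)
    for start in range(0, n_pairs, chunk):
        sl = slice(start, min(start + chunk, n_pairs))
        diff = E[ref_idx[sl, None] + k_off] - E[nbr_idx[sl, None] + k_off]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.maximum(dist, params.min_distance, out=dist)
        curve += np.log(dist).sum(axis=0)
    curve /= n_pairs

    return DivergenceResult(
        mean_log_divergence=curve,
        lde=lde_slope(curve, params.fit_range),
        n_pairs_used=n_pairs,
        n_refs_skipped=skipped,
        params=params,
    )


def compute_lde(signal, time, ref_heelstrikes, params: LdeParams | None = None) -> DivergenceResult:
    """Time-normalize a raw scalar signal, then run the divergence analysis."""
    params = params or LdeParams()
    normalized = time_normalize(signal, time, ref_heelstrikes, params.samples_per_stride)
    return divergence_exponent(normalized, params)


def lde_slope(curve, fit_range: int) -> float:
    """Ordinary least-squares slope of `curve` vs sample index on [0, fit_range)."""
    curve = np.asarray(curve, float)
    if fit_range > curve.size:
        raise ValueError(
            f"fit_range {fit_range} exceeds curve length {curve.size}"
        )
    if fit_range < 2:
        raise ValueError("fit_range must be >= 2")
    k = np.arange(fit_range)
    return float(np.polyfit(k, curve[:fit_range], 1)[0])
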