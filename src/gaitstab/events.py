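"""Kinematic gait-event detection and per-stride outcome construction.

Heelstrikes are detected from marker kinematics alone (no force plates):
on a treadmill, the heel reaches its most anterior position relative to the
trunk at initial contact, so each local maximum of
``heel_AP - thorax_AP`` marks one heelstrike of that side.

From the interleaved left/right heelstrike sequence the module derives, for
every step (one foot landing):

* the terminal-swing instant — the heelstrike itself by default (an
  adjustable lead ``terminal_swing_offset_s`` is provided), at which the
  mediolateral CoM position and velocity relative to the stance foot are
  sampled;
* the midstance instant — temporal midpoint between the heelstrike and the
  next contralateral heelstrike, at which foot placement / step width is
  measured.

Left steps are mirrored (mediolateral values negated) so that a wider-
than-usual lateral placement is positive for both sides and one pooled
regression covers left and right steps. Demeaning of FP, CoM position and
CoM velocity is done per analysis block and per side, before mirroring, so
side asymmetries never masquerade as placement variance.

All marker signals are low-pass filtered (zero-phase Butterworth,
default cutoff 10 Hz) before differentiation or event detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from .io import MarkerTimeSeries

#: Stride times outside this window (s) are flagged and excluded from fits.
STRIDE_TIME_GATE = (0.4, 3.0)


class InsufficientGaitError(ValueError):
    """Too few heelstrikes to analyze."""


@dataclass
class EventParams:
    """Detector settings.

    cutoff_hz : low-pass cutoff for marker smoothing (zero-phase, 4th-order
        effective). 10 Hz keeps all gait content at 100 Hz sampling.
    min_spacing_s : minimum spacing between same-side heelstrikes.
    edge_margin_s : events closer than this to either record edge are
        dropped (filter transients).
    terminal_swing_offset_s : how far before the heelstrike the CoM state
        is sampled (0 = at heelstrike).
    """

    cutoff_hz: float = 10.0
    min_spacing_s: float = 0.4
    edge_margin_s: float = 0.5
    terminal_swing_offset_s: float = 0.0


@dataclass
class GaitEvents:
    """Interleaved heelstrike times with per-step sampling instants.

    ``steps`` (filled by :func:`compute_sampling_instants`) has one row per
    step: side, t_heelstrike, t_terminal, t_midstance, stride_time (time to
    the next same-side heelstrike; NaN at the record end).
    """

    heelstrikes_L: np.ndarray
    heelstrikes_R: np.ndarray
    steps: pd.DataFrame | None = None
    n_discarded: int = 0
    params: EventParams = field(default_factory=EventParams)

    @property
    def merged(self) -> pd.DataFrame:
        """All heelstrikes, time-ordered, with side labels."""
        t = np.concatenate([self.heelstrikes_L, self.heelstrikes_R])
        s = np.array(["L"] * len(self.heelstrikes_L) + ["R"] * len(self.heelstrikes_R))
        order = np.argsort(t, kind="stable")
        return pd.DataFrame({"time": t[order], "side": s[order]})


def lowpass(signal: np.ndarray, sample_rate: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass (2nd order forward-backward)."""
    b, a = butter(2, cutoff_hz / (sample_rate / 2.0), btype="low")
    return filtfilt(b, a, signal)


def detect_heelstrikes(ts: MarkerTimeSeries, params: EventParams | None = None) -> GaitEvents:
    """Detect left/right heelstrikes from heel-vs-trunk AP position.

    Per side, heelstrike candidates are local maxima of the smoothed
    ``heel_AP - thorax_AP`` signal with at least ``min_spacing_s`` between
    events. Candidates within ``edge_margin_s`` of either record edge are
    dropped. Alternation is then enforced on the merged sequence by
    discarding the weaker (lower peak value) of any two consecutive
    same-side events; a warning reports how many were discarded.
    """
    params = params or EventParams()
    ts.require()
    if ts.duration < 5.0:
        raise InsufficientGaitError("need at least 5 s of data")

    fs = ts.sample_rate
    thorax_ap = lowpass(ts.axis("thorax", "ap"), fs, params.cutoff_hz)
    events = {}
    heights = {}
    for side in ("L", "R"):
        rel = lowpass(ts.axis(f"heel_{side}", "ap"), fs, params.cutoff_hz) - thorax_ap
        # adaptive prominence gate: real forward extremes span most of the
        # signal range; numerical ripple on flat segments does not
        prom = 0.25 * (np.percentile(rel, 95) - np.percentile(rel, 5))
        idx, _ = find_peaks(
            rel,
            distance=max(1, int(round(params.min_spacing_s * fs))),
            prominence=max(prom, 1e-9),
        )
        # sub-sample refinement: parabola through the peak and its
        # neighbors (events would otherwise be quantized to the sample grid)
        t_ev = ts.time[idx].copy()
        inner = (idx > 0) & (idx < rel.size - 1)
        i = idx[inner]
        denom = rel[i - 1] - 2.0 * rel[i] + rel[i + 1]
        shift = np.zeros(i.size)
        nz = denom < -1e-15
        shift[nz] = 0.5 * (rel[i - 1] - rel[i + 1])[nz] / denom[nz]
        t_ev[inner] += np.clip(shift, -0.5, 0.5) / fs
        keep = (t_ev >= ts.time[0] + params.edge_margin_s) & (
            t_ev <= ts.time[-1] - params.edge_margin_s
        )
        idx = idx[keep]
        if idx.size < 3:
            raise InsufficientGaitError(
                f"insufficient gait: only {idx.size} heelstrikes on side {side}"
            )
        events[side] = ts.time[idx]
        heights[side] = rel[idx]

    # enforce alternation on the merged sequence
    t_all = np.concatenate([events["L"], events["R"]])
    s_all = np.array(["L"] * len(events["L"]) + ["R"] * len(events["R"]))
    h_all = np.concatenate([heights["L"], heights["R"]])
    order = np.argsort(t_all, kind="stable")
    t_all, s_all, h_all = t_all[order], s_all[order], h_all[order]

    discarded = 0
    keep = np.ones(t_all.size, dtype=bool)
    changed = True
    while changed:
        changed = False
        live = np.flatnonzero(keep)
        for a, b in zip(live[:-1], live[1:]):
            if s_all[a] == s_all[b]:
                keep[a if h_all[a] < h_all[b] else b] = False
                discarded += 1
                changed = True
                break
    if discarded:
        warnings.warn(
            f"discarded {discarded} same-side heelstrike candidate(s) to "
            "restore left/right alternation",
            stacklevel=2,
        )
    t_all, s_all = t_all[keep], s_all[keep]
    hs_L = t_all[s_all == "L"]
    hs_R = t_all[s_all == "R"]
    if hs_L.size < 3 or hs_R.size < 3:
        raise InsufficientGaitError("insufficient gait after alternation repair")
    return GaitEvents(
        heelstrikes_L=hs_L, heelstrikes_R=hs_R, n_discarded=discarded, params=params
    )


def compute_sampling_instants(events: GaitEvents) -> GaitEvents:
    """Fill per-step terminal-swing and midstance instants.

    For a step ending with the heelstrike of foot F at ``t_hs``: terminal
    swing := ``t_hs - terminal_swing_offset_s``; midstance of the new
    stance phase := midpoint of ``t_hs`` and the next contralateral
    heelstrike. The final step (no following contralateral event) is
    dropped. Stride time is the interval to the next same-side heelstrike.
    """
    merged = events.merged
    t = merged["time"].to_numpy()
    s = merged["side"].to_numpy()
    n = len(merged)
    rows = []
    for k in range(n - 1):
        # alternating sequence: the next event is the contralateral one
        t_mid = 0.5 * (t[k] + t[k + 1])
        stride = t[k + 2] - t[k] if k + 2 < n else np.nan
        rows.append(
            {
                "side": s[k],
                "t_heelstrike": t[k],
                "t_terminal": t[k] - events.params.terminal_swing_offset_s,
                "t_midstance": t_mid,
                "stride_time": stride,
            }
        )
    events.steps = pd.DataFrame(rows)
    return events


def reference_heelstrikes(events: GaitEvents) -> np.ndarray:
    """Heelstrike times of the reference leg (side of the first event).

    Using the leading side — rather than always the left — makes every
    stride-indexed computation invariant under left/right mirroring of the
    recording.
    """
    merged = events.merged
    ref_side = merged["side"].iloc[0]
    return merged.loc[merged["side"] == ref_side, "time"].to_numpy()


def _assign_strides(steps: pd.DataFrame, condition_plan, block_size: int) -> pd.DataFrame:
    """Label steps with condition, stride index and block index.

    A stride runs from one heelstrike of the reference leg (the side of the
    first detected heelstrike, so the partition is invariant under
    left/right mirroring) to the next. A stride belongs to a condition
    window only if both bounding reference heelstrikes fall inside it
    (half-open [start, end)); windows sharing a condition name are
    concatenated in time order, so strides spanning a bout boundary are
    dropped. Within each condition, strides are numbered consecutively and
    grouped in blocks of ``block_size``; trailing incomplete blocks get
    block index -1 (excluded from fits).
    """
    steps = steps.copy()
    steps["condition"] = ""
    steps["stride_index"] = -1
    steps["block"] = -1

    ref_side = steps["side"].iloc[0]
    left_times = steps.loc[steps["side"] == ref_side, "t_heelstrike"].to_numpy()
    if left_times.size < 2:
        return steps

    if not condition_plan:
        condition_plan = [("all", -np.inf, np.inf)]

    counters: dict[str, int] = {}
    t_hs = steps["t_heelstrike"].to_numpy()
    for name, start, end in condition_plan:
        counters.setdefault(name, 0)
        for i in range(left_times.size - 1):
            t0, t1 = left_times[i], left_times[i + 1]
            if t0 >= start and t1 < end:
                stride_no = counters[name]
                counters[name] += 1
                in_stride = (t_hs >= t0) & (t_hs < t1)
                steps.loc[in_stride, "condition"] = name
                steps.loc[in_stride, "stride_index"] = stride_no
    # block_raw groups every stride (the trailing partial block keeps its
    # own group so demeaning stays local); block = -1 marks strides outside
    # a complete block, which never enter per-block fits.
    steps["block_raw"] = -1
    for name, total in counters.items():
        n_complete = (total // block_size) * block_size
        sel = steps["condition"] == name
        idx = steps.loc[sel, "stride_index"]
        steps.loc[sel, "block_raw"] = idx // block_size
        steps.loc[sel, "block"] = np.where(
            idx < n_complete, idx // block_size, -1
        )
    return steps


def build_stride_table(
    ts: MarkerTimeSeries,
    events: GaitEvents,
    condition_plan=None,
    block_size: int = 30,
    cutoff_hz: float | None = None,
) -> pd.DataFrame:
    """Per-step foot-placement observations with block/condition labels.

    One row per step with columns: side, t_heelstrike, t_terminal,
    t_midstance, stride_time, step_width, fp, com_pos, com_vel, condition,
    stride_index, block, valid.

    * ``step_width`` — |heel_L_ml - heel_R_ml| at midstance.
    * ``fp`` — mediolateral position of the newly placed heel minus the
      stance heel at midstance, mirrored so wider placement is positive,
      demeaned per (condition, block, side).
    * ``com_pos`` / ``com_vel`` — thorax (CoM proxy) mediolateral position
      relative to the stance heel / mediolateral velocity at terminal
      swing, mirrored and demeaned the same way.
    * ``valid`` — stride time inside the gate and the step inside a
      complete block; only valid rows enter model fits.
    """
    if events.steps is None:
        events = compute_sampling_instants(events)
    params = events.params
    cutoff = cutoff_hz if cutoff_hz is not None else params.cutoff_hz
    fs = ts.sample_rate

    heel_ml = {
        s: lowpass(ts.axis(f"heel_{s}", "ml"), fs, cutoff) for s in ("L", "R")
    }
    thorax_ml = lowpass(ts.axis("thorax", "ml"), fs, cutoff)
    thorax_vel = np.gradient(thorax_ml, ts.time)

    steps = events.steps.copy()
    t_mid = steps["t_midstance"].to_numpy()
    t_term = steps["t_terminal"].to_numpy()
    side = steps["side"].to_numpy()
    sign = np.where(side == "R", 1.0, -1.0)

    ml_at_mid = {s: np.interp(t_mid, ts.time, heel_ml[s]) for s in ("L", "R")}
    new_ml = np.where(side == "L", ml_at_mid["L"], ml_at_mid["R"])
    stance_ml_mid = np.where(side == "L", ml_at_mid["R"], ml_at_mid["L"])
    ml_at_term = {s: np.interp(t_term, ts.time, heel_ml[s]) for s in ("L", "R")}
    stance_ml_term = np.where(side == "L", ml_at_term["R"], ml_at_term["L"])

    steps["step_width"] = np.abs(ml_at_mid["L"] - ml_at_mid["R"])
    steps["fp_raw"] = new_ml - stance_ml_mid
    steps["com_pos_raw"] = np.interp(t_term, ts.time, thorax_ml) - stance_ml_term
    steps["com_vel_raw"] = np.interp(t_term, ts.time, thorax_vel)

    steps = _assign_strides(steps, condition_plan, block_size)

    gate_lo, gate_hi = STRIDE_TIME_GATE
    stride_gate = (steps["stride_time"] >= gate_lo) & (steps["stride_time"] <= gate_hi)
    steps["stride_ok"] = stride_gate.fillna(False) & (steps["stride_index"] >= 0)
    steps["valid"] = steps["stride_ok"] & (steps["block"] >= 0)

    # demean per (condition, block, side) over gated rows, then mirror;
    # block_raw keeps the trailing partial block as its own demeaning group
    ok = steps["stride_ok"].to_numpy()
    for raw, out in (
        ("fp_raw", "fp"),
        ("com_pos_raw", "com_pos"),
        ("com_vel_raw", "com_vel"),
    ):
        steps[out] = np.nan
        grouped = steps[ok].groupby(["condition", "block_raw", "side"])[raw]
        demeaned = grouped.transform(lambda x: x - x.mean())
        steps.loc[ok, out] = demeaned * sign[ok]
    return steps.drop(columns=["fp_raw", "com_pos_raw", "com_vel_raw"])
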