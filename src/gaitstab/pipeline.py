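"""Session-level orchestration: markers in, tidy outcome tables out.

A session mirrors the experimental structure of a treadmill training
protocol: a "normal" walking bout, several "training" bouts that are
concatenated at the stride level, and an "after-effect" bout. For each
condition the pipeline

1. detects heelstrikes and builds the per-step stride table,
2. fits the foot-placement control model per 30-stride block and averages
   the outcomes over blocks (plus first-30 / last-30 stride fits for
   within-session comparisons),
3. computes the local divergence exponent of the mediolateral CoM-proxy
   velocity (once per condition by default, per block optionally),
4. reports mean step width, mean stride time, and every exclusion count.

The per-block and per-condition tables are deliberately inference-free:
they are tidy inputs for any external statistics package
(repeated-measures ANOVA etc. are out of scope here).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .divergence import DivergenceResult, divergence_exponent, time_normalize
from .events import (
    GaitEvents,
    build_stride_table,
    compute_sampling_instants,
    detect_heelstrikes,
    lowpass,
    reference_heelstrikes,
)
from .foot_placement import fit_foot_placement_model, summarize_blocks
from .io import MarkerTimeSeries, write_outcomes

#: Measures reported in the long-format comparison table.
DEFAULT_MEASURES = ("r_squared", "fp_error_sd", "step_width", "stride_time", "lde")


@dataclass
class ConditionResult:
    name: str
    n_strides: int
    n_steps_valid: int
    n_excluded: int
    block_fits: pd.DataFrame | None
    summary: dict | None
    first30: dict | None
    last30: dict | None
    lde: DivergenceResult | None
    mean_step_width: float
    mean_stride_time: float

    def measures(self) -> dict:
        out = {
            "step_width": self.mean_step_width,
            "stride_time": self.mean_stride_time,
            "lde": self.lde.lde if self.lde is not None else np.nan,
        }
        if self.summary:
            out.update(
                {k: self.summary[k]
                 for k in ("r_squared", "fp_error_sd", "beta_pos", "beta_vel")}
            )
        else:
            out.update(dict.fromkeys(
                ("r_squared", "fp_error_sd", "beta_pos", "beta_vel"), np.nan))
        return out


@dataclass
class SessionResult:
    conditions: dict[str, ConditionResult]
    stride_table: pd.DataFrame
    events: GaitEvents
    log: list[str] = field(default_factory=list)


def _condition_lde(ts, events, steps, windows, config) -> DivergenceResult | None:
    """Divergence exponent of the ML CoM-proxy velocity for one condition.

    The velocity signal inside each of the condition's windows is
    time-normalized on the window's own reference-leg stride grid; the
    normalized segments are concatenated before the divergence analysis
    (training bouts are short, and this mirrors stride-level
    concatenation). Pairs straddling a concatenation boundary are not
    treated specially.
    """
    params = config.lde_params
    ep = config.event_params
    vel = np.gradient(
        lowpass(ts.axis("thorax", "ml"), ts.sample_rate, ep.cutoff_hz), ts.time
    )
    ref_hs = reference_heelstrikes(events)
    segments = []
    for _, start, end in windows:
        hs = ref_hs[(ref_hs >= start) & (ref_hs < end)]
        if hs.size - 1 < 10:
            continue
        segments.append(
            time_normalize(vel, ts.time, hs, params.samples_per_stride)
        )
    if not segments:
        return None
    series = np.concatenate(segments)
    try:
        return divergence_exponent(series, params)
    except ValueError:
        return None


def analyze_session(ts: MarkerTimeSeries, config: RunConfig) -> SessionResult:
    """Run the full analysis for one recording session.

    Deterministic for a fixed input and configuration: no stochastic step
    is involved anywhere in the analysis chain.
    """
    events = compute_sampling_instants(
        detect_heelstrikes(ts, config.event_params)
    )
    plan = config.condition_plan or [("all", float(ts.time[0]), float(ts.time[-1]) + 1.0)]
    steps = build_stride_table(
        ts, events, condition_plan=plan, block_size=config.block_size
    )

    log: list[str] = [f"discarded_heelstrike_candidates={events.n_discarded}"]
    conditions: dict[str, ConditionResult] = {}
    for name in dict.fromkeys(w[0] for w in plan):  # preserve plan order
        windows = [w for w in plan if w[0] == name]
        cond = steps[steps["condition"] == name]
        valid = cond[cond["valid"]]
        n_strides = int(cond["stride_index"].max()) + 1 if len(cond) else 0
        n_excluded = int(len(cond) - len(valid))
        log.append(f"{name}: strides={n_strides} steps_valid={len(valid)} "
                   f"steps_excluded={n_excluded}")

        block_fits = summary = first30 = last30 = None
        if n_strides >= config.block_size:
            fits = []
            rows = []
            for blk, grp in valid.groupby("block", sort=True):
                fit = fit_foot_placement_model(grp)
                fits.append(fit)
                rows.append({"condition": name, "block": int(blk), **fit.as_dict()})
            block_fits = pd.DataFrame(rows)
            summary = summarize_blocks(fits)
            gated = cond[cond["stride_ok"]]
            first = gated[gated["stride_index"] < config.block_size]
            last = gated[gated["stride_index"] >= n_strides - config.block_size]
            first30 = fit_foot_placement_model(first).as_dict()
            last30 = fit_foot_placement_model(last).as_dict()
        else:
            warnings.warn(
                f"condition '{name}' has {n_strides} strides "
                f"(< block_size {config.block_size}); summaries are null",
                stacklevel=2,
            )
            log.append(f"{name}: too few strides for any block")

        lde = None
        if config.lde_scope == "condition":
            lde = _condition_lde(ts, events, steps, windows, config)
        elif config.lde_scope == "block":
            lde = _per_block_lde(ts, events, valid, windows, config, log, name)
        if config.lde_scope != "off" and lde is None:
            log.append(f"{name}: divergence analysis skipped (too short)")
        if lde is not None:
            log.append(f"{name}: lde_refs_skipped={lde.n_refs_skipped}")

        conditions[name] = ConditionResult(
            name=name,
            n_strides=n_strides,
            n_steps_valid=int(len(valid)),
            n_excluded=n_excluded,
            block_fits=block_fits,
            summary=summary,
            first30=first30,
            last30=last30,
            lde=lde,
            mean_step_width=float(valid["step_width"].mean()) if len(valid) else np.nan,
            mean_stride_time=float(valid["stride_time"].mean()) if len(valid) else np.nan,
        )
    return SessionResult(conditions=conditions, stride_table=steps,
                         events=events, log=log)


def _per_block_lde(ts, events, valid, windows, config, log, name):
    """Average of per-30-stride-block divergence exponents (optional mode)."""
    params = config.lde_params
    ep = config.event_params
    vel = np.gradient(
        lowpass(ts.axis("thorax", "ml"), ts.sample_rate, ep.cutoff_hz), ts.time
    )
    ref_hs = reference_heelstrikes(events)
    results = []
    for blk, grp in valid.groupby("block", sort=True):
        t0 = grp["t_heelstrike"].min()
        t1 = grp["t_heelstrike"].max()
        hs = ref_hs[(ref_hs >= t0 - 1e-9) & (ref_hs <= t1 + 1e-9)]
        if hs.size - 1 < 10:
            continue
        series = time_normalize(vel, ts.time, hs, params.samples_per_stride)
        try:
            results.append(divergence_exponent(series, params))
        except ValueError:
            log.append(f"{name}: block {blk} too short for divergence analysis")
    if not results:
        return None
    mean_curve = np.mean([r.mean_log_divergence for r in results], axis=0)
    return DivergenceResult(
        mean_log_divergence=mean_curve,
        lde=float(np.mean([r.lde for r in results])),
        n_pairs_used=int(np.sum([r.n_pairs_used for r in results])),
        n_refs_skipped=int(np.sum([r.n_refs_skipped for r in results])),
        params=params,
    )


def session_summary_table(result: SessionResult) -> pd.DataFrame:
    """One row per condition with the headline outcome measures."""
    rows = []
    for name, cond in result.conditions.items():
        row = {"condition": name, "n_strides": cond.n_strides,
               "n_steps_valid": cond.n_steps_valid,
               "n_excluded": cond.n_excluded}
        row.update(cond.measures())
        rows.append(row)
    return pd.DataFrame(rows)


def compare_sessions(results, labels, measures=DEFAULT_MEASURES) -> pd.DataFrame:
    """Long-format (week, session, condition, measure, value) table.

    ``labels`` is a (week, session) pair per result; duplicates are an
    error. The output feeds external repeated-measures statistics; no
    inference is computed here.
    """
    results = list(results)
    labels = list(labels)
    if len(results) != len(labels):
        raise ValueError("need one (week, session) label per result")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate (week, session) labels")
    rows = []
    for (week, session), res in zip(labels, results):
        for cond_name, cond in res.conditions.items():
            vals = cond.measures()
            for m in measures:
                rows.append(
                    {"week": week, "session": session, "condition": cond_name,
                     "measure": m, "value": vals.get(m, np.nan)}
                )
    return pd.DataFrame(rows)


def write_session_outputs(result: SessionResult, outdir) -> None:
    """Write strides.csv, blocks.csv, session_summary.csv, lde.json, run.log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_outcomes(result.stride_table, outdir / "strides.csv")
    blocks = [c.block_fits for c in result.conditions.values()
              if c.block_fits is not None]
    if blocks:
        write_outcomes(pd.concat(blocks, ignore_index=True), outdir / "blocks.csv")
    write_outcomes(session_summary_table(result), outdir / "session_summary.csv")
    lde_payload = {
        name: None if cond.lde is None else {
            "lde": cond.lde.lde,
            "lde_per_stride": cond.lde.lde_per_stride,
            "n_pairs_used": cond.lde.n_pairs_used,
            "n_refs_skipped": cond.lde.n_refs_skipped,
            "mean_log_divergence": cond.lde.mean_log_divergence.tolist(),
        }
        for name, cond in result.conditions.items()
    }
    (outdir / "lde.json").write_text(json.dumps(lde_payload, indent=1))
    (outdir / "run.log").write_text("\n".join(result.log) + "\n")
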