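import numpy as np
import pandas as pd
import pytest

import gaitstab as g
from gaitstab.events import InsufficientGaitError, compute_sampling_instants


def match_events(detected, truth, tol=0.05):
    """Greedy one-to-one matching; returns (n_matched, max_abs_error)."""
    used = np.zeros(truth.size, bool)
    errors = []
    for t in detected:
        i = np.argmin(np.abs(truth - t))
        if not used[i] and abs(truth[i] - t) <= tol:
            used[i] = True
            errors.append(abs(truth[i] - t))
    return len(errors), (max(errors) if errors else np.inf)


class TestDetection:
    def test_all_events_recovered_with_tight_timing(self, gait60):
        _, _, ts, events = gait60
        hs = g.truth_heelstrikes(ts)
        for side in ("L", "R"):
            det = getattr(events, f"heelstrikes_{side}")
            n_match, max_err = match_events(det, hs[side])
            assert n_match == det.size == hs[side].size  # no missed, no extra
            assert max_err <= 0.02

    def test_constant_markers_raise_insufficient_gait(self):
        n = 1000
        ts = g.MarkerTimeSeries(
            sample_rate=100.0,
            time=np.arange(n) / 100.0,
            markers={m: np.zeros((n, 3)) for m in ("heel_L", "heel_R", "thorax")},
        )
        with pytest.raises(InsufficientGaitError):
            g.detect_heelstrikes(ts)

    def test_noise_free_gait_has_constant_intervals(self, noise_free_gait):
        _, ts = noise_free_gait
        events = g.detect_heelstrikes(ts)
        for side in ("L", "R"):
            iv = np.diff(getattr(events, f"heelstrikes_{side}"))
            assert np.max(np.abs(iv - np.median(iv))) <= 0.01 + 1e-9

    def test_robust_to_marker_noise(self):
        # 2 mm RMS white noise on every marker axis: F1 >= 0.98
        cfg = g.SyntheticGaitConfig(n_strides=60, seed=21)
        ts = g.render_continuous(g.simulate_step_table(cfg), cfg)
        rng = np.random.default_rng(99)
        noisy = {
            name: arr + rng.normal(0.0, 0.002, arr.shape)
            for name, arr in ts.markers.items()
        }
        ts_noisy = g.MarkerTimeSeries(
            sample_rate=ts.sample_rate, time=ts.time, markers=noisy,
            metadata=ts.metadata,
        )
        events = g.detect_heelstrikes(ts_noisy)
        hs = g.truth_heelstrikes(ts)
        for side in ("L", "R"):
            det = getattr(events, f"heelstrikes_{side}")
            n_match, _ = match_events(det, hs[side])
            precision = n_match / det.size
            recall = n_match / hs[side].size
            f1 = 2 * precision * recall / (precision + recall)
            assert f1 >= 0.98

    def test_alternation_repair_warns_and_restores(self, noise_free_gait):
        _, ts = noise_free_gait
        # inject a spurious forward excursion of the left heel mid-cycle
        markers = {k: v.copy() for k, v in ts.markers.items()}
        t = ts.time
        bump_at = 10.3  # mid-cycle for the left heel (cycle 9.8 -> 10.9)
        markers["heel_L"][:, 1] += 0.35 * np.exp(-((t - bump_at) ** 2) / (2 * 0.05**2))
        ts_bad = g.MarkerTimeSeries(
            sample_rate=ts.sample_rate, time=t, markers=markers,
            metadata=ts.metadata,
        )
        with pytest.warns(UserWarning, match="alternation"):
            events = g.detect_heelstrikes(ts_bad)
        merged = events.merged
        assert (merged["side"].values[:-1] != merged["side"].values[1:]).all()
        assert events.n_discarded >= 1


class TestSamplingInstants:
    def test_midstance_is_midpoint_of_contralateral_pair(self):
        events = g.GaitEvents(
            heelstrikes_L=np.array([0.0, 1.10, 2.20]),
            heelstrikes_R=np.array([0.55, 1.65]),
        )
        steps = compute_sampling_instants(events).steps
        r_step = steps[(steps["side"] == "R") & (steps["t_heelstrike"] == 0.55)]
        assert r_step["t_midstance"].iloc[0] == pytest.approx(0.825)
        # stride time = next same-side interval
        assert r_step["stride_time"].iloc[0] == pytest.approx(1.10)

    def test_last_event_without_contralateral_is_dropped(self):
        events = g.GaitEvents(
            heelstrikes_L=np.array([0.0, 1.10, 2.20]),
            heelstrikes_R=np.array([0.55, 1.65]),
        )
        steps = compute_sampling_instants(events).steps
        assert len(steps) == 4  # 5 events, final one has no contralateral
        assert steps["t_heelstrike"].max() == pytest.approx(1.65)


class TestStrideTable:
    def test_step_width_from_heel_geometry(self, gait60):
        _, truth, ts, events = gait60
        table = g.build_stride_table(ts, events)
        m = table.dropna(subset=["fp"])
        idx = np.searchsorted(
            truth["heelstrike_time"].values, m["t_heelstrike"].values - 0.025
        )
        assert (np.abs(truth["heelstrike_time"].values[idx]
                       - m["t_heelstrike"].values) < 0.03).all()
        tm = truth.iloc[idx]
        np.testing.assert_allclose(
            m["step_width"], tm["step_width"], atol=1e-3
        )

    def test_fp_and_com_state_match_truth(self, gait60):
        """Measured FP/CoM values equal the generator's (block-demeaned)."""
        _, truth, ts, events = gait60
        table = g.build_stride_table(ts, events)
        m = table.dropna(subset=["fp"]).reset_index(drop=True)
        idx = np.searchsorted(
            truth["heelstrike_time"].values, m["t_heelstrike"].values - 0.025
        )
        tm = truth.iloc[idx].reset_index(drop=True)
        for col, atol in (("fp", 1e-3), ("com_pos", 2e-3), ("com_vel", 0.025)):
            # the table demeans per (block, side); demean truth identically
            t_dm = tm[col].groupby(
                [m["block_raw"], m["side"]]
            ).transform(lambda x: x - x.mean())
            assert np.corrcoef(t_dm, m[col])[0, 1] > 0.99
            if col == "fp":
                np.testing.assert_allclose(m[col], t_dm, atol=atol)

    def test_blocking_arithmetic(self):
        cfg = g.SyntheticGaitConfig(n_strides=66, seed=13)
        ts = g.render_continuous(g.simulate_step_table(cfg), cfg)
        events = g.compute_sampling_instants(g.detect_heelstrikes(ts))
        table = g.build_stride_table(ts, events, block_size=30)
        strides = table[table["stride_index"] >= 0]
        n_strides = strides["stride_index"].max() + 1
        assert n_strides == 65  # 66 reference heelstrikes -> 65 strides
        assert set(strides.loc[strides["block"] >= 0, "block"]) == {0, 1}
        unassigned = strides.loc[strides["block"] < 0, "stride_index"].unique()
        assert len(unassigned) == 5

    def test_block_demeaning_centers_fp(self, gait60):
        _, _, ts, events = gait60
        table = g.build_stride_table(ts, events)
        valid = table[table["valid"]]
        for _, grp in valid.groupby("block"):
            assert abs(grp["fp"].mean()) < 1e-12

    def test_mirrored_recording_gives_identical_numbers(self, gait60):
        _, _, ts, events = gait60
        mirrored = g.MarkerTimeSeries(
            sample_rate=ts.sample_rate,
            time=ts.time,
            markers={
                "heel_L": ts.markers["heel_R"] * np.array([-1.0, 1.0, 1.0]),
                "heel_R": ts.markers["heel_L"] * np.array([-1.0, 1.0, 1.0]),
                "thorax": ts.markers["thorax"] * np.array([-1.0, 1.0, 1.0]),
            },
        )
        table = g.build_stride_table(ts, events)
        ev_m = g.compute_sampling_instants(g.detect_heelstrikes(mirrored))
        table_m = g.build_stride_table(mirrored, ev_m)
        assert (table["side"].values != table_m["side"].values).all()
        for col in ("t_heelstrike", "step_width", "fp", "com_pos", "com_vel",
                    "stride_time", "stride_index", "block"):
            np.testing.assert_allclose(
                table[col].astype(float), table_m[col].astype(float),
                atol=1e-10, err_msg=col,
            )

    def test_stride_time_gate_flags_rows(self, gait60):
        _, _, ts, events = gait60
        table = g.build_stride_table(ts, events)
        # rows lacking a next same-side heelstrike are never valid
        assert not table.loc[table["stride_time"].isna(), "valid"].any()
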