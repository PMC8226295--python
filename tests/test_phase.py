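import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chronocell import (
    PhaseTable,
    aggregate_by_cluster,
    build_phase_bins,
    call_phase,
    phase_shift,
)
from chronocell.circular import (
    circular_corr,
    circular_diff_hours,
    circular_mae_hours,
    circular_mean_hours,
)
from chronocell.phase import BIN_CENTERS_H


GRID = [round(0.5 * i, 1) for i in range(50)]  # 0.0 .. 24.5


class TestPhaseBins:
    @pytest.mark.parametrize(
        "phase,expected_bin",
        [(2.5, 2), (1.5, 2), (2.0, 2), (0.0, 0), (0.5, 0), (24.5, 24), (23.5, 24), (4.5, 4)],
    )
    def test_window_membership(self, phase, expected_bin):
        bins = build_phase_bins(PhaseTable({"g": phase}))
        assert bins.bins[expected_bin].members == ["g"]
        for c, gs in bins.bins.items():
            if c != expected_bin:
                assert gs.members == []

    @pytest.mark.parametrize("phase", [1.0, 3.0, 23.0])
    def test_odd_hour_phases_belong_to_no_bin(self, phase):
        bins = build_phase_bins(PhaseTable({"g": phase}))
        assert all(len(gs) == 0 for gs in bins.bins.values())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(GRID), min_size=1, max_size=60))
    def test_partition_property_on_random_tables(self, phases):
        pt = PhaseTable({f"g{i}": p for i, p in enumerate(phases)})
        bins = build_phase_bins(pt)
        assert list(bins.bins) == list(BIN_CENTERS_H)
        seen = []
        for c, gs in bins.bins.items():
            window = {0.0, 0.5} if c == 0 else {c - 0.5, float(c), c + 0.5}
            assert all(pt[g] in window for g in gs.members)
            seen.extend(gs.members)
        assert len(seen) == len(set(seen))  # pairwise disjoint
        unbinned = set(pt.genes) - set(seen)
        assert all(pt[g] in {1.0 + 2 * k for k in range(12)} for g in unbinned)


class TestAggregateByCluster:
    def test_single_cluster_equals_column_means(self):
        psm = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 13)),
                           columns=list(BIN_CENTERS_H))
        agg = aggregate_by_cluster(psm, np.zeros(6, dtype=int))
        assert np.allclose(agg.loc[0], psm.mean(axis=0))

    def test_two_cluster_hand_computed(self):
        psm = pd.DataFrame([[1.0] * 13, [3.0] * 13, [5.0] * 13], columns=list(BIN_CENTERS_H))
        agg = aggregate_by_cluster(psm, np.array([0, 0, 1]))
        assert np.allclose(agg.loc[0], 2.0)
        assert np.allclose(agg.loc[1], 5.0)


class TestCallPhase:
    def _psm(self, rows):
        return pd.DataFrame(rows, columns=list(BIN_CENTERS_H))

    def test_one_hot_bin_14_circular_mean(self):
        row = np.zeros(13)
        row[BIN_CENTERS_H.index(14)] = 1.0
        out = call_phase(self._psm([row]), method="circular_mean")
        assert out["phase_hat"].iloc[0] == pytest.approx(14.0)
        assert out["confidence"].iloc[0] == pytest.approx(1.0)

    def test_antipodal_scores_flagged_for_circular_mean_argmax_earliest(self):
        row = np.zeros(13)
        row[BIN_CENTERS_H.index(6)] = 1.0
        row[BIN_CENTERS_H.index(18)] = 1.0
        cm = call_phase(self._psm([row]), method="circular_mean")
        assert bool(cm["flagged"].iloc[0]) and np.isnan(cm["phase_hat"].iloc[0])
        am = call_phase(self._psm([row]), method="argmax")
        assert am["phase_hat"].iloc[0] == 6.0

    def test_all_nonpositive_undefined_for_circular_mean(self):
        out = call_phase(self._psm([-np.ones(13)]), method="circular_mean")
        assert bool(out["flagged"].iloc[0])
        am = call_phase(self._psm([-np.ones(13)]), method="argmax")
        assert am["phase_hat"].iloc[0] == 0.0  # earliest of the tied maxima

    def test_argmax_tie_takes_earliest(self):
        row = np.zeros(13)
        row[BIN_CENTERS_H.index(8)] = 2.0
        row[BIN_CENTERS_H.index(16)] = 2.0
        out = call_phase(self._psm([row]), method="argmax")
        assert out["phase_hat"].iloc[0] == 8.0

    def test_timetable_on_noiseless_cosine_rows(self):
        """Cosine profiles at known phases are recovered exactly."""
        true = np.arange(0, 24, 2.0)
        rows = [np.cos(2 * np.pi * (np.array(BIN_CENTERS_H) - t) / 24) for t in true]
        out = call_phase(self._psm(rows), method="timetable")
        assert circular_mae_hours(out["phase_hat"].to_numpy(float), true) < 1e-6

    def test_timetable_equivariant_under_rotation(self):
        """Rotating every true phase by 4 h rotates the calls by 4 h."""
        rng = np.random.default_rng(1)
        true = rng.uniform(0, 24, 40)
        def rows_at(phases):
            return [np.cos(2 * np.pi * (np.array(BIN_CENTERS_H) - t) / 24) for t in phases]
        a = call_phase(self._psm(rows_at(true)), method="timetable")["phase_hat"]
        b = call_phase(self._psm(rows_at((true + 4) % 24)), method="timetable")["phase_hat"]
        d = circular_diff_hours(b.to_numpy(float), a.to_numpy(float))
        assert np.allclose(d, 4.0, atol=1e-6)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            call_phase(self._psm([np.zeros(13)]), method="nope")


class TestPhaseShift:
    def test_identical_groups_delta_zero_p_near_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 24, 80)
        res = phase_shift(a, a.copy(), n_perm=200, seed=0)
        assert res["delta_hours"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] > 0.9

    def test_exact_two_hour_rotation_detected(self):
        rng = np.random.default_rng(1)
        a = (rng.vonmises(0, 2, 100) * 24 / (2 * np.pi)) % 24
        b = (a + 2.0) % 24
        res = phase_shift(a, b, n_perm=1000, seed=0)
        assert res["delta_hours"] == pytest.approx(2.0, abs=1e-9)
        assert res["p_value"] < 0.01

    def test_wrap_into_signed_half_interval(self):
        rng = np.random.default_rng(2)
        a = (rng.vonmises(0, 4, 60) * 24 / (2 * np.pi)) % 24
        b = (a - 3.0) % 24  # a 21-h advance reads as a 3-h delay
        res = phase_shift(a, b, n_perm=100, seed=0)
        assert res["delta_hours"] == pytest.approx(-3.0, abs=1e-9)

    def test_too_many_undefined_calls_rejected(self):
        a = np.full(100, np.nan)
        a[:40] = 5.0
        with pytest.raises(ValueError, match="undefined"):
            phase_shift(a, np.full(100, 6.0), n_perm=10, seed=0)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 30"):
            phase_shift(np.full(10, 1.0), np.full(40, 2.0), n_perm=10, seed=0)


class TestPhaseRecoveryOnSimulation:
    def test_per_cell_calls_track_truth(self, sim_bundle):
        norm = sim_bundle["norm"]
        psm = sim_bundle["psm"]
        truth = sim_bundle["truth"].cells.loc[norm.barcodes]
        calls = call_phase(psm, method="timetable")
        ok = calls["phase_hat"].notna().to_numpy()
        mae = circular_mae_hours(
            calls["phase_hat"].to_numpy(float)[ok], truth["true_phase"].to_numpy()[ok]
        )
        assert mae < 2.0

    def test_calls_correlate_circularly_with_truth(self, sim_bundle):
        norm = sim_bundle["norm"]
        calls = call_phase(sim_bundle["psm"], method="timetable")
        truth = sim_bundle["truth"].cells.loc[norm.barcodes, "true_phase"]
        ok = calls["phase_hat"].notna().to_numpy()
        r = circular_corr(calls["phase_hat"].to_numpy(float)[ok], truth.to_numpy()[ok])
        assert r > 0.8

    def test_circular_corr_agrees_with_pingouin(self, sim_bundle):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 24, 200)
        b = (a + rng.normal(0, 1, 200)) % 24
        ours = circular_corr(a, b)
        theirs, _ = pg.circ_corrcc(a * 2 * np.pi / 24, b * 2 * np.pi / 24)
        assert ours == pytest.approx(theirs, abs=1e-6)
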