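"""Change statistics: normalized changes, MEC, gradient mapping, paired
significance and firing-rate classification."""

import numpy as np
import pandas as pd
import pytest

from nirspike import changes as ch


def make_table(duration, amplitude=80.0, depol=5.0, repol=-3.0, n=10,
               label="control"):
    return pd.DataFrame({
        "peak_time_ms": np.arange(n) * 500.0 + 200.0,
        "duration_ms": np.full(n, float(duration)),
        "amplitude_mV": np.full(n, float(amplitude)),
        "depol_slope": np.full(n, float(depol)),
        "repol_slope": np.full(n, float(repol)),
        "trial_label": label,
    })


def make_triplet(d_control=20.0, d_laser=15.0, d_recovery=20.0):
    return ch.TrialTriplet(
        control=make_table(d_control),
        laser=make_table(d_laser, label="laser"),
        recovery=make_table(d_recovery, label="recovery"),
        duration_s={"control": 60.0, "laser": 60.0, "recovery": 60.0},
    )


class TestExperimentalChange:
    def test_equal_means_give_zero(self):
        assert ch.experimental_change([20.0, 20.0], [20.0]) == 0.0

    def test_quarter_change(self):
        assert ch.experimental_change([20.0], [15.0]) == pytest.approx(0.25)

    def test_sign_insensitive(self):
        assert ch.experimental_change([20.0], [25.0]) == pytest.approx(0.25)

    def test_zero_control_mean_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            ch.experimental_change([0.0], [1.0])


class TestModelChange:
    def test_constant_sweep_gives_zero(self):
        assert ch.model_change([7.0, 7.0, 7.0]) == 0.0

    def test_min_max_normalization(self):
        assert ch.model_change([8.0, 10.0]) == pytest.approx(0.2)

    def test_order_invariance(self):
        vals = [3.0, 9.0, 5.0, 7.0]
        assert ch.model_change(vals) == ch.model_change(sorted(vals))


class TestMEC:
    def test_single_experiment_matches_experimental_change(self):
        c = ch.experimental_change([20.0], [15.0])
        ref = ch.mec([c])
        assert ref.mu["metric"] == pytest.approx(c)
        assert ref.sigma["metric"] == 0.0

    def test_two_experiment_mean(self):
        ref = ch.mec([0.1, 0.3])
        assert ref.mu["metric"] == pytest.approx(0.2)

    def test_identical_experiments_have_zero_sd(self):
        ref = ch.mec([0.25] * 8)
        assert ref.sigma["metric"] == 0.0
        assert ref.n_experiments == 8


class TestGradientMapping:
    def test_endpoints_map_to_zero_and_one(self):
        gs_lo = ch.gradient_value(12.0, 32.0, 10.0)   # Vmin = 12
        gs_hi = ch.gradient_value(52.0, 32.0, 10.0)   # Vmax = 52
        assert gs_lo.score == pytest.approx(0.0)
        assert gs_hi.score == pytest.approx(1.0)

    def test_capacitance_duration_example_out_of_range(self):
        """3.2% against the (32±20)% reference lies below Vmin = 12."""
        gs = ch.gradient_value(3.2, 32.0, 10.0)
        assert not gs.in_range
        assert gs.vmin == pytest.approx(12.0)

    def test_depolarization_example_in_range(self):
        """28.3% against (23±12)%: in range, score (28.3−11)/24 ≈ 0.72."""
        gs = ch.gradient_value(28.3, 23.0, 6.0)
        assert gs.in_range
        assert gs.score == pytest.approx((28.3 - 11.0) / 24.0)

    def test_vmin_floored_at_zero(self):
        gs = ch.gradient_value(0.0, 10.0, 20.0)   # μ − 2σ < 0
        assert gs.vmin == 0.0
        assert gs.score == 0.0

    def test_affine_and_order_preserving(self):
        vals = [13.0, 20.0, 30.0, 51.0]
        scores = [ch.gradient_value(v, 32.0, 10.0).score for v in vals]
        assert scores == sorted(scores)
        # affine: equal spacing maps to equal spacing
        diffs = np.diff([ch.gradient_value(v, 32.0, 10.0).score
                         for v in [12.0, 22.0, 32.0, 42.0]])
        assert np.allclose(diffs, diffs[0])


class TestPairedSignificance:
    def test_identical_trials_are_not_significant(self):
        trips = [make_triplet(20.0, 20.0, 20.0) for _ in range(5)]
        out = ch.paired_significance(trips)
        assert (out["p_value"] == 1.0).all()
        assert not out["high_significance"].any()

    def test_consistent_shift_is_flagged(self):
        rng = np.random.default_rng(0)
        trips = [make_triplet(20.0 + rng.normal(0, 0.01),
                              15.0 + rng.normal(0, 0.01),
                              20.0 + rng.normal(0, 0.01))
                 for _ in range(10)]
        out = ch.paired_significance(trips)
        row = out[(out.metric == "duration_ms")
                  & (out.comparison == "control_vs_laser")].iloc[0]
        assert row.high_significance
        rec = out[(out.metric == "duration_ms")
                  & (out.comparison == "control_vs_recovery")].iloc[0]
        assert not rec.high_significance

    def test_fewer_than_two_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            ch.paired_significance([make_triplet()])

    def test_null_flag_rate_near_bonferroni_level(self):
        """Paired samples from one distribution are flagged at ≈ 0.01/4."""
        rng = np.random.default_rng(1234)
        n_rep, n_exp = 3000, 12
        flags = 0
        total = 0
        for _ in range(n_rep):
            means = {
                trial: {m: rng.normal(20.0, 2.0, n_exp)
                        for m in ch.METRIC_COLUMNS}
                for trial in ("control", "laser")
            }
            out = ch.paired_significance_from_means(means)
            flags += int(out["high_significance"].sum())
            total += len(out)
        rate = flags / total
        se = np.sqrt(0.0025 * (1 - 0.0025) / total)
        assert abs(rate - 0.0025) < 4 * se


class TestFiringRate:
    def _times(self, n, duration_s=60.0):
        return np.linspace(100.0, duration_s * 1000.0 - 100.0, n)

    def test_identical_trains_no_change_and_included(self):
        t = self._times(60)
        out = ch.firing_rate_analysis(
            {"control": t, "laser": t, "recovery": t},
            {"control": 60.0, "laser": 60.0, "recovery": 60.0})
        assert out.classification == "no-change"
        assert out.included

    def test_excitation_classification(self):
        out = ch.firing_rate_analysis(
            {"control": self._times(60), "laser": self._times(90),
             "recovery": self._times(61)},
            {"control": 60.0, "laser": 60.0, "recovery": 60.0})
        assert out.classification == "excitation"
        assert out.included

    def test_inhibition_classification(self):
        out = ch.firing_rate_analysis(
            {"control": self._times(60), "laser": self._times(40),
             "recovery": self._times(60)},
            {"control": 60.0, "laser": 60.0, "recovery": 60.0})
        assert out.classification == "inhibition"

    def test_recovery_gate_excludes_drifting_experiment(self):
        out = ch.firing_rate_analysis(
            {"control": self._times(60), "laser": self._times(65),
             "recovery": self._times(40)},
            {"control": 60.0, "laser": 60.0, "recovery": 60.0})
        assert not out.included

    def test_classification_is_a_partition(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_l = int(rng.integers(30, 90))
            out = ch.firing_rate_analysis(
                {"control": self._times(60), "laser": self._times(n_l),
                 "recovery": self._times(60)},
                {"control": 60.0, "laser": 60.0, "recovery": 60.0})
            assert out.classification in ("no-change", "excitation", "inhibition")

    def test_isi_histograms_share_edges(self):
        out = ch.firing_rate_analysis(
            {"control": self._times(60), "laser": self._times(80),
             "recovery": self._times(60)},
            {"control": 60.0, "laser": 60.0, "recovery": 60.0})
        for trial in ("control", "laser", "recovery"):
            assert out.isi_histograms[trial].size == out.isi_bin_edges.size - 1


class TestNormalization:
    def test_control_normalizes_to_unity(self):
        trip = make_triplet(20.0, 15.0, 20.0)
        normed = ch.normalize_to_first_control(trip)
        assert np.allclose(normed.control["duration_ms"], 1.0)
        assert np.allclose(normed.laser["duration_ms"], 0.75)
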