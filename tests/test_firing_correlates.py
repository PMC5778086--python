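import numpy as np
import pytest
from scipy import stats

from ruleflux import behavior
from ruleflux.firing_correlates import (FiringRateMatrix,
                                        compute_segment_rates,
                                        performance_correlations,
                                        rate_group_enrichment,
                                        shuffled_performance_null,
                                        spearman_columns)

from conftest import make_toy_session


def _curve_from(p):
    p = np.asarray(p, float)
    return behavior.PerformanceCurve(p_mode=p, ci_lower=p, ci_upper=p,
                                     sigma_eps_sq=0.01)


def _frm(values, segment="entire_trial"):
    values = np.atleast_2d(np.asarray(values, float))
    m, n = values.shape
    return FiringRateMatrix(segment=segment, values=values,
                            segment_durations=np.ones(m),
                            neuron_ids=[f"n{j}" for j in range(n)],
                            trial_indices=np.arange(m))


class TestSegmentRates:
    def test_ten_spikes_in_reward_window_is_five_hz(self):
        session = make_toy_session(np.linspace(3.05, 4.95, 10))
        frm = compute_segment_rates(session, "reward")
        assert frm.values[0, 0] == pytest.approx(5.0)
        assert np.all(frm.segment_durations == 2.0)

    def test_no_spikes_gives_all_zero_matrix(self):
        session = make_toy_session([])
        for seg in ("run", "reward", "inter_trial", "entire_trial"):
            assert not compute_segment_rates(session, seg).values.any()

    def test_toy_session_rates_match_hand_counts(self, toy_session):
        # trial 0: spikes 0.5, 2.9 in run [0,3); 3.1 plus nine more in
        # reward [3,5); trial 1: one spike at 16.0 in inter-trial [15, 20)
        run = compute_segment_rates(toy_session, "run")
        assert run.values[0, 0] == pytest.approx(2 / 3)
        assert run.values[1, 0] == 0
        reward = compute_segment_rates(toy_session, "reward")
        assert reward.values[0, 0] == pytest.approx(10 / 2)
        inter = compute_segment_rates(toy_session, "inter_trial")
        assert inter.values[1, 0] == pytest.approx(1 / 5)
        entire = compute_segment_rates(toy_session, "entire_trial")
        assert entire.values[0, 0] == pytest.approx(12 / 10)

    def test_zero_duration_segment_names_trial(self, toy_session):
        toy_session.trials[3].t_reward_cross = toy_session.trials[3].t_run_start
        with pytest.raises(ValueError, match="trial 3"):
            compute_segment_rates(toy_session, "run")


class TestPerformanceCorrelations:
    def test_rate_equal_to_performance_gives_rho_one(self):
        p = np.linspace(0.5, 0.9, 30)
        ct = performance_correlations(_frm(p[:, None]), _curve_from(p))
        assert ct.table["rho"].iloc[0] == pytest.approx(1.0)
        assert ct.table["holm_significant"].iloc[0]
        assert ct.table["sign"].iloc[0] == "pos"

    def test_matches_scipy_spearman_per_neuron(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        p = rng.random(40)
        rho, praw = spearman_columns(X, p)
        for j in range(5):
            ref = stats.spearmanr(X[:, j], p)
            assert rho[j] == pytest.approx(ref.statistic, abs=1e-12)
            assert praw[j] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_holm_flags_obey_stepdown_thresholds(self):
        """Every Holm-significant neuron's raw p must clear its step-down
        threshold alpha/(m - rank), computed here as an oracle."""
        rng = np.random.default_rng(1)
        p_perf = np.linspace(0.5, 0.9, 60)
        X = rng.normal(size=(60, 20))
        X[:, :4] += 3.0 * p_perf[:, None]  # four coupled neurons
        ct = performance_correlations(_frm(X), _curve_from(p_perf), alpha=0.05)
        tab = ct.table.sort_values("p_raw").reset_index(drop=True)
        m = len(tab)
        rejecting = True
        for k, row in tab.iterrows():
            thr = 0.05 / (m - k)
            rejecting = rejecting and row["p_raw"] <= thr
            assert bool(row["holm_significant"]) == rejecting

    def test_constant_neuron_flagged_and_excluded(self):
        p = np.linspace(0.5, 0.9, 20)
        X = np.column_stack([np.full(20, 3.0), p])
        ct = performance_correlations(_frm(X), _curve_from(p))
        assert np.isnan(ct.table["rho"].iloc[0])
        assert ct.table["sign"].iloc[0] == "none"
        assert ct.table["holm_significant"].iloc[1]

    def test_invariant_under_monotone_rate_transform(self):
        rng = np.random.default_rng(2)
        X = rng.gamma(2.0, size=(50, 6))
        p = rng.random(50)
        a = performance_correlations(_frm(X), _curve_from(p)).table
        b = performance_correlations(_frm(np.exp(X)), _curve_from(p)).table
        np.testing.assert_allclose(a["rho"], b["rho"], atol=1e-12)


class TestShuffleNull:
    def test_identity_permutations_collapse_band_onto_observed(self):
        class IdentityRng:
            def permutation(self, n):
                return np.arange(n)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        null = shuffled_performance_null(_frm(X), y, n_shuffles=100,
                                         seed=IdentityRng())
        np.testing.assert_allclose(null.band_lo, null.observed_rho, atol=1e-12)
        np.testing.assert_allclose(null.band_hi, null.observed_rho, atol=1e-12)

    def test_integrator_detected_instantaneous_not(self):
        """A neuron tracking the smoothed performance falls outside the
        shuffle band; a neuron echoing the same-trial outcome stays inside."""
        rng = np.random.default_rng(4)
        m = 120
        from ruleflux.synthetic_data import learning_curve
        p = np.tile(learning_curve(np.arange(30), 0.35, 0.9), 4)
        y = (rng.random(m) < p).astype(int)
        curve = behavior.estimate_performance(y)
        integrator = curve.p_mode * 4 + 0.3 * rng.normal(size=m)
        instantaneous = y * 2.0 + 0.3 * rng.normal(size=m)
        frm = _frm(np.column_stack([integrator, instantaneous]))
        null = shuffled_performance_null(frm, y, n_shuffles=150, seed=5,
                                         curve=curve)
        outside = null.outside_band()
        assert outside[0] and not outside[1]


class TestEnrichment:
    @staticmethod
    def _table(high_sig, high_not, low_sig, low_not, signs=None):
        import pandas as pd
        n = high_sig + high_not + low_sig + low_not
        sig = [True] * high_sig + [False] * high_not + \
              [True] * low_sig + [False] * low_not
        rates = [20.0] * (high_sig + high_not) + [2.0] * (low_sig + low_not)
        if signs is None:
            signs = ["pos" if s else "none" for s in sig]
        from ruleflux.firing_correlates import CorrelationTable
        tab = pd.DataFrame({"neuron": [f"n{i}" for i in range(n)],
                            "rho": np.where(sig, 0.5, 0.01),
                            "p_raw": np.where(sig, 1e-4, 0.5),
                            "holm_significant": sig, "sign": signs})
        return CorrelationTable("entire_trial", 0.05, tab), rates

    def test_hand_computed_chi_square(self):
        # counts [[30,20],[10,40]] -> expected [[20,30],[20,30]] -> 16.667
        ct, rates = self._table(30, 20, 10, 40)
        res = rate_group_enrichment(ct, rates)
        assert res.chi2 == pytest.approx(16.667, abs=1e-3)
        np.testing.assert_array_equal(res.counts, [[30, 20], [10, 40]])

    def test_identical_proportions_give_zero_statistic(self):
        ct, rates = self._table(10, 10, 20, 20)
        res = rate_group_enrichment(ct, rates)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.ratio_high == pytest.approx(1.0)
        assert res.ratio_low == pytest.approx(1.0)

    def test_all_significant_gives_unit_ratios(self):
        ct, rates = self._table(15, 0, 25, 0)
        res = rate_group_enrichment(ct, rates)
        assert res.ratio_high == pytest.approx(1.0)
        assert res.ratio_low == pytest.approx(1.0)

    def test_too_small_group_rejected(self):
        ct, rates = self._table(1, 0, 20, 20)
        with pytest.raises(ValueError, match="at least 2"):
            rate_group_enrichment(ct, rates)
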