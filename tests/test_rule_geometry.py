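import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ruleflux.rule_geometry import (DistanceTable, distance_regression,
                                    partial_spearman, repeated_rule_test,
                                    rule_distance_table)
from ruleflux.population_states import build_population_vectors
from ruleflux.firing_correlates import FiringRateMatrix
from ruleflux.session_io import RuleBlock
from ruleflux import behavior

from _oracles import partial_spearman_residual_oracle


def _pm_from_blocks(block_sizes, n=8, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    dirs, _ = np.linalg.qr(rng.normal(size=(n, len(block_sizes))))
    rows, labels, blocks = [], [], []
    start = 0
    for b, size in enumerate(block_sizes):
        centre = sep / np.sqrt(2) * dirs[:, b]
        rows.append(centre + rng.normal(size=(size, n)))
        labels += [b] * size
        blocks.append(RuleBlock(b, ["go_east", "go_right", "go_west",
                                    "go_left"][b % 4], start,
                                start + size - 1, "switch"))
        start += size
    X = np.vstack(rows)
    frm = FiringRateMatrix("entire_trial", X, np.ones(len(X)),
                           [f"n{j}" for j in range(n)], np.arange(len(X)))
    phases = behavior.PhaseLabels(np.array(["learnt"] * len(X), dtype=object),
                                  behavior.NAIVE_THRESHOLDS, 0.6)
    return build_population_vectors(frm, phases, blocks), blocks


def _toy_table(rows):
    return DistanceTable(pd.DataFrame(
        rows, columns=["session_id", "block_i", "block_j", "euclidean",
                       "mahalanobis", "trials_between", "rules_between",
                       "same_rule_pair"]))


class TestDistanceTable:
    def test_three_sequential_blocks_pair_structure(self):
        pm, blocks = _pm_from_blocks([10, 10, 10])
        table = rule_distance_table(pm, blocks).pairs
        got = {(r.block_i, r.block_j): r.rules_between
               for r in table.itertuples()}
        assert got == {(0, 1): 0, (0, 2): 1, (1, 2): 0}

    def test_trials_between_is_median_gap(self):
        pm, blocks = _pm_from_blocks([10, 20, 10])
        table = rule_distance_table(pm, blocks).pairs
        med = {0: np.median(np.arange(0, 10)),
               1: np.median(np.arange(10, 30)),
               2: np.median(np.arange(30, 40))}
        for r in table.itertuples():
            assert r.trials_between == pytest.approx(
                abs(med[r.block_i] - med[r.block_j]))

    def test_repeat_pair_flagged(self):
        pm, blocks = _pm_from_blocks([10, 10, 10])
        blocks[2].rule_name = blocks[0].rule_name  # A ... A° with one between
        table = rule_distance_table(pm, blocks).pairs
        row = table[(table.block_i == 0) & (table.block_j == 2)].iloc[0]
        assert bool(row.same_rule_pair)
        assert row.rules_between == 1
        assert not table[(table.block_i == 0)
                         & (table.block_j == 1)].iloc[0].same_rule_pair

    def test_distances_are_nonnegative_and_symmetric_definition(self):
        pm, blocks = _pm_from_blocks([12, 12, 12], sep=3.0, seed=5)
        t = rule_distance_table(pm, blocks).pairs
        assert (t["euclidean"] >= 0).all()
        assert (t["mahalanobis"].dropna() >= 0).all()


class TestDistanceRegression:
    @staticmethod
    def _planted(n_sessions=12, noise=0.5, beta_rules=2.0, beta_trials=0.0,
                 seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sessions):
            sizes = rng.integers(15, 35, size=4)
            med = np.cumsum(sizes) - sizes / 2
            for i in range(4):
                for j in range(i + 1, 4):
                    tb = abs(med[i] - med[j])
                    rb = j - i - 1
                    d = (beta_rules * rb + beta_trials * tb
                         + noise * rng.normal())
                    rows.append((f"s{s}", i, j, d, d, tb, rb, False))
        return _toy_table(rows)

    def test_rules_flagged_trials_not_when_planted_on_rules(self):
        res = distance_regression(self._planted(beta_rules=2.0), True)
        assert res.pvalues["rules_between"] < 0.05
        assert res.pvalues["trials_between"] > 0.05

    def test_trials_flagged_when_planted_on_trials(self):
        res = distance_regression(
            self._planted(beta_rules=0.0, beta_trials=0.1), True)
        assert res.pvalues["trials_between"] < 0.05
        assert res.pvalues["rules_between"] > 0.05

    def test_constant_distance_gives_zero_slopes(self):
        rng = np.random.default_rng(7)  # trial gaps varied: regressors
        rows = [("s0", i, j, 5.0, 5.0, float(rng.integers(5, 60)),
                 j - i - 1, False)      # must not be collinear
                for i in range(4) for j in range(i + 1, 4)]
        res = distance_regression(_toy_table(rows), use_zscored_distance=False)
        assert res.params["trials_between"] == pytest.approx(0.0, abs=1e-10)
        assert res.params["rules_between"] == pytest.approx(0.0, abs=1e-10)

    def test_collinear_regressors_rejected(self):
        rows = [("s0", i, j, 1.0 * (j - i), np.nan, 10.0 * (j - i),
                 (j - i), False)  # rules ~ exactly 0.1 * trials
                for i in range(5) for j in range(i + 1, 5)]
        with pytest.raises(ValueError, match="collinear"):
            distance_regression(_toy_table(rows), False)


class TestPartialSpearman:
    def test_control_removes_shared_driver(self):
        # x and y are associated only through z: the raw rank correlation
        # is large, the partial one collapses to noise level
        rng = np.random.default_rng(1)
        z = rng.normal(size=200)
        x = z + 0.7 * rng.normal(size=200)
        y = z + 0.7 * rng.normal(size=200)
        raw = stats.spearmanr(x, y).statistic
        rho, p = partial_spearman(x, y, z)
        assert raw > 0.5
        assert abs(rho) < 0.15
        assert p > 1e-3

    def test_independent_control_leaves_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        z = rng.normal(size=60)
        rho, p = partial_spearman(x, x, z)
        assert rho > 0.97
        assert p < 1e-10

    def test_matches_rank_residual_oracle(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=50)
        x = 0.5 * z + rng.normal(size=50)
        y = -0.3 * z + rng.normal(size=50)
        rho, _ = partial_spearman(x, y, z)
        assert rho == pytest.approx(
            partial_spearman_residual_oracle(x, y, z), abs=0.02)

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        z = rng.normal(size=40)
        x = 0.4 * z + rng.normal(size=40)
        y = 0.6 * z + rng.normal(size=40)
        rho, p = partial_spearman(x, y, z)
        ref = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y",
            covar="z", method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-3)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman([1, 2, 3, 4, 5], [1, 1, 1, 1, 1],
                             [2, 1, 4, 3, 5])


class TestRepeatedRuleTest:
    def test_all_equal_distances_normalise_to_one_and_p_is_one(self):
        rows = [("s0", 0, 1, 3.0, 3.0, 10, 0, False),
                ("s0", 1, 2, 3.0, 3.0, 12, 0, False),
                ("s0", 0, 2, 3.0, 3.0, 22, 1, True),
                ("s1", 0, 2, 3.0, 3.0, 20, 1, False)]
        res = repeated_rule_test(_toy_table(rows))
        assert np.allclose(res.normalised_same, 1.0)
        assert np.allclose(res.normalised_different, 1.0)
        assert res.p == pytest.approx(1.0)

    def test_stratum_means_are_exactly_one(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(6):
            for rb in (0, 0, 1):
                rows.append((f"s{s}", 0, rb + 1, rng.gamma(3.0), np.nan,
                             10.0, rb, bool(rng.random() < 0.3)))
        table = _toy_table(rows)
        try:
            res = repeated_rule_test(table)
        except ValueError:
            pytest.skip("random draw produced no same/different contrast")
        df = table.pairs
        all_norm = np.concatenate([res.normalised_same,
                                   res.normalised_different])
        all_rb = np.concatenate([
            df.loc[df.same_rule_pair, "rules_between"],
            df.loc[~df.same_rule_pair, "rules_between"]])
        for rb in np.unique(all_rb):
            stratum = all_norm[all_rb == rb]
            if stratum.size:
                assert stratum.mean() == pytest.approx(1.0, abs=1e-9)

    def test_same_rule_stratum_without_reference_dropped_with_warning(self):
        rows = [("s0", 0, 1, 2.0, np.nan, 10, 0, False),
                ("s0", 1, 2, 2.5, np.nan, 10, 0, False),
                ("s0", 0, 3, 4.0, np.nan, 30, 2, True)]  # lone stratum rb=2
        with pytest.warns(UserWarning, match="rules_between=2"):
            with pytest.raises(ValueError, match="no comparable"):
                repeated_rule_test(_toy_table(rows))

    def test_regression_residual_variant_runs(self):
        rng = np.random.default_rng(6)
        rows = [("s0", i, j, 2.0 * (j - i - 1) + rng.gamma(2.0), np.nan,
                 10.0 * (j - i), j - i - 1, (i, j) == (0, 3))
                for i in range(5) for j in range(i + 1, 5)]
        res = repeated_rule_test(_toy_table(rows),
                                 normalisation="regression_residual")
        assert res.n_same == 1
        assert np.isfinite(res.p)
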