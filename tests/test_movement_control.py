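import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ruleflux import behavior
from ruleflux.firing_correlates import FiringRateMatrix
from ruleflux.movement_control import (ResidualModel, TrajectoryFit,
                                       coefficient_ranges, fit_movement_glm,
                                       fit_trajectory, rerun_on_residuals,
                                       similarity_index,
                                       trajectory_matched_distance_test)
from ruleflux.session_io import from_canonical

from _oracles import ols_normal_equations


def _canonical_samples(a, b, c, path="NE", n=30, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    s = np.linspace(0, 113.0, n)
    w = a * s ** 2 + b * s + c + noise * rng.normal(size=n)
    return from_canonical(s, w, path)


class TestFitTrajectory:
    def test_exact_quadratic_recovered(self):
        xy = _canonical_samples(2.0, 3.0, 1.0)
        fit = fit_trajectory(xy, "NE")
        assert (fit.a, fit.b, fit.c) == pytest.approx((2.0, 3.0, 1.0),
                                                      abs=1e-9)

    def test_collinear_points_give_zero_curvature(self):
        xy = _canonical_samples(0.0, -0.5, 4.0)
        fit = fit_trajectory(xy, "SW")
        assert fit.a == pytest.approx(0.0, abs=1e-10)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        xy = _canonical_samples(0.01, -1.0, 2.0, noise=1.5, seed=4)
        fit = fit_trajectory(xy, "NE")
        from ruleflux.session_io import to_canonical
        can = to_canonical(xy, "NE")
        X = np.column_stack([can[:, 0] ** 2, can[:, 0], np.ones(len(can))])
        beta = ols_normal_equations(X, can[:, 1])
        assert fit.coeffs == pytest.approx(beta, abs=1e-9)

    def test_refit_of_fitted_parabola_is_identity(self):
        fit = fit_trajectory(_canonical_samples(0.01, -1.1, 2.0, noise=2.0,
                                                seed=1), "NE")
        clean = _canonical_samples(fit.a, fit.b, fit.c)
        refit = fit_trajectory(clean, "NE")
        assert refit.coeffs == pytest.approx(fit.coeffs, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_trajectory(np.zeros((2, 2)), "NE")


class TestSimilarityIndex:
    RANGES = {"a": (0.0, 2.0), "b": (0.0, 1.0), "c": (0.0, 4.0)}

    @staticmethod
    def _fit(a, b, c):
        return TrajectoryFit(-1, "NE", a, b, c, 0.0)

    def test_hand_computed_example_sqrt_seven(self):
        # weights 1/2, 1, 1/4 against squared diffs 4, 1, 16 -> sqrt(7)
        ned = similarity_index(self._fit(0, 0, 0), self._fit(2, 1, 4),
                               self.RANGES)
        assert ned == pytest.approx(np.sqrt(7.0), abs=1e-12)

    def test_identity_and_symmetry(self):
        f1, f2 = self._fit(0.5, 0.2, 1.0), self._fit(1.5, 0.8, 3.0)
        assert similarity_index(f1, f1, self.RANGES) == 0.0
        assert similarity_index(f1, f2, self.RANGES) == \
            similarity_index(f2, f1, self.RANGES)

    def test_degenerate_range_term_contributes_zero(self):
        ranges = {"a": (1.0, 1.0), "b": (0.0, 1.0), "c": (0.0, 4.0)}
        ned = similarity_index(self._fit(0, 0, 0), self._fit(5, 1, 4), ranges)
        assert ned == pytest.approx(np.sqrt(1.0 + 4.0), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
                    min_size=3, max_size=3))
    def test_metric_triangle_inequality(self, triples):
        f = [self._fit(*t) for t in triples]
        d01 = similarity_index(f[0], f[1], self.RANGES)
        d12 = similarity_index(f[1], f[2], self.RANGES)
        d02 = similarity_index(f[0], f[2], self.RANGES)
        assert d02 <= d01 + d12 + 1e-9

    def test_coefficient_ranges_cover_population(self):
        fits = [self._fit(0.1, -1, 2), self._fit(0.3, -2, 0)]
        r = coefficient_ranges(fits)
        assert r["a"] == (0.1, 0.3)
        assert r["b"] == (-2.0, -1.0)
        assert r["c"] == (0.0, 2.0)


def _session_pieces(seed=21, **over):
    from ruleflux import firing_correlates as fc
    from ruleflux import movement_control as mc
    from ruleflux import synthetic_data as sd
    cfg = sd.GeneratorConfig(seed=seed, **over)
    session, truth = sd.generate_session(cfg, seed=seed)
    phases = behavior.session_phases(session)
    curve = behavior.estimate_performance(session.outcomes())
    frm = fc.compute_segment_rates(session, "entire_trial")
    fits = mc.fit_session_trajectories(session)
    speeds = np.array([t.mean_speed for t in session.trials])
    return session, truth, phases, curve, frm, fits, speeds


class TestMovementGlm:
    def test_rate_proportional_to_speed_leaves_no_residual(self):
        session, _, _, _, frm, fits, speeds = _session_pieces()
        vals = np.outer(3.0 * speeds, np.ones(4))
        frm3 = FiringRateMatrix("entire_trial", vals, frm.segment_durations,
                                ["n0", "n1", "n2", "n3"], frm.trial_indices)
        model = fit_movement_glm(frm3, fits, speeds)
        assert np.max(np.abs(model.residuals)) < 1e-9

    def test_residuals_orthogonal_to_design(self):
        session, _, _, _, frm, fits, speeds = _session_pieces()
        model = fit_movement_glm(frm, fits, speeds)
        paths = np.array(model.path_per_trial)
        for ptype in model.coefficients:
            rows = np.nonzero(paths == ptype)[0]
            X = np.column_stack([
                np.ones(rows.size),
                [fits[int(frm.trial_indices[i])].a for i in rows],
                [fits[int(frm.trial_indices[i])].b for i in rows],
                [fits[int(frm.trial_indices[i])].c for i in rows],
                speeds[rows]])
            dots = X.T @ model.residuals[rows]
            scale = np.abs(X).sum(axis=0)[:, None] + 1e-12
            assert np.max(np.abs(dots) / scale) < 1e-6

    def test_planted_movement_coupling_fraction_recovered(self):
        """~30% of neurons coupled to movement: the per-path fraction with a
        significant coefficient lands within 10 points of 30%."""
        session, truth, phases, curve, frm, fits, speeds = _session_pieces(
            seed=3, n_neurons=40, state_separation=0.0, frac_pos_coupled=0.0,
            frac_neg_coupled=0.0, movement_coupling=0.0)
        rng = np.random.default_rng(3)
        coupled = rng.choice(40, size=12, replace=False)
        vals = frm.values.copy()
        feats = np.column_stack([[fits[t.index].a for t in session.trials],
                                 speeds])
        feats = (feats - feats.mean(0)) / feats.std(0)
        for j in coupled:
            vals[:, j] = vals[:, j] + 4.0 * feats @ rng.normal(size=2)
        frm2 = FiringRateMatrix(frm.segment, vals, frm.segment_durations,
                                frm.neuron_ids, frm.trial_indices)
        model = fit_movement_glm(frm2, fits, speeds)
        mean_frac = np.mean(list(model.frac_significant.values()))
        assert mean_frac == pytest.approx(0.30, abs=0.10)

    def test_identity_residuals_reproduce_original_pipeline(self):
        """Forcing all betas to zero (residual = rate) must reproduce the
        original correlations and clustering exactly."""
        session, _, phases, curve, frm, fits, speeds = _session_pieces()
        model = ResidualModel(
            residuals=frm.values.copy(), coefficients={}, pvalues={},
            path_per_trial=[fits[t.index].path_type for t in session.trials],
            frac_significant={}, skipped_paths=[], alpha=0.05)
        report = rerun_on_residuals(frm, model, curve, phases,
                                    session.rule_schedule, n_perm=30, seed=4,
                                    n_restarts=5)
        a = report.corr_original.table
        b = report.corr_residual.table
        np.testing.assert_allclose(a["rho"], b["rho"], atol=1e-12)
        assert report.rho_agreement == pytest.approx(1.0)
        assert report.clustering_original.accuracy == \
            report.clustering_residual.accuracy
        np.testing.assert_array_equal(report.clustering_original.assignments,
                                      report.clustering_residual.assignments)

    def test_movement_free_residuals_keep_correlations(self):
        """Rates independent of movement: residual correlations track the
        originals closely (rank agreement near 1)."""
        session, _, phases, curve, frm, fits, speeds = _session_pieces()
        model = fit_movement_glm(frm, fits, speeds)
        report = rerun_on_residuals(frm, model, curve, phases,
                                    session.rule_schedule, n_perm=30, seed=4,
                                    n_restarts=5)
        assert report.rho_agreement > 0.85
        ro = report.corr_original.table["rho"].to_numpy()
        rr = report.corr_residual.table["rho"].to_numpy()
        assert np.nanmedian(np.abs(ro - rr)) < 0.05


class TestTrajectoryMatched:
    def test_distinct_state_with_matched_trajectories_detected(self):
        """A deg occupies a new state but trajectories are drawn exactly as
        in A: matched-trajectory cross pairs still show larger population
        distances than mismatched within-A pairs."""
        session, truth, phases, curve, frm, fits, speeds = _session_pieces(
            seed=11, state_separation=8.0, asymptote_p=0.65,
            max_block_trials=80,
            rule_sequence=("go_east", "go_right", "go_east"))
        from ruleflux.population_states import build_population_vectors
        pm = build_population_vectors(frm, phases, session.rule_schedule)
        blocks = session.rule_schedule
        res = trajectory_matched_distance_test(pm, fits, blocks[0], blocks[2])
        assert res.p < 0.05
        assert np.median(res.cross_distances) > np.median(res.within_distances)

    def test_selection_counts_follow_floor_convention(self):
        session, truth, phases, curve, frm, fits, speeds = _session_pieces(
            seed=12, state_separation=8.0)
        from ruleflux.population_states import build_population_vectors
        pm = build_population_vectors(frm, phases, session.rule_schedule)
        blocks = session.rule_schedule
        res = trajectory_matched_distance_test(pm, fits, blocks[0], blocks[3])
        assert res.n_similar_cross == max(1, int(0.05 * len(res.cross_nED)))
        assert res.n_different_within == max(1, int(0.05 * len(res.within_nED)))

    def test_insufficient_shared_path_trials_rejected(self):
        session, truth, phases, curve, frm, fits, speeds = _session_pieces()
        from ruleflux.population_states import build_population_vectors
        pm = build_population_vectors(frm, phases, session.rule_schedule)
        blocks = session.rule_schedule
        few = {k: v for k, v in fits.items()
               if k < blocks[3].first_trial or v.path_type != "NE"}
        # drop NE fits from the repetition block, then demand NE
        with pytest.raises(ValueError, match="shared path"):
            trajectory_matched_distance_test(pm, few, blocks[0], blocks[3],
                                             path_type="NE")
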