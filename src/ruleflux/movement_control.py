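"""Movement controls: trajectory fits, similarity index, residual re-analysis.

A run on the plus maze is summarised by a quadratic fit of its trajectory
in the path's canonical frame: the transverse deviation w as a function of
the longitudinal coordinate s, w = a*s^2 + b*s + c.  Two trajectories are
compared with the *similarity index* nED, a range-normalised Euclidean
distance between coefficient triples,

    nED = sqrt(W_a (a2-a1)^2 + W_b (b2-b1)^2 + W_c (c2-c1)^2),
    W_k = 1 / (max(k) - min(k))  over the comparison population,

where 0 means identical paths and larger values more different ones.

Two controls rule out movement as the source of rule-specific population
states:

* the *trajectory-matched* comparison: population-vector distances between
  rule-A and repetition-A° trials whose trajectories are nearly identical
  (cross-pair nED below the 5th percentile) are compared with distances
  between A trials whose trajectories are very different (within-A nED
  above the 95th percentile);
* the *residual* re-analysis: each neuron's rate is regressed per path type
  on (a, b, c, speed); the residuals — the firing not explained by movement
  — are pushed through the performance-correlation and clustering stages
  and reported side by side with the originals.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import behavior
from .firing_correlates import (CorrelationTable, FiringRateMatrix,
                                performance_correlations, spearman_columns)
from .population_states import (ClusterEvaluation, PopulationMatrix,
                                build_population_vectors, cluster_by_rule,
                                euclidean_distance)
from .session_io import PATH_TYPES, RuleBlock, Session, path_type_of, to_canonical

__all__ = [
    "TrajectoryFit", "ResidualModel", "TrajectoryMatchedResult",
    "ResidualReport", "fit_trajectory", "fit_session_trajectories",
    "coefficient_ranges", "similarity_index",
    "trajectory_matched_distance_test", "fit_movement_glm",
    "rerun_on_residuals",
]

logger = logging.getLogger("ruleflux")

PERCENTILE_FRACTION = 0.05
MIN_SHARED_PATH_TRIALS = 5
GLM_REGRESSORS = ("a", "b", "c", "speed")


@dataclasses.dataclass
class TrajectoryFit:
    trial_index: int
    path_type: str
    a: float
    b: float
    c: float
    rmse: float

    @property
    def coeffs(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


def fit_trajectory(samples: np.ndarray, path_type: str,
                   trial_index: int = -1) -> TrajectoryFit:
    """Least-squares quadratic of transverse vs longitudinal coordinate.

    ``samples`` is an (n, 2) array of maze-frame (x, y) positions, or an
    (n, 3) array whose first column is time (as stored in trajectories.csv).
    """
    pts = np.asarray(samples, float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 position samples")
    if pts.shape[1] == 3:
        pts = pts[:, 1:]
    can = to_canonical(pts, path_type)
    s, w = can[:, 0], can[:, 1]
    a, b, c = np.polyfit(s, w, 2)
    resid = w - (a * s ** 2 + b * s + c)
    return TrajectoryFit(trial_index=trial_index, path_type=path_type,
                         a=float(a), b=float(b), c=float(c),
                         rmse=float(np.sqrt(np.mean(resid ** 2))))


def fit_session_trajectories(session: Session) -> dict[int, TrajectoryFit]:
    """Quadratic fit for every trial with recorded position samples."""
    fits: dict[int, TrajectoryFit] = {}
    for t in session.trials:
        samples = session.trajectories.get(t.index)
        if samples is None or len(samples) < 3:
            continue
        ptype = path_type_of(t.start_arm, t.chosen_arm)
        fits[t.index] = fit_trajectory(samples, ptype, trial_index=t.index)
    return fits


def coefficient_ranges(fits: Sequence[TrajectoryFit]) -> dict[str, tuple[float, float]]:
    """(min, max) of each quadratic coefficient over a comparison population."""
    arr = np.array([[f.a, f.b, f.c] for f in fits])
    return {k: (float(arr[:, i].min()), float(arr[:, i].max()))
            for i, k in enumerate(("a", "b", "c"))}


def similarity_index(fit_i: TrajectoryFit, fit_j: TrajectoryFit,
                     ranges: Mapping[str, tuple[float, float]]) -> float:
    """Range-normalised Euclidean distance between coefficient triples.

    Each squared coefficient difference is weighted by 1/(max - min) of that
    coefficient over the comparison population.  A degenerate range
    (max == min, so the coefficient is constant in the population) carries
    no information and its term contributes 0, with a logged notice.
    """
    total = 0.0
    for key, di in zip(("a", "b", "c"),
                       fit_j.coeffs - fit_i.coeffs):
        lo, hi = ranges[key]
        if hi < lo:
            raise ValueError(f"range for {key} has max < min")
        if hi == lo:
            logger.info("similarity_index: coefficient %s has zero range; "
                        "term dropped", key)
            continue
        total += (di ** 2) / (hi - lo)
    return float(np.sqrt(total))


# --------------------------------------------------------------------------
# Trajectory-matched population-distance comparison
# --------------------------------------------------------------------------

@dataclasses.dataclass
class TrajectoryMatchedResult:
    path_type: str
    statistic: float
    p: float
    n_similar_cross: int
    n_different_within: int
    cross_distances: np.ndarray    # population distances, selected A x A° pairs
    within_distances: np.ndarray   # population distances, selected A x A pairs
    cross_nED: np.ndarray          # full cross-pair similarity distribution
    within_nED: np.ndarray


def _select_count(n: int, fraction: float = PERCENTILE_FRACTION) -> int:
    """Pairs kept at a percentile cut: floor(fraction * n), at least 1."""
    return max(1, int(np.floor(fraction * n)))


def trajectory_matched_distance_test(pm: PopulationMatrix,
                                     fits: Mapping[int, TrajectoryFit],
                                     block_A: RuleBlock,
                                     block_Arep: RuleBlock,
                                     path_type: str | None = None,
                                     fraction: float = PERCENTILE_FRACTION) -> TrajectoryMatchedResult:
    """Compare population distances of trajectory-matched A-A° pairs with
    trajectory-mismatched within-A pairs.

    Builds the A x A° cross-pair nED distribution and the within-A pair
    distribution on a shared path type (chosen as the path with the largest
    minimum count when not given); selects cross pairs below the 5th
    percentile of cross nED (similar trajectories) and within-A pairs above
    the 95th percentile of within nED (different trajectories); compares
    their population-vector Euclidean distances by Wilcoxon rank-sum.
    """
    row_of = {int(t): i for i, t in enumerate(pm.included_trials)}

    def _rows(block: RuleBlock, ptype: str) -> list[int]:
        return [row_of[t] for t in block.trial_indices()
                if t in row_of and t in fits and fits[t].path_type == ptype]

    if path_type is None:
        best, best_min = None, -1
        for ptype in PATH_TYPES:
            lo = min(len(_rows(block_A, ptype)), len(_rows(block_Arep, ptype)))
            if lo > best_min:
                best, best_min = ptype, lo
        path_type = best
    rows_A = _rows(block_A, path_type)
    rows_rep = _rows(block_Arep, path_type)
    if min(len(rows_A), len(rows_rep)) < MIN_SHARED_PATH_TRIALS:
        raise ValueError(
            f"path {path_type}: need >= {MIN_SHARED_PATH_TRIALS} trials of a "
            f"shared path type in both blocks (have {len(rows_A)} and "
            f"{len(rows_rep)})")

    trial_of = {i: int(t) for t, i in row_of.items()}
    pool = [fits[trial_of[r]] for r in rows_A + rows_rep]
    ranges = coefficient_ranges(pool)

    cross_pairs = [(i, j) for i in rows_A for j in rows_rep]
    within_pairs = [(rows_A[i], rows_A[j]) for i in range(len(rows_A))
                    for j in range(i + 1, len(rows_A))]
    cross_ned = np.array([similarity_index(fits[trial_of[i]],
                                           fits[trial_of[j]], ranges)
                          for i, j in cross_pairs])
    within_ned = np.array([similarity_index(fits[trial_of[i]],
                                            fits[trial_of[j]], ranges)
                           for i, j in within_pairs])

    n_sim = _select_count(len(cross_pairs), fraction)
    n_diff = _select_count(len(within_pairs), fraction)
    sim_idx = np.argsort(cross_ned, kind="stable")[:n_sim]
    diff_idx = np.argsort(within_ned, kind="stable")[-n_diff:]
    if sim_idx.size == 0 or diff_idx.size == 0:
        raise ValueError("empty percentile selection; relax the percentile")

    cross_d = np.array([euclidean_distance(pm.Z[cross_pairs[i][0]],
                                           pm.Z[cross_pairs[i][1]])
                        for i in sim_idx])
    within_d = np.array([euclidean_distance(pm.Z[within_pairs[i][0]],
                                            pm.Z[within_pairs[i][1]])
                         for i in diff_idx])
    stat, p = stats.ranksums(cross_d, within_d)
    return TrajectoryMatchedResult(path_type=path_type, statistic=float(stat),
                                   p=float(p), n_similar_cross=int(n_sim),
                                   n_different_within=int(n_diff),
                                   cross_distances=cross_d,
                                   within_distances=within_d,
                                   cross_nED=cross_ned, within_nED=within_ned)


# --------------------------------------------------------------------------
# Movement GLM and residual re-analysis
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ResidualModel:
    residuals: np.ndarray              # trials x neurons, trial order
    coefficients: dict[str, np.ndarray]  # path -> neurons x 5 (incl. intercept)
    pvalues: dict[str, np.ndarray]       # path -> neurons x 4 (a, b, c, speed)
    path_per_trial: list[str]
    frac_significant: dict[str, float]   # per path: neurons with >=1 sig coef
    skipped_paths: list[str]
    alpha: float


def fit_movement_glm(frm: FiringRateMatrix, fits: Mapping[int, TrajectoryFit],
                     speeds: Sequence[float],
                     alpha: float = 0.05) -> ResidualModel:
    """Per neuron and path type, OLS of rate on (a, b, c, speed) + intercept.

    Residuals are reassembled in trial order.  A path subset with fewer
    trials than regressors is skipped: its residuals are the mean-centred
    rates and its coefficients are undefined (logged).
    """
    speeds = np.asarray(speeds, float)
    m, n = frm.values.shape
    if len(speeds) != m:
        raise ValueError("speeds must cover every trial of the rate matrix")
    missing = [int(t) for t in frm.trial_indices if int(t) not in fits]
    if missing:
        raise ValueError(f"trials without a trajectory fit: {missing[:5]}")

    path_per_trial = [fits[int(t)].path_type for t in frm.trial_indices]
    residuals = np.empty_like(frm.values, dtype=float)
    coefficients: dict[str, np.ndarray] = {}
    pvalues: dict[str, np.ndarray] = {}
    frac_sig: dict[str, float] = {}
    skipped: list[str] = []

    for ptype in sorted(set(path_per_trial)):
        rows = np.array([i for i, p in enumerate(path_per_trial) if p == ptype])
        Y = frm.values[rows]
        k = len(GLM_REGRESSORS) + 1
        if rows.size <= k:
            skipped.append(ptype)
            logger.warning("path %s: %d trial(s) <= %d regressors; residual "
                           "= rate - mean", ptype, rows.size, k)
            residuals[rows] = Y - Y.mean(axis=0)
            continue
        A = np.array([[fits[int(frm.trial_indices[i])].a,
                       fits[int(frm.trial_indices[i])].b,
                       fits[int(frm.trial_indices[i])].c,
                       speeds[i]] for i in rows])
        X = np.column_stack([np.ones(rows.size), A])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        fitted = X @ beta
        res = Y - fitted
        residuals[rows] = res
        # classical OLS t-tests per neuron and coefficient
        dof = rows.size - k
        XtX_inv = np.linalg.pinv(X.T @ X)
        s2 = (res ** 2).sum(axis=0) / dof
        se = np.sqrt(np.outer(np.diag(XtX_inv), s2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        pv = 2.0 * stats.t.sf(np.abs(tvals), df=dof)
        coefficients[ptype] = beta.T            # neurons x (1 + 4)
        pvalues[ptype] = pv[1:].T               # neurons x 4, intercept excluded
        frac_sig[ptype] = float(np.mean((pv[1:] < alpha).any(axis=0)))
    return ResidualModel(residuals=residuals, coefficients=coefficients,
                         pvalues=pvalues, path_per_trial=path_per_trial,
                         frac_significant=frac_sig, skipped_paths=skipped,
                         alpha=alpha)


@dataclasses.dataclass
class ResidualReport:
    corr_original: CorrelationTable
    corr_residual: CorrelationTable
    rho_agreement: float               # Spearman(original rho, residual rho)
    rho_agreement_p: float
    clustering_original: ClusterEvaluation
    clustering_residual: ClusterEvaluation
    per_path_residual_clustering: dict[str, ClusterEvaluation]
    per_path_original_clustering: dict[str, ClusterEvaluation]


def rerun_on_residuals(frm: FiringRateMatrix, residual_model: ResidualModel,
                       curve: behavior.PerformanceCurve,
                       phases: behavior.PhaseLabels,
                       blocks: Sequence[RuleBlock],
                       n_perm: int = 200, seed: int = 0,
                       n_restarts: int = 20, alpha: float = 0.05) -> ResidualReport:
    """Repeat the correlation and clustering stages on movement residuals.

    Reports the original and residual performance correlations with their
    rank agreement (how well per-neuron correlation values survive the
    movement correction), overall clustering on originals and residuals,
    and per-path-type residual clustering (each path analysed alone, so the
    trajectory cannot distinguish rules within the subset).
    """
    res_frm = FiringRateMatrix(segment=frm.segment + "_residual",
                               values=residual_model.residuals,
                               segment_durations=frm.segment_durations,
                               neuron_ids=frm.neuron_ids,
                               trial_indices=frm.trial_indices)
    corr_orig = performance_correlations(frm, curve, alpha=alpha)
    corr_res = performance_correlations(res_frm, curve, alpha=alpha)
    ro = corr_orig.table["rho"].to_numpy()
    rr = corr_res.table["rho"].to_numpy()
    ok = ~(np.isnan(ro) | np.isnan(rr))
    if ok.sum() >= 3:
        agree, agree_p = stats.spearmanr(ro[ok], rr[ok])
    else:
        agree, agree_p = np.nan, np.nan

    pm_orig = build_population_vectors(frm, phases, blocks)
    pm_res = build_population_vectors(res_frm, phases, blocks)
    clus_orig = cluster_by_rule(pm_orig, n_perm=n_perm, seed=seed,
                                n_restarts=n_restarts)
    clus_res = cluster_by_rule(pm_res, n_perm=n_perm, seed=seed,
                               n_restarts=n_restarts)

    per_path_res: dict[str, ClusterEvaluation] = {}
    per_path_orig: dict[str, ClusterEvaluation] = {}
    incl = phases.included()
    path_all = np.array(residual_model.path_per_trial)
    for ptype in sorted(set(residual_model.path_per_trial)):
        sub_phase_mask = incl[path_all == ptype]
        labels = behavior.PhaseLabels(
            labels=np.where(sub_phase_mask, "learning", "naive"),
            naive_thresholds=phases.naive_thresholds,
            learnt_threshold=phases.learnt_threshold)
        for source, store in ((res_frm, per_path_res), (frm, per_path_orig)):
            try:
                pm_sub = build_population_vectors(source.subset(path_all == ptype),
                                                  labels, blocks)
                if len(pm_sub.blocks_present()) < 2:
                    continue
                store[ptype] = cluster_by_rule(pm_sub, n_perm=n_perm,
                                               seed=seed,
                                               n_restarts=n_restarts)
            except ValueError:
                continue
    return ResidualReport(corr_original=corr_orig, corr_residual=corr_res,
                          rho_agreement=float(agree),
                          rho_agreement_p=float(agree_p),
                          clustering_original=clus_orig,
                          clustering_residual=clus_res,
                          per_path_residual_clustering=per_path_res,
                          per_path_original_clustering=per_path_orig)
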