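"""Geometry of rule-cluster centres: drift vs discrete state changes.

If prefrontal population activity merely drifted with time, the distance
between two rule clusters would grow with the number of trials separating
them; if each rule change pushes the population to a new state, distance
should instead track the number of intervening rules.  The analyses here
disambiguate the two:

* a table of all unordered rule-block pairs with their centre distances
  (Euclidean and Mahalanobis), the trial gap (difference of median included
  trial indices) and the number of blocks strictly in between;
* a pooled multiple linear regression of (within-session z-scored) centre
  distance on trials-between, rules-between and their interaction;
* first-order partial Spearman correlations of distance with each regressor
  controlling for the other;
* the repeated-rule test: distances between two blocks of the *same* rule,
  normalised within strata of equal rules-between, compared by rank-sum to
  distances between different rules.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .population_states import (PopulationMatrix, RuleCluster,
                                clusters_from_labels, euclidean_distance,
                                mahalanobis_distance)
from .session_io import RuleBlock

__all__ = [
    "DistanceTable", "RegressionResult", "RepeatTestResult",
    "rule_distance_table", "distance_regression", "partial_spearman",
    "repeated_rule_test",
]

logger = logging.getLogger("ruleflux")

PAIR_COLUMNS = ["session_id", "block_i", "block_j", "euclidean", "mahalanobis",
                "trials_between", "rules_between", "same_rule_pair"]


@dataclasses.dataclass
class DistanceTable:
    pairs: pd.DataFrame  # PAIR_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in PAIR_COLUMNS if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"distance table missing columns: {missing}")

    @staticmethod
    def concat(tables: Sequence["DistanceTable"]) -> "DistanceTable":
        return DistanceTable(pd.concat([t.pairs for t in tables],
                                       ignore_index=True))


def rule_distance_table(pm: PopulationMatrix, blocks: Sequence[RuleBlock],
                        session_id: str = "s0") -> DistanceTable:
    """All unordered block pairs with centre distances and separations.

    trials_between is the absolute difference of the blocks' median included
    trial indices; rules_between counts blocks strictly between the two in
    presentation order (adjacent blocks = 0).  The Mahalanobis entry is the
    symmetrised centre-to-cluster distance (each centre against the other
    cluster's shrunk covariance, averaged).
    """
    present = pm.blocks_present()
    if len(present) < 2:
        raise ValueError("need at least 2 rule blocks with included trials")
    order = {b.rule_id: i for i, b in enumerate(blocks)}
    names = {b.rule_id: b.rule_name for b in blocks}
    clusters = {c.block_id: c for c in clusters_from_labels(pm)}
    med = {bid: float(np.median(pm.included_trials[pm.rule_labels == bid]))
           for bid in present}

    rows = []
    for ii in range(len(present)):
        for jj in range(ii + 1, len(present)):
            bi, bj = present[ii], present[jj]
            ci, cj = clusters[bi], clusters[bj]
            eu = euclidean_distance(ci.centre_of_mass, cj.centre_of_mass)
            try:
                md = 0.5 * (mahalanobis_distance(ci.centre_of_mass, cj)
                            + mahalanobis_distance(cj.centre_of_mass, ci))
            except np.linalg.LinAlgError:
                md = np.nan
            rows.append({
                "session_id": session_id,
                "block_i": bi,
                "block_j": bj,
                "euclidean": eu,
                "mahalanobis": md,
                "trials_between": abs(med[bi] - med[bj]),
                "rules_between": abs(order[bi] - order[bj]) - 1,
                "same_rule_pair": names[bi] == names[bj],
            })
    return DistanceTable(pd.DataFrame(rows, columns=PAIR_COLUMNS))


@dataclasses.dataclass
class RegressionResult:
    params: dict[str, float]
    pvalues: dict[str, float]
    n_pairs: int
    distance_col: str
    r_squared: float
    homoscedasticity_p: float  # Breusch-Pagan LM test


def distance_regression(table: DistanceTable,
                        use_zscored_distance: bool = True,
                        distance_col: str = "euclidean") -> RegressionResult:
    """OLS of centre distance on trials_between, rules_between and their
    interaction, pooled over sessions.

    Distances are z-scored within session before pooling (sessions differ
    in neuron count, hence in raw distance scale), and so is the trial gap
    (sessions differ in trial counts; a shared slope on raw trial gaps would
    mistake between-session scale for a within-session trend).  The rule
    gap is already on a common scale across sessions.  Collinear regressors
    (|r| > 0.999) raise; homoscedasticity is checked with Breusch-Pagan.
    """
    df = table.pairs.dropna(subset=[distance_col]).copy()
    if len(df) < 3:
        raise ValueError("need at least 3 block pairs pooled across sessions")

    def _z(v: pd.Series) -> pd.Series:
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    if use_zscored_distance:
        df["_d"] = df.groupby("session_id")[distance_col].transform(_z)
        df["_t"] = df.groupby("session_id")["trials_between"].transform(_z)
    else:
        df["_d"] = df[distance_col]
        df["_t"] = df["trials_between"]

    t = df["_t"].to_numpy(float)
    r = df["rules_between"].to_numpy(float)
    if np.std(t) > 0 and np.std(r) > 0 and abs(np.corrcoef(t, r)[0, 1]) > 0.999:
        raise ValueError("trials_between and rules_between are collinear "
                         "(|r| > 0.999); regression is unidentifiable")
    X = pd.DataFrame({"trials_between": t, "rules_between": r,
                      "interaction": t * r})
    X = sm.add_constant(X)
    fit = sm.OLS(df["_d"].to_numpy(), X).fit()
    pvalues = {k: float(v) for k, v in fit.pvalues.items()}
    if use_zscored_distance:
        # each per-session standardisation of distance and trial gap
        # consumes two degrees of freedom (mean and scale); naive OLS df
        # understates the SEs and roughly doubles the false-positive rate
        n_sessions = df["session_id"].nunique()
        df_corr = len(df) - 2 * n_sessions - X.shape[1]
        if 2 <= df_corr < fit.df_resid:
            tvals = fit.tvalues / np.sqrt(fit.df_resid / df_corr)
            from scipy.stats import t as t_dist
            pvalues = {k: float(2.0 * t_dist.sf(abs(v), df=df_corr))
                       for k, v in tvals.items()}
    try:
        bp_p = float(het_breuschpagan(fit.resid, X.to_numpy())[1])
    except (ValueError, np.linalg.LinAlgError):
        bp_p = np.nan
    return RegressionResult(
        params={k: float(v) for k, v in fit.params.items()},
        pvalues=pvalues,
        n_pairs=len(df), distance_col=distance_col,
        r_squared=float(fit.rsquared),
        homoscedasticity_p=bp_p)


def partial_spearman(x: Sequence[float], y: Sequence[float],
                     z: Sequence[float]) -> tuple[float, float]:
    """First-order partial Spearman correlation of x and y controlling z.

    All three vectors are rank-transformed; the partial coefficient comes
    from the pairwise rank correlations, with a two-sided p-value from the
    t approximation on n - 3 degrees of freedom.
    """
    x, y, z = (np.asarray(v, float) for v in (x, y, z))
    n = len(x)
    if not (len(y) == len(z) == n) or n < 5:
        raise ValueError("x, y, z must have equal length >= 5")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.all(v == v[0]):
            raise ValueError(f"{name} is constant; partial rank correlation "
                             "undefined")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    rxy = np.corrcoef(rx, ry)[0, 1]
    rxz = np.corrcoef(rx, rz)[0, 1]
    ryz = np.corrcoef(ry, rz)[0, 1]
    denom = np.sqrt((1.0 - rxz ** 2) * (1.0 - ryz ** 2))
    if denom <= 0:
        raise ValueError("a control correlation is +-1; partial undefined")
    rho = float(np.clip((rxy - rxz * ryz) / denom, -1.0, 1.0))
    df_ = n - 3
    tstat = rho * np.sqrt(df_ / max(1.0 - rho ** 2, 1e-300))
    p = float(2.0 * stats.t.sf(abs(tstat), df=df_)) if abs(rho) < 1 else 0.0
    return rho, p


@dataclasses.dataclass
class RepeatTestResult:
    statistic: float
    p: float
    n_same: int
    n_different: int
    normalised_same: np.ndarray
    normalised_different: np.ndarray
    normalisation: str
    dropped_pairs: int


def repeated_rule_test(table: DistanceTable, distance_col: str = "euclidean",
                       normalisation: str = "stratum_mean") -> RepeatTestResult:
    """Are two blocks of the same rule closer than two different rules?

    Distances are first normalised to account for how many rules were
    presented in between: with ``stratum_mean`` each pair's distance is
    divided by the pooled mean distance of all pairs sharing its
    rules_between count; with ``regression_residual`` the residuals of an
    OLS of distance on rules_between are compared instead.  Same-rule vs
    different-rule normalised distances are compared by Wilcoxon rank-sum.
    """
    df = table.pairs.dropna(subset=[distance_col]).copy()
    same = df["same_rule_pair"].to_numpy(bool)
    if same.sum() < 1 or (~same).sum() < 1:
        raise ValueError("need at least one same-rule and one different-rule "
                         "pair")
    dropped = 0
    if normalisation == "stratum_mean":
        norm = np.full(len(df), np.nan)
        for rb, grp in df.groupby("rules_between"):
            idx = grp.index
            g_same = grp["same_rule_pair"].to_numpy(bool)
            if g_same.all():
                # a stratum with only same-rule pairs has no reference scale
                dropped += int(g_same.sum())
                warnings.warn(
                    f"rules_between={rb}: same-rule pair(s) without any "
                    "different-rule pair in the stratum; dropped")
                continue
            norm[df.index.get_indexer(idx)] = (
                grp[distance_col] / grp[distance_col].mean())
        df["_norm"] = norm
        df = df.dropna(subset=["_norm"])
    elif normalisation == "regression_residual":
        X = sm.add_constant(df["rules_between"].to_numpy(float))
        fit = sm.OLS(df[distance_col].to_numpy(), X).fit()
        df["_norm"] = fit.resid
    else:
        raise ValueError(f"unknown normalisation {normalisation!r}")

    same = df["same_rule_pair"].to_numpy(bool)
    vals_same = df.loc[same, "_norm"].to_numpy()
    vals_diff = df.loc[~same, "_norm"].to_numpy()
    if vals_same.size < 1 or vals_diff.size < 1:
        raise ValueError("normalisation left no comparable pairs")
    stat, p = stats.ranksums(vals_same, vals_diff)
    return RepeatTestResult(statistic=float(stat), p=float(p),
                            n_same=int(vals_same.size),
                            n_different=int(vals_diff.size),
                            normalised_same=vals_same,
                            normalised_different=vals_diff,
                            normalisation=normalisation,
                            dropped_pairs=dropped)
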