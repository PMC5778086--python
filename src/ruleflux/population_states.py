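"""Trial population vectors, distance primitives, and rule clustering.

Each trial is a population vector of the z-scored firing rates of all
simultaneously recorded neurons; only learning and learnt trials enter
(naive trials mostly reflect perseveration on the previous rule).  A rule
block's trials form a candidate *rule cluster*, summarised by its centre of
mass and covariance.

Two distances are used throughout: the Euclidean distance between two
population vectors, and the Mahalanobis distance between a vector and a
rule cluster, sqrt((t - RM)' S^-1 (t - RM)), with a diagonally shrunk
covariance because sessions routinely have fewer trials per rule than
neurons.

Whether trials cluster by rule is tested by K-means with k equal to the
number of rule blocks, mapping each cluster to its majority rule
(many-to-one allowed) and scoring the fraction of correctly grouped trials;
significance comes from re-clustering under random permutations of the rule
labels against the firing rates.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from sklearn.cluster import KMeans

from . import behavior
from .firing_correlates import FiringRateMatrix
from .session_io import RuleBlock

__all__ = [
    "PopulationMatrix", "RuleCluster", "ClusterEvaluation",
    "build_population_vectors", "euclidean_distance", "mahalanobis_distance",
    "cluster_by_rule", "clusters_from_labels",
]

logger = logging.getLogger("ruleflux")

SHRINKAGE_CANDIDATES = (0.1, 0.5, 1.0)
MAX_CONDITION_NUMBER = 1e6


@dataclasses.dataclass
class PopulationMatrix:
    included_trials: np.ndarray   # original trial indices (learning + learnt)
    Z: np.ndarray                 # included trials x retained neurons, z-scored
    rule_labels: np.ndarray       # block id per included trial
    neuron_ids: list[str]
    dropped_neurons: list[str]

    @property
    def n_trials(self) -> int:
        return self.Z.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.Z.shape[1]

    def blocks_present(self) -> list[int]:
        return list(dict.fromkeys(int(b) for b in self.rule_labels))


def build_population_vectors(frm: FiringRateMatrix,
                             phases: behavior.PhaseLabels,
                             rule_blocks: Sequence[RuleBlock]) -> PopulationMatrix:
    """Filter to learning+learnt trials and z-score each neuron over them.

    Neurons with zero variance over the included trials carry no geometry
    and are dropped with a logged warning.
    """
    included = phases.included()
    if len(included) != frm.n_trials:
        raise ValueError("phase labels and rate matrix cover different trials")
    idx = frm.trial_indices[included]
    if idx.size < 2:
        raise ValueError("fewer than 2 learning/learnt trials; nothing to "
                         "cluster (all trials naive?)")
    X = frm.values[included]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [nid for nid, k in zip(frm.neuron_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d constant neuron(s) from population "
                       "vectors: %s", len(dropped), ", ".join(dropped))
    Z = (X[:, keep] - mean[keep]) / sd[keep]

    labels = np.full(frm.n_trials, -1, dtype=int)
    for b in rule_blocks:
        sl = (frm.trial_indices >= b.first_trial) & (frm.trial_indices <= b.last_trial)
        labels[sl] = b.rule_id
    return PopulationMatrix(
        included_trials=idx, Z=Z, rule_labels=labels[included],
        neuron_ids=[nid for nid, k in zip(frm.neuron_ids, keep) if k],
        dropped_neurons=dropped)


def euclidean_distance(u: Sequence[float], v: Sequence[float]) -> float:
    """sqrt of the summed squared coordinate differences."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.sqrt(((u - v) ** 2).sum()))


@dataclasses.dataclass
class RuleCluster:
    block_id: int
    members: np.ndarray           # row positions into the population matrix
    centre_of_mass: np.ndarray    # per-neuron mean over member trials
    covariance: np.ndarray        # raw empirical covariance (neurons x neurons)
    shrinkage: float | None = None  # lambda actually used, set lazily

    @classmethod
    def from_members(cls, Z: np.ndarray, members: np.ndarray,
                     block_id: int = -1) -> "RuleCluster":
        members = np.asarray(members)
        if members.size < 2:
            raise ValueError("a rule cluster needs at least 2 member trials")
        pts = Z[members]
        return cls(block_id=block_id, members=members,
                   centre_of_mass=pts.mean(axis=0),
                   covariance=np.cov(pts, rowvar=False, ddof=1))

    def regularised_covariance(self) -> tuple[np.ndarray, float]:
        """Diagonal shrinkage S' = (1-l)S + l diag(S), smallest l in
        {0.1, 0.5, 1.0} with condition number below 1e6."""
        S = np.atleast_2d(self.covariance)
        d = np.diag(np.diag(S))
        for lam in SHRINKAGE_CANDIDATES:
            Sp = (1.0 - lam) * S + lam * d
            if np.all(np.diag(Sp) > 0) and np.linalg.cond(Sp) < MAX_CONDITION_NUMBER:
                self.shrinkage = lam
                return Sp, lam
        raise np.linalg.LinAlgError(
            f"cluster {self.block_id}: covariance singular even after "
            "diagonal shrinkage (a neuron with zero variance?)")


def mahalanobis_distance(t: Sequence[float], cluster: RuleCluster,
                         covariance: str = "empirical") -> float:
    """Mahalanobis distance from a trial vector to a rule cluster.

    ``covariance='identity'`` forces S to the identity, in which case the
    distance equals the Euclidean distance to the centre of mass.
    """
    t = np.asarray(t, float)
    diff = t - cluster.centre_of_mass
    if covariance == "identity":
        return float(np.sqrt(diff @ diff))
    Sp, _ = cluster.regularised_covariance()
    sol = sla.solve(Sp, diff, assume_a="pos")
    return float(np.sqrt(max(diff @ sol, 0.0)))


def clusters_from_labels(pm: PopulationMatrix) -> list[RuleCluster]:
    """One RuleCluster per block present, from the labelled member trials."""
    out = []
    for bid in pm.blocks_present():
        members = np.nonzero(pm.rule_labels == bid)[0]
        out.append(RuleCluster.from_members(pm.Z, members, block_id=bid))
    return out


# --------------------------------------------------------------------------
# K-means rule clustering with permutation accuracy test
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ClusterEvaluation:
    accuracy: float
    assignments: np.ndarray          # cluster index per included trial
    cluster_to_rule: dict[int, int]  # majority mapping (many-to-one allowed)
    null_accuracies: np.ndarray
    p_perm: float
    init: str
    distance: str
    k: int


def _majority_accuracy(assign: np.ndarray, labels: np.ndarray):
    """Map each cluster to its majority rule and score the agreement."""
    mapping: dict[int, int] = {}
    correct = 0
    for c in np.unique(assign):
        mask = assign == c
        vals, counts = np.unique(labels[mask], return_counts=True)
        best = vals[np.argmax(counts)]
        mapping[int(c)] = int(best)
        correct += int(counts.max())
    return correct / len(labels), mapping


def _kmeans_assign(Z: np.ndarray, k: int, init: str, labels: np.ndarray,
                   n_restarts: int, seed: int) -> np.ndarray:
    if init == "centre_of_mass":
        centres = np.stack([Z[labels == b].mean(axis=0)
                            for b in dict.fromkeys(labels.tolist())])
        km = KMeans(n_clusters=k, init=centres, n_init=1, algorithm="lloyd",
                    random_state=seed)
    else:
        km = KMeans(n_clusters=k, init="random", n_init=n_restarts,
                    algorithm="lloyd", random_state=seed)
    return km.fit_predict(Z)


def _mahalanobis_assign(Z: np.ndarray, k: int, init: str, labels: np.ndarray,
                        n_restarts: int, seed: int,
                        covariance: str = "empirical",
                        max_iter: int = 100) -> np.ndarray:
    """Lloyd-style iteration assigning trials to regularised rule clusters
    by Mahalanobis distance.  Empty clusters are re-seeded from the trial
    farthest from its assigned cluster; ties go to the lowest cluster index.
    """
    rng = np.random.default_rng(seed)
    m = Z.shape[0]

    def run(start_assign: np.ndarray) -> tuple[np.ndarray, float]:
        assign = start_assign.copy()
        for _ in range(max_iter):
            dists = np.empty((m, k))
            for c in range(k):
                members = np.nonzero(assign == c)[0]
                if members.size < 2:
                    # re-seed a collapsed cluster from the trial farthest
                    # from the centroid of its own assigned cluster
                    centroids = np.stack([
                        Z[assign == cc].mean(axis=0) if (assign == cc).any()
                        else Z.mean(axis=0) for cc in range(k)])
                    far = int(np.argmax(
                        ((Z - centroids[assign]) ** 2).sum(axis=1)))
                    members = np.unique([far, (far + 1) % m])
                    if members.size < 2:
                        members = np.array([0, 1])
                cl = RuleCluster.from_members(Z, members, block_id=c)
                if covariance == "identity":
                    dists[:, c] = np.sqrt(
                        ((Z - cl.centre_of_mass) ** 2).sum(axis=1))
                else:
                    Sp, _lam = cl.regularised_covariance()
                    diff = Z - cl.centre_of_mass
                    sol = sla.solve(Sp, diff.T, assume_a="pos").T
                    dists[:, c] = np.sqrt(np.maximum((diff * sol).sum(axis=1),
                                                     0.0))
            new_assign = np.argmin(dists, axis=1)  # argmin takes lowest index on ties
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
        score = float(dists[np.arange(m), assign].sum())
        return assign, score

    if init == "centre_of_mass":
        start = np.searchsorted(np.unique(labels), labels)
        assign, _ = run(start)
        return assign
    best_assign, best_score = None, np.inf
    for _ in range(max(1, n_restarts)):
        start = rng.integers(0, k, size=m)
        assign, score = run(start)
        if score < best_score:
            best_assign, best_score = assign, score
    return best_assign


def cluster_by_rule(pm: PopulationMatrix, k: int | None = None,
                    init: str = "random_restarts",
                    distance: str = "euclidean",
                    n_perm: int = 1000, seed: int = 0,
                    n_restarts: int = 100,
                    covariance: str = "empirical") -> ClusterEvaluation:
    """Cluster included trials into k rule clusters and score rule recovery.

    ``k`` defaults to the number of rule blocks among the included trials
    (a repeated rule's two blocks count separately).  The permutation null
    shuffles the rule labels against the firing-rate rows and re-clusters
    identically; p_perm = (1 + #{null >= observed}) / (1 + n_perm).
    """
    labels = pm.rule_labels
    if k is None:
        k = len(pm.blocks_present())
    if k < 1 or k > pm.n_trials:
        raise ValueError(f"k={k} incompatible with {pm.n_trials} trials")
    if init not in ("random_restarts", "centre_of_mass"):
        raise ValueError(f"unknown init {init!r}")
    if distance not in ("euclidean", "mahalanobis"):
        raise ValueError(f"unknown distance {distance!r}")

    assigner = _kmeans_assign if distance == "euclidean" else _mahalanobis_assign
    kwargs = {} if distance == "euclidean" else {"covariance": covariance}

    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=n_perm + 1)
    assign = assigner(pm.Z, k, init, labels, n_restarts, int(sub[0]), **kwargs)
    accuracy, mapping = _majority_accuracy(assign, labels)

    null = np.empty(n_perm)
    for s in range(n_perm):
        perm_labels = rng.permutation(labels)
        a = assigner(pm.Z, k, init, perm_labels, n_restarts,
                     int(sub[s + 1]), **kwargs)
        null[s], _ = _majority_accuracy(a, perm_labels)
    p_perm = (1.0 + float((null >= accuracy).sum())) / (1.0 + n_perm)
    return ClusterEvaluation(accuracy=accuracy, assignments=assign,
                             cluster_to_rule=mapping, null_accuracies=null,
                             p_perm=p_perm, init=init, distance=distance, k=k)
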