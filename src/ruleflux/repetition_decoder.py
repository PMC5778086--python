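"""Does a repeated rule re-enter its original population state?

Protocol: pick the first presentation of a rule ('A') and its later
repetition ('A°').  Train a linear classifier on a random 70% of A's trials
(labelled 1) against the trials of all other rules (labelled 0) — A° never
enters training.  Test on the held-out 30% of A and, separately, on A°.
The reported accuracy of each test subset is the fraction of its trials
classified as belonging to A.  Because the 70/30 split is random, the whole
procedure is repeated (1000 times by default) and the two accuracy
distributions are compared.

If the repetition re-used the original state, A° would be classified like
held-out A; if it forms a new state, A° accuracy collapses while held-out A
accuracy stays high.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .population_states import PopulationMatrix
from .session_io import RuleBlock

__all__ = ["DecoderResult", "decode_rule_repetition"]

logger = logging.getLogger("ruleflux")

TRAIN_FRACTION = 0.7


@dataclasses.dataclass
class DecoderResult:
    accuracy_on_A_holdout: np.ndarray  # per repetition
    accuracy_on_Arep: np.ndarray
    kind: str
    n_reps: int          # repetitions that converged
    n_dropped: int
    seed: int
    degenerate: bool
    ranksum_statistic: float
    ranksum_p: float

    @property
    def median_A(self) -> float:
        return float(np.median(self.accuracy_on_A_holdout))

    @property
    def median_Arep(self) -> float:
        return float(np.median(self.accuracy_on_Arep))


def _make_classifier(kind: str):
    if kind == "logistic":
        # near-unpenalised fit; the tiny ridge only stabilises separable data
        return LogisticRegression(C=1e4, class_weight="balanced",
                                  solver="lbfgs", max_iter=2000)
    if kind == "linear_svm":
        return LinearSVC(C=1.0, class_weight="balanced", max_iter=5000)
    raise ValueError(f"unknown classifier kind {kind!r}")


def _block_id(block) -> int:
    return block.rule_id if isinstance(block, RuleBlock) else int(block)


def decode_rule_repetition(pm: PopulationMatrix, block_A, block_Arep,
                           kind: str = "logistic", n_reps: int = 1000,
                           seed: int = 0) -> DecoderResult:
    """Train A-vs-others (excluding A°), test on held-out A and on A°.

    ``block_A``/``block_Arep`` are RuleBlock objects (checked to share a
    rule name) or block ids.  Returns per-repetition fractions of test
    trials labelled as A, plus a rank-sum comparison of the two accuracy
    distributions.  Non-converging repetitions are dropped and counted.
    """
    if isinstance(block_A, RuleBlock) and isinstance(block_Arep, RuleBlock):
        if block_A.rule_name != block_Arep.rule_name:
            raise ValueError("block_A and block_Arep must share a rule name")
    a_id, rep_id = _block_id(block_A), _block_id(block_Arep)
    labels = pm.rule_labels
    rows_A = np.nonzero(labels == a_id)[0]
    rows_rep = np.nonzero(labels == rep_id)[0]
    rows_other = np.nonzero((labels != a_id) & (labels != rep_id))[0]
    if rows_A.size < 4:
        raise ValueError(f"rule block {a_id} has {rows_A.size} included "
                         "trials; need at least 4")
    if rows_rep.size < 1 or rows_other.size < 1:
        raise ValueError("need trials in the repetition block and in at "
                         "least one other rule")

    Z = pm.Z
    degenerate = bool(np.allclose(Z, Z[0]))
    rng = np.random.default_rng(seed)
    n_train = max(2, int(round(TRAIN_FRACTION * rows_A.size)))
    if n_train >= rows_A.size:
        n_train = rows_A.size - 1

    acc_A, acc_rep = [], []
    n_dropped = 0
    for _ in range(n_reps):
        picked = rng.choice(rows_A.size, size=n_train, replace=False)
        mask = np.zeros(rows_A.size, dtype=bool)
        mask[picked] = True
        train_rows = np.concatenate([rows_A[mask], rows_other])
        y_train = np.concatenate([np.ones(mask.sum(), int),
                                  np.zeros(rows_other.size, int)])
        test_A = rows_A[~mask]
        if degenerate:
            # identical vectors: the classifier output is a constant label
            const = int(np.bincount(y_train).argmax())
            acc_A.append(float(const))
            acc_rep.append(float(const))
            continue
        clf = _make_classifier(kind)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                clf.fit(Z[train_rows], y_train)
            except ConvergenceWarning:
                n_dropped += 1
                continue
        acc_A.append(float(np.mean(clf.predict(Z[test_A]) == 1)))
        acc_rep.append(float(np.mean(clf.predict(Z[rows_rep]) == 1)))
    if n_dropped:
        logger.warning("decoder (%s): dropped %d of %d repetitions for "
                       "non-convergence", kind, n_dropped, n_reps)
    acc_A = np.asarray(acc_A)
    acc_rep = np.asarray(acc_rep)
    if acc_A.size and not (np.all(acc_A == acc_A[0]) and
                           np.all(acc_rep == acc_rep[0]) and
                           acc_A[0] == acc_rep[0]):
        stat, p = stats.ranksums(acc_A, acc_rep)
    else:
        stat, p = 0.0, 1.0
    return DecoderResult(accuracy_on_A_holdout=acc_A,
                         accuracy_on_Arep=acc_rep, kind=kind,
                         n_reps=int(acc_A.size), n_dropped=n_dropped,
                         seed=seed, degenerate=degenerate,
                         ranksum_statistic=float(stat), ranksum_p=float(p))
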