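"""Segment firing rates and their correlation with task performance.

Each trial is split into non-overlapping behavioural segments — run (start
of movement to the reward-sensor crossing), reward (a fixed 2 s window from
the crossing), inter-trial (end of the reward window to the start of the
next run) — plus the entire trial (trial start to the start of the next
trial).  A neuron's per-trial rate is its spike count in the segment divided
by the segment duration.

Rates are correlated with the estimated performance curve by Spearman rank
correlation, with Bonferroni-Holm control over the neuron family within a
segment.  Two bespoke nulls accompany the correlations:

* the *shuffled-performance* null rearranges trial order jointly for rates
  and outcomes, re-estimates the performance curve on the shuffled outcome
  sequence and re-correlates: a neuron that merely echoes the same-trial
  outcome keeps its correlation under this null, whereas a neuron tracking
  the integrated learning state loses it;
* a chi-square enrichment test asks whether high-rate neurons (>= 10 Hz,
  enriched for putative fast-spiking interneurons) are over-represented
  among the significantly correlated ones, and among the negative ones.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import behavior, session_io
from .session_io import REWARD_DURATION_S, Session

__all__ = [
    "FiringRateMatrix", "CorrelationTable", "ShuffleNull", "EnrichmentResult",
    "compute_segment_rates", "performance_correlations",
    "shuffled_performance_null", "rate_group_enrichment", "spearman_columns",
]

RATE_GROUP_THRESHOLD_HZ = 10.0


@dataclasses.dataclass
class FiringRateMatrix:
    segment: str
    values: np.ndarray            # trials x neurons, Hz
    segment_durations: np.ndarray  # per-trial seconds
    neuron_ids: list[str]
    trial_indices: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    def subset(self, mask: np.ndarray) -> "FiringRateMatrix":
        mask = np.asarray(mask)
        return FiringRateMatrix(self.segment, self.values[mask],
                                self.segment_durations[mask], self.neuron_ids,
                                self.trial_indices[mask])


def _segment_interval(session: Session, i: int, segment: str) -> tuple[float, float]:
    t = session.trials[i]
    nxt = session.trials[i + 1] if i + 1 < session.n_trials else None
    if segment == "run":
        return t.t_run_start, t.t_reward_cross
    if segment == "reward":
        return t.t_reward_cross, t.t_reward_cross + REWARD_DURATION_S
    if segment == "inter_trial":
        end = nxt.t_run_start if nxt is not None else t.t_trial_end
        return t.t_reward_cross + REWARD_DURATION_S, end
    if segment == "entire_trial":
        end = nxt.t_trial_start if nxt is not None else t.t_trial_end
        return t.t_trial_start, end
    raise ValueError(f"unknown segment {segment!r}")


def compute_segment_rates(session: Session, segment: str) -> FiringRateMatrix:
    """Spike count in the segment interval over the segment duration, per
    trial and neuron.  Spikes outside every trial belong to no segment."""
    m = session.n_trials
    ids = [n.neuron_id for n in session.neurons]
    values = np.zeros((m, len(ids)))
    durations = np.empty(m)
    for i in range(m):
        t0, t1 = _segment_interval(session, i, segment)
        dur = t1 - t0
        if dur <= 0:
            raise ValueError(
                f"trial {session.trials[i].index}: zero-duration "
                f"{segment} segment")
        durations[i] = dur
        for j, nid in enumerate(ids):
            times = session.spikes.get(nid)
            if times is not None and times.size:
                values[i, j] = session_io.spikes_in_interval(times, t0, t1) / dur
    return FiringRateMatrix(segment=segment, values=values,
                            segment_durations=durations, neuron_ids=ids,
                            trial_indices=np.arange(m))


# --------------------------------------------------------------------------
# Spearman correlation against the performance curve
# --------------------------------------------------------------------------

def spearman_columns(X: np.ndarray, y: np.ndarray):
    """Spearman rho and two-sided p for each column of X against y.

    Vectorised rank correlation with the t approximation (the scipy default
    for n > 2); constant columns yield NaN.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    m = len(y)
    rx = np.apply_along_axis(stats.rankdata, 0, X)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean(axis=0)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum(axis=0) * (ry_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rx_c * ry_c[:, None]).sum(axis=0) / denom,
                       np.nan)
        rho = np.clip(rho, -1.0, 1.0)
        tstat = rho * np.sqrt((m - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=m - 2)
    p = np.where(np.isnan(rho), np.nan, np.where(np.abs(rho) >= 1.0, 0.0, p))
    return rho, p


@dataclasses.dataclass
class CorrelationTable:
    segment: str
    alpha: float
    table: pd.DataFrame  # neuron, rho, p_raw, holm_significant, sign

    @property
    def n_significant(self) -> int:
        return int(self.table["holm_significant"].sum())


def performance_correlations(frm: FiringRateMatrix,
                             curve: behavior.PerformanceCurve,
                             alpha: float = 0.05) -> CorrelationTable:
    """Per-neuron Spearman rho against the performance estimate, with
    Bonferroni-Holm step-down over the neuron family of this segment.

    Constant-rate neurons have undefined rho; they are flagged (NaN) and
    excluded from the Holm family.
    """
    if frm.n_trials != curve.n_trials:
        raise ValueError("rate matrix and performance curve cover different "
                         f"trial counts ({frm.n_trials} vs {curve.n_trials})")
    rho, p_raw = spearman_columns(frm.values, curve.p_mode)
    ok = ~np.isnan(rho)
    holm = np.zeros(frm.n_neurons, dtype=bool)
    if ok.sum():
        holm[ok] = multipletests(p_raw[ok], alpha=alpha, method="holm")[0]
    sign = np.where(holm & (rho > 0), "pos",
                    np.where(holm & (rho < 0), "neg", "none"))
    table = pd.DataFrame({
        "neuron": frm.neuron_ids,
        "rho": rho,
        "p_raw": p_raw,
        "holm_significant": holm,
        "sign": sign,
    })
    return CorrelationTable(segment=frm.segment, alpha=alpha, table=table)


# --------------------------------------------------------------------------
# Shuffled-performance null
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ShuffleNull:
    segment: str
    n_shuffles: int
    observed_rho: np.ndarray          # per neuron
    null_rho: np.ndarray              # n_shuffles x neurons
    band_lo: np.ndarray               # per-neuron 2.5th percentile
    band_hi: np.ndarray               # per-neuron 97.5th percentile
    ks_statistic: float
    ks_p: float

    def outside_band(self) -> np.ndarray:
        return (self.observed_rho < self.band_lo) | (self.observed_rho > self.band_hi)


def shuffled_performance_null(frm: FiringRateMatrix, outcomes: Sequence[int],
                              n_shuffles: int = 1000, seed: int = 0,
                              background_p: float = 0.5,
                              curve: behavior.PerformanceCurve | None = None) -> ShuffleNull:
    """Re-estimate the performance curve on jointly shuffled trials.

    Each shuffle permutes trial order for the rate matrix and the outcome
    vector together (the multiset of (rate row, outcome) pairs is preserved
    and asserted), recomputes the performance curve from the shuffled
    outcome sequence, and re-correlates.  Bands are per-neuron 2.5/97.5
    percentiles of the null rho; the Kolmogorov-Smirnov statistic compares
    the observed rho distribution across neurons with the pooled null.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    y = np.asarray(outcomes, dtype=int)
    X = frm.values
    if len(y) != frm.n_trials:
        raise ValueError("outcomes length must match the rate matrix")
    # any object with .permutation works (lets tests force degenerate draws)
    rng = seed if hasattr(seed, "permutation") else np.random.default_rng(seed)
    if curve is None:
        curve = behavior.estimate_performance(y, background_p=background_p)
    observed_rho, _ = spearman_columns(X, curve.p_mode)

    pair_key = np.lexsort((y, X.sum(axis=1)))
    ref_pairs = np.column_stack([X.sum(axis=1), y])[pair_key]
    null = np.empty((n_shuffles, frm.n_neurons))
    for s in range(n_shuffles):
        perm = rng.permutation(len(y))
        Xs, ys = X[perm], y[perm]
        key = np.lexsort((ys, Xs.sum(axis=1)))
        assert np.allclose(np.column_stack([Xs.sum(axis=1), ys])[key],
                           ref_pairs), "shuffle must preserve (rate, outcome) pairs"
        shuf_curve = behavior.estimate_performance(ys, background_p=background_p)
        null[s], _ = spearman_columns(Xs, shuf_curve.p_mode)

    band_lo = np.nanpercentile(null, 2.5, axis=0)
    band_hi = np.nanpercentile(null, 97.5, axis=0)
    obs_ok = observed_rho[~np.isnan(observed_rho)]
    pooled = null[~np.isnan(null)]
    ks = stats.ks_2samp(obs_ok, pooled.ravel())
    return ShuffleNull(segment=frm.segment, n_shuffles=n_shuffles,
                       observed_rho=observed_rho, null_rho=null,
                       band_lo=band_lo, band_hi=band_hi,
                       ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue))


# --------------------------------------------------------------------------
# 10 Hz rate-group enrichment
# --------------------------------------------------------------------------

@dataclasses.dataclass
class EnrichmentResult:
    threshold_hz: float
    counts: np.ndarray              # 2x2: [high, low] x [significant, not]
    chi2: float
    p: float
    ratio_high: float               # observed / expected significant, >= thr
    ratio_low: float
    sign_counts: np.ndarray | None  # [high, low] x [pos, neg] among significant
    sign_chi2: float | None
    sign_p: float | None


def _chi2_2x2(counts: np.ndarray) -> tuple[float, float]:
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        return 0.0, 1.0  # a degenerate margin carries no association
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), float(p)


def rate_group_enrichment(corr_table: CorrelationTable,
                          neuron_rates: Sequence[float],
                          threshold_hz: float = RATE_GROUP_THRESHOLD_HZ) -> EnrichmentResult:
    """Chi-square enrichment of significant correlations in the >= 10 Hz group.

    ``neuron_rates`` are session-mean rates in the order of the correlation
    table.  Also tests, among significant neurons, whether the high-rate
    group is enriched for negative correlations.
    """
    rates = np.asarray(neuron_rates, float)
    tab = corr_table.table
    if len(rates) != len(tab):
        raise ValueError("neuron_rates must match the correlation table")
    high = rates >= threshold_hz
    sig = tab["holm_significant"].to_numpy()
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("need at least 2 neurons in each rate group")
    counts = np.array([
        [int((high & sig).sum()), int((high & ~sig).sum())],
        [int((~high & sig).sum()), int((~high & ~sig).sum())],
    ])
    chi2, p = _chi2_2x2(counts)
    total_sig = sig.sum()
    exp_high = counts[0].sum() * total_sig / len(rates) if total_sig else np.nan
    exp_low = counts[1].sum() * total_sig / len(rates) if total_sig else np.nan
    ratio_high = counts[0, 0] / exp_high if total_sig else np.nan
    ratio_low = counts[1, 0] / exp_low if total_sig else np.nan

    sign_counts = sign_chi2 = sign_p = None
    signs = tab["sign"].to_numpy()
    sc = np.array([
        [int((high & (signs == "pos")).sum()), int((high & (signs == "neg")).sum())],
        [int((~high & (signs == "pos")).sum()), int((~high & (signs == "neg")).sum())],
    ])
    if sc.sum(axis=1).min() > 0 and sc.sum(axis=0).min() > 0:
        sign_counts = sc
        sign_chi2, sign_p = _chi2_2x2(sc)
    return EnrichmentResult(threshold_hz=threshold_hz, counts=counts,
                            chi2=chi2, p=p, ratio_high=float(ratio_high),
                            ratio_low=float(ratio_low),
                            sign_counts=sign_counts, sign_chi2=sign_chi2,
                            sign_p=sign_p)
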