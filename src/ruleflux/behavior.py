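"""Rule bookkeeping and behavioural learning-state estimation.

The task: a rat starts from the North or South arm of a plus maze and must
choose the East or West goal arm.  Four rules are possible — two allocentric
(``go_east``, ``go_west``: go to a fixed goal arm regardless of start) and
two egocentric (``go_right``, ``go_left``: turn to the animal's own side).
Maze geometry fixes the egocentric mapping: heading from the North arm
toward the centre the animal faces South, so East is on its *left*; from the
South arm, East is on its *right*.

Whenever the animal makes 13 correct choices within the last 15 trials of
the current rule, the rule changes unannounced.

Per-trial performance is estimated with a Bernoulli state-space model: a
latent learning state follows a Gaussian random walk,

    x_t = x_{t-1} + eps_t,   eps_t ~ N(0, sigma_eps^2),

and each outcome is Bernoulli with logit(p_t) = x_t + logit(background_p).
The random-walk variance is estimated by maximising the Gaussian-filter
approximate marginal likelihood (the initial state profiled out); the
per-trial estimate and equal-tailed credible interval come from Gaussian
expectation-propagation smoothing of the latent chain, mapped through the
logistic.  A Metropolis sampler over the latent path is provided as an
independent cross-check of the smoother.

Behavioural phases are assigned per trial by thresholding the lower credible
bound of the ongoing rule's curve: naive below 0.1 after a reversal (0.3
after a switch), learnt above 0.6, learning in between.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np

try:  # jit the per-trial recursions; fall back to pure Python if unavailable
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "recode_outcomes", "apply_rule_change_criterion", "estimate_performance",
    "assign_phases", "estimate_rule_curves", "session_phases",
    "PerformanceCurve", "PhaseLabels", "metropolis_curve",
    "NAIVE_THRESHOLDS", "LEARNT_THRESHOLD",
]

# left/right goal arm as seen by the animal, by start arm (see module docstring)
_LEFT_OF = {"N": "E", "S": "W"}
_RIGHT_OF = {"N": "W", "S": "E"}

NAIVE_THRESHOLDS = {"reversal": 0.1, "switch": 0.3, "session_start": 0.3}
LEARNT_THRESHOLD = 0.6

CRITERION_CORRECT = 13
CRITERION_WINDOW = 15


def recode_outcomes(start_arms: Sequence[str], chosen_arms: Sequence[str],
                    rule_name: str) -> np.ndarray:
    """Correctness of each (start, choice) pair had ``rule_name`` been active.

    Returns a binary int array.  Raises ValueError for an unknown rule.
    """
    start = np.asarray(start_arms, dtype=object)
    chosen = np.asarray(chosen_arms, dtype=object)
    if start.shape != chosen.shape:
        raise ValueError("start_arms and chosen_arms must have equal length")
    if rule_name == "go_east":
        correct = chosen == "E"
    elif rule_name == "go_west":
        correct = chosen == "W"
    elif rule_name == "go_right":
        correct = chosen == np.vectorize(_RIGHT_OF.__getitem__)(start) \
            if start.size else np.zeros(0, dtype=bool)
    elif rule_name == "go_left":
        correct = chosen == np.vectorize(_LEFT_OF.__getitem__)(start) \
            if start.size else np.zeros(0, dtype=bool)
    else:
        raise ValueError(f"unknown rule_name: {rule_name!r}")
    return np.asarray(correct, dtype=int)


def apply_rule_change_criterion(outcomes: Sequence[int]) -> int | None:
    """First trial index at which 13-of-the-last-15 correct is reached.

    ``outcomes`` are the binary outcomes since the start of the current rule
    block.  The criterion is evaluated on a sliding window of the last
    ``min(15, t)`` trials and can fire from the 13th block trial onward.
    Returns the 0-based index of the triggering trial, or None.
    """
    y = np.asarray(outcomes, dtype=int)
    if y.ndim != 1:
        raise ValueError("outcomes must be a 1-D binary vector")
    csum = np.concatenate([[0], np.cumsum(y)])
    for t in range(CRITERION_CORRECT - 1, len(y)):
        lo = max(0, t + 1 - CRITERION_WINDOW)
        if csum[t + 1] - csum[lo] >= CRITERION_CORRECT:
            return t
    return None


# --------------------------------------------------------------------------
# Bernoulli random-walk state-space model (EM + Gaussian smoother)
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PerformanceCurve:
    """Per-trial estimated probability of a correct choice with bounds."""
    p_mode: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    sigma_eps_sq: float
    background_p: float = 0.5
    ci_level: float = 0.90
    x_mode: np.ndarray | None = None
    x_var: np.ndarray | None = None
    x0: float = 0.0
    converged: bool = True
    n_iter: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.p_mode)


@njit(cache=False)
def _forward_backward(y, mu, x0, s2):  # pragma: no cover - exercised via wrapper
    T = y.shape[0]
    xf = np.empty(T); vf = np.empty(T)
    xp = np.empty(T); vp = np.empty(T)
    xprev = x0
    vprev = 0.0
    for t in range(T):
        xpred = xprev
        vpred = vprev + s2
        x = xpred
        for _ in range(12):  # Newton on the filter posterior mode
            p = 1.0 / (1.0 + math.exp(-(x + mu)))
            g = x - xpred - vpred * (y[t] - p)
            gp = 1.0 + vpred * p * (1.0 - p)
            step = g / gp
            x -= step
            if abs(step) < 1e-12:
                break
        p = 1.0 / (1.0 + math.exp(-(x + mu)))
        xf[t] = x
        vf[t] = 1.0 / (1.0 / vpred + p * (1.0 - p))
        xp[t] = xpred
        vp[t] = vpred
        xprev = x
        vprev = vf[t]

    xs = np.empty(T); vs = np.empty(T); cs = np.zeros(T)
    xs[T - 1] = xf[T - 1]
    vs[T - 1] = vf[T - 1]
    for t in range(T - 2, -1, -1):
        A = vf[t] / vp[t + 1]
        xs[t] = xf[t] + A * (xs[t + 1] - xp[t + 1])
        vs[t] = vf[t] + A * A * (vs[t + 1] - vp[t + 1])
        cs[t + 1] = A * vs[t + 1]
    return xs, vs, cs


@njit(cache=False)
def _filter_loglik(y, mu, x0, s2):  # pragma: no cover - via wrapper
    """Approximate marginal log-likelihood from the Gaussian forward filter.

    The Bernoulli predictive under a Gaussian state prior is approximated
    with the probit-style moderation E[sigmoid(z)] ~ sigmoid(m/sqrt(1+pi*v/8)).
    """
    T = y.shape[0]
    ll = 0.0
    xprev = x0
    vprev = 0.0
    for t in range(T):
        xpred = xprev
        vpred = vprev + s2
        moderated = (xpred + mu) / math.sqrt(1.0 + math.pi * vpred / 8.0)
        p_pred = 1.0 / (1.0 + math.exp(-moderated))
        p_pred = min(max(p_pred, 1e-12), 1.0 - 1e-12)
        ll += y[t] * math.log(p_pred) + (1.0 - y[t]) * math.log(1.0 - p_pred)
        x = xpred
        for _ in range(12):
            p = 1.0 / (1.0 + math.exp(-(x + mu)))
            g = x - xpred - vpred * (y[t] - p)
            gp = 1.0 + vpred * p * (1.0 - p)
            step = g / gp
            x -= step
            if abs(step) < 1e-12:
                break
        p = 1.0 / (1.0 + math.exp(-(x + mu)))
        xprev = x
        vprev = 1.0 / (1.0 / vpred + p * (1.0 - p))
    return ll


# Search bounds for the random-walk variance, acting as a weakly
# informative prior.  Lower bound: >= 0.1 logit units of drift per trial —
# the marginal likelihood is nearly flat in sigma^2 for unremarkable
# outcome sequences and an unbounded maximiser collapses to 0, which
# over-smooths and makes the credible intervals badly anti-conservative.
# Upper bound: 1 logit unit of drift per trial already allows learning
# within a single trial; beyond it the latent path is unidentifiable.
_S2_BOUNDS = (1e-2, 1.0)

# probabilists' Gauss-Hermite rule for 1-D Bernoulli moment matching
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(31)


@njit(cache=False)
def _kalman_chain(x0, s2, tau, nu):  # pragma: no cover - via wrapper
    """Gaussian smoother for the random-walk chain with Gaussian
    pseudo-observations given in natural parameters (tau, nu)."""
    T = tau.shape[0]
    xf = np.empty(T); vf = np.empty(T)
    xp = np.empty(T); vp = np.empty(T)
    xprev = x0
    vprev = 0.0
    for t in range(T):
        xpred = xprev
        vpred = vprev + s2
        v = 1.0 / (1.0 / vpred + tau[t])
        m = v * (xpred / vpred + nu[t])
        xf[t] = m; vf[t] = v; xp[t] = xpred; vp[t] = vpred
        xprev = m; vprev = v
    xs = np.empty(T); vs = np.empty(T)
    xs[T - 1] = xf[T - 1]
    vs[T - 1] = vf[T - 1]
    for t in range(T - 2, -1, -1):
        A = vf[t] / vp[t + 1]
        xs[t] = xf[t] + A * (xs[t + 1] - xp[t + 1])
        vs[t] = vf[t] + A * A * (vs[t + 1] - vp[t + 1])
    return xs, vs


@njit(cache=False)
def _ep_smooth(y, mu, x0, s2, gh_x, gh_w, n_sweeps=50, damp=0.7,
               tol=1e-9):  # pragma: no cover - via wrapper
    """Expectation propagation over the chain: Gaussian site per trial,
    moment-matched against the Bernoulli likelihood by quadrature.

    For this log-concave model EP marginal means agree with dense-grid
    integration to ~1e-3 on the probability scale.
    """
    T = y.shape[0]
    tau = np.zeros(T)
    nu = np.zeros(T)
    xs, vs = _kalman_chain(x0, s2, tau, nu)
    for _ in range(n_sweeps):
        max_change = 0.0
        for t in range(T):
            cav_p = 1.0 / vs[t] - tau[t]
            if cav_p < 1e-8:
                continue
            cav_m = (xs[t] / vs[t] - nu[t]) / cav_p
            sd = math.sqrt(1.0 / cav_p)
            Z = 0.0; m1 = 0.0; m2 = 0.0
            for i in range(gh_x.shape[0]):
                z = cav_m + sd * gh_x[i]
                p = 1.0 / (1.0 + math.exp(-(z + mu)))
                lik = p if y[t] == 1.0 else 1.0 - p
                w = gh_w[i] * lik
                Z += w; m1 += w * z; m2 += w * z * z
            m = m1 / Z
            v = m2 / Z - m * m
            tau_new = 1.0 / v - cav_p
            if tau_new < 0.0:
                tau_new = 0.0
            nu_new = m / v - cav_m * cav_p
            d1 = abs(tau_new - tau[t]); d2 = abs(nu_new - nu[t])
            if d1 > max_change:
                max_change = d1
            if d2 > max_change:
                max_change = d2
            tau[t] = damp * tau_new + (1.0 - damp) * tau[t]
            nu[t] = damp * nu_new + (1.0 - damp) * nu[t]
        xs, vs = _kalman_chain(x0, s2, tau, nu)
        if max_change < tol:
            break
    return xs, vs


def _profiled_x0(y, mu, s2, n_iter=4):
    x0 = 0.0
    for _ in range(n_iter):
        xs, _, _ = _forward_backward(y, mu, x0, s2)
        if abs(xs[0] - x0) < 1e-8:
            return float(xs[0])
        x0 = float(xs[0])
    return x0


def _fit_walk_variance(y, mu, max_iter, tol):
    """Maximise the approximate marginal likelihood over the random-walk
    variance (Brent on log sigma^2, initial state profiled)."""
    from scipy.optimize import minimize_scalar

    def neg_ll(log_s2: float) -> float:
        s2 = math.exp(log_s2)
        x0 = _profiled_x0(y, mu, s2)
        return -_filter_loglik(y, mu, x0, s2)

    res = minimize_scalar(neg_ll, bounds=(math.log(_S2_BOUNDS[0]),
                                          math.log(_S2_BOUNDS[1])),
                          method="bounded",
                          options={"xatol": tol, "maxiter": max_iter})
    s2 = float(math.exp(res.x))
    x0 = _profiled_x0(y, mu, s2)
    xs, vs = _ep_smooth(y, mu, x0, s2, _GH_X, _GH_W)
    return xs, vs, s2, x0, int(res.nfev), bool(res.success)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def estimate_performance(outcomes: Sequence[int],
                         background_p: float = 0.5,
                         ci_level: float = 0.90,
                         sigma_eps_sq: float | None = None,
                         max_iter: int = 200,
                         tol: float = 1e-4) -> PerformanceCurve:
    """Fit the Bernoulli random-walk model and return the performance curve.

    ``sigma_eps_sq=None`` estimates the random-walk variance by maximum
    marginal likelihood; a fixed value skips the estimation (0 collapses to
    the constant-probability limit).
    The credible interval is equal-tailed at ``ci_level`` (default 90%, so
    the lower bound is the 5th percentile of the posterior).
    """
    y = np.asarray(outcomes, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("need a 1-D outcome vector with at least 5 trials")
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("outcomes must be binary (0/1)")
    if not (0.0 < background_p < 1.0):
        raise ValueError("background_p must be in (0, 1)")
    mu = _logit(background_p)
    from scipy.stats import norm
    z = norm.ppf(0.5 + ci_level / 2.0)
    T = y.size

    if sigma_eps_sq is not None and sigma_eps_sq == 0.0:
        # degenerate limit: the random walk collapses to a constant state
        m = float(np.clip(y.mean(), 0.5 / T, 1.0 - 0.5 / T))
        x = _logit(m) - mu
        var = 1.0 / (T * m * (1.0 - m))
        xs = np.full(T, x)
        vs = np.full(T, var)
        s2_hat, x0, n_iter, conv = 0.0, x, 0, True
    elif sigma_eps_sq is not None:
        x0 = _profiled_x0(y, mu, float(sigma_eps_sq))
        xs, vs = _ep_smooth(y, mu, x0, float(sigma_eps_sq), _GH_X, _GH_W)
        s2_hat, n_iter, conv = float(sigma_eps_sq), 0, True
    else:
        xs, vs, s2_hat, x0, n_iter, conv = _fit_walk_variance(y, mu, max_iter,
                                                              tol)
        if not conv:
            warnings.warn(
                "state-space likelihood maximisation did not converge "
                f"within {max_iter} evaluations; returning last iterate",
                RuntimeWarning)

    p_mode = _logistic(xs + mu)
    sd = np.sqrt(np.maximum(vs, 0.0))
    return PerformanceCurve(
        p_mode=p_mode,
        ci_lower=_logistic(xs - z * sd + mu),
        ci_upper=_logistic(xs + z * sd + mu),
        sigma_eps_sq=float(s2_hat),
        background_p=background_p,
        ci_level=ci_level,
        x_mode=np.asarray(xs, dtype=float),
        x_var=np.asarray(vs, dtype=float),
        x0=float(x0),
        converged=bool(conv),
        n_iter=int(n_iter),
    )


@njit(cache=False)
def _metropolis_paths(y, mu, x0, s2, n_sweeps, burn_in, step, seed):  # pragma: no cover
    T = y.shape[0]
    np.random.seed(seed)
    x = np.full(T, x0)
    n_keep = n_sweeps - burn_in
    kept = np.empty((n_keep, T))
    for sweep in range(n_sweeps):
        for t in range(T):
            cur = x[t]
            prop = cur + step * np.random.normal()
            prev = x0 if t == 0 else x[t - 1]
            # log target: random-walk prior terms + Bernoulli likelihood
            lp_new = -0.5 * (prop - prev) ** 2 / s2
            lp_old = -0.5 * (cur - prev) ** 2 / s2
            if t + 1 < T:
                lp_new += -0.5 * (x[t + 1] - prop) ** 2 / s2
                lp_old += -0.5 * (x[t + 1] - cur) ** 2 / s2
            p_new = 1.0 / (1.0 + math.exp(-(prop + mu)))
            p_old = 1.0 / (1.0 + math.exp(-(cur + mu)))
            lp_new += y[t] * math.log(p_new) + (1.0 - y[t]) * math.log(1.0 - p_new)
            lp_old += y[t] * math.log(p_old) + (1.0 - y[t]) * math.log(1.0 - p_old)
            if math.log(np.random.random() + 1e-300) < lp_new - lp_old:
                x[t] = prop
        if sweep >= burn_in:
            kept[sweep - burn_in] = x
    return kept


def metropolis_curve(outcomes: Sequence[int], background_p: float = 0.5,
                     sigma_eps_sq: float | None = None, x0: float | None = None,
                     n_sweeps: int = 4000, burn_in: int = 1000,
                     step: float = 0.4, seed: int = 0) -> np.ndarray:
    """Posterior-mean performance curve from a single-site Metropolis sampler.

    Independent cross-check of the Gaussian-approximation smoother.  When
    sigma_eps_sq / x0 are omitted they are taken from a full fit so that
    both routes smooth under the same model parameters.
    """
    y = np.asarray(outcomes, dtype=float)
    if sigma_eps_sq is None or x0 is None:
        fit = estimate_performance(y, background_p=background_p)
        sigma_eps_sq = fit.sigma_eps_sq if sigma_eps_sq is None else sigma_eps_sq
        x0 = fit.x0 if x0 is None else x0
    mu = _logit(background_p)
    paths = _metropolis_paths(y, mu, float(x0), float(sigma_eps_sq),
                              int(n_sweeps), int(burn_in), float(step),
                              int(seed))
    return _logistic(paths + mu).mean(axis=0)


# --------------------------------------------------------------------------
# Behavioural phases
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PhaseLabels:
    labels: np.ndarray  # per-trial: naive | learning | learnt
    naive_thresholds: Mapping[str, float]
    learnt_threshold: float

    def included(self) -> np.ndarray:
        """Boolean mask of learning + learnt trials (naive excluded)."""
        return self.labels != "naive"


def label_phase(ci_lower: float, change_type: str,
                naive_thresholds: Mapping[str, float] = NAIVE_THRESHOLDS,
                learnt_threshold: float = LEARNT_THRESHOLD) -> str:
    thr = naive_thresholds[change_type]
    if ci_lower < thr:
        return "naive"
    if ci_lower > learnt_threshold:
        return "learnt"
    return "learning"


def assign_phases(curves: Mapping[str, PerformanceCurve], blocks,
                  naive_thresholds: Mapping[str, float] = NAIVE_THRESHOLDS,
                  learnt_threshold: float = LEARNT_THRESHOLD) -> PhaseLabels:
    """Per-trial phase labels from the ongoing rule's curve.

    ``curves`` maps rule_name -> PerformanceCurve estimated on the *whole*
    session under that rule's recoding; each block's trials are thresholded
    on its own rule's lower credible bound, with the naive cutoff set by the
    block's change type at entry.
    """
    n = max(b.last_trial for b in blocks) + 1
    labels = np.empty(n, dtype=object)
    for b in blocks:
        curve = curves[b.rule_name]
        if curve.n_trials < n:
            raise ValueError(
                f"curve for {b.rule_name} covers {curve.n_trials} trials, "
                f"session has {n}")
        for t in range(b.first_trial, b.last_trial + 1):
            labels[t] = label_phase(float(curve.ci_lower[t]),
                                    b.change_type_at_entry,
                                    naive_thresholds, learnt_threshold)
    return PhaseLabels(labels=labels, naive_thresholds=dict(naive_thresholds),
                       learnt_threshold=learnt_threshold)


def estimate_rule_curves(session, background_p: float = 0.5,
                         ci_level: float = 0.90) -> dict[str, PerformanceCurve]:
    """One learning curve per rule present, each over the full session.

    Outcomes are recoded under the rule before fitting, so every curve asks
    "how well would the animal be doing if this rule were in force?".
    """
    start = [t.start_arm for t in session.trials]
    chosen = [t.chosen_arm for t in session.trials]
    curves = {}
    for name in dict.fromkeys(b.rule_name for b in session.rule_schedule):
        rec = recode_outcomes(start, chosen, name)
        curves[name] = estimate_performance(rec, background_p=background_p,
                                            ci_level=ci_level)
    return curves


def session_phases(session, curves: Mapping[str, PerformanceCurve] | None = None,
                   **kwargs) -> PhaseLabels:
    if curves is None:
        curves = estimate_rule_curves(session)
    return assign_phases(curves, session.rule_schedule, **kwargs)
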