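"""Synthetic plus-maze sessions with controllable ground truth.

No public recording of this task exists, so every downstream stage is
exercised on generated sessions that carry the statistical structure the
analyses assume:

* behaviour follows per-rule logistic learning toward an asymptote, and the
  rule changes the moment 13 of the last 15 trials are correct;
* each rule block occupies a population state — a centre in latent z-space —
  and trials scatter around it with isotropic within-state noise.  The
  centres form a random walk, one orthogonal step of length
  ``state_separation`` per rule change, so centre distances grow with the
  number of intervening rules.  A repeated rule can take a fresh step like
  any new rule (``new_state``), re-use its first centre (``same_state``),
  or all block structure can be replaced by a slow linear drift of the
  whole population (``drift_only``);
* a configurable fraction of neurons is positively or negatively coupled to
  the *latent* probability of a correct choice (the integrated learning
  state, not the single-trial outcome), with a target Spearman magnitude;
  a separate fraction can instead respond to the same-trial outcome only;
* run trajectories are parabolas in each path's canonical frame with
  additive Gaussian sampling noise, and firing can optionally load on the
  trajectory coefficients and running speed (movement confound scenarios).

Rates are emitted as spike trains whose counts encode the per-segment rates,
plus the exact rate matrices in the ground truth for rate-level analyses.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.random import Generator, default_rng
from scipy.stats import norm, rankdata

from . import behavior, session_io
from .session_io import (NeuronMeta, RuleBlock, Session, TrialRecord,
                         blocks_from_trials, path_frame, from_canonical,
                         path_type_of)

__all__ = ["GeneratorConfig", "GroundTruth", "generate_session",
           "sample_trajectory", "synthesize_rates", "learning_curve",
           "ConfigError", "SEGMENTS"]

SEGMENTS = ("run", "reward", "inter_trial", "entire_trial")

# log-rate change (natural-log units) per latent z-unit; chosen so that a
# few z-units of state separation move rates by a factor of 2-3, keeping
# simulated Hz in a physiological range
LOG_RATE_PER_Z = 0.3
# baseline-rate distribution across neurons (log-normal, Hz): median ~3 Hz
# with a tail above 10 Hz standing in for putative fast-spiking cells
BASELINE_LOG_MEAN = math.log(3.0)
BASELINE_LOG_SD = 1.1
# per-segment log-rate jitter, so segments agree but are not identical
SEGMENT_JITTER_Z = 0.3

_Z75 = norm.ppf(0.75)  # 0.6744897...


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions for one synthetic session.

    Defaults emulate the task's descriptive scale: four rule blocks (three
    changes — the median), ~100 trials, ~20 simultaneous neurons, ~30% of
    neurons performance-coupled, segment durations matched to the printed
    quartiles, reward fixed at 2 s.
    """
    n_neurons: int = 20
    rule_sequence: tuple[str, ...] = ("go_east", "go_right", "go_west", "go_east")
    n_rules: int | None = None  # derived from rule_sequence when None
    learning_rate: float = 0.35       # logistic slope per trial
    asymptote_p: float = 0.9
    state_separation: float = 4.0     # z-units between rule-state centres
    within_state_sd: float = 1.0      # z-units
    repeat_mode: str = "new_state"    # new_state | same_state | drift_only
    frac_pos_coupled: float = 0.15
    frac_neg_coupled: float = 0.15
    coupling_strength: float = 0.5    # target |Spearman rho| vs true p(correct)
    frac_instantaneous: float = 0.0   # neurons coding the same-trial outcome
    instantaneous_strength: float = 1.5
    movement_coupling: float = 0.0    # z-units per SD of trajectory features
    trajectory_drift: float = 0.0     # per-trial drift of the approach angle
    trajectory_noise_sd: float = 1.0  # cm
    segment_duration_quartiles: dict = dataclasses.field(default_factory=lambda: {
        # (q25, median, q75) in seconds; the inter-trial upper quartile is
        # the log-symmetric counterpart of the lower one (see methods note)
        "run": (2.28, 2.86, 4.34),
        "inter_trial": (15.48, 19.16, 23.72),
    })
    max_block_trials: int = 60
    drift_rate_per_trial: float | None = None  # default: separation / 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rules is None:
            self.n_rules = len(self.rule_sequence)
        if self.n_rules < 1 or len(self.rule_sequence) != self.n_rules:
            raise ConfigError("n_rules must be >= 1 and match rule_sequence")
        for name in self.rule_sequence:
            if name not in session_io.RULE_NAMES:
                raise ConfigError(f"unknown rule name {name!r}")
        for a, b in zip(self.rule_sequence, self.rule_sequence[1:]):
            if a == b:
                raise ConfigError(
                    f"adjacent identical rules in rule_sequence: {a!r}")
        if not (0.0 < self.asymptote_p < 1.0):
            raise ConfigError("asymptote_p must be in (0, 1)")
        fr = self.frac_pos_coupled + self.frac_neg_coupled + self.frac_instantaneous
        if min(self.frac_pos_coupled, self.frac_neg_coupled,
               self.frac_instantaneous) < 0 or fr > 1.0:
            raise ConfigError("neuron fractions must be >= 0 and sum to <= 1")
        if not (0.0 <= self.coupling_strength < 1.0):
            raise ConfigError("coupling_strength must be in [0, 1)")
        if self.repeat_mode not in ("new_state", "same_state", "drift_only"):
            raise ConfigError(f"unknown repeat_mode {self.repeat_mode!r}")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")

    @property
    def drift_rate(self) -> float:
        if self.drift_rate_per_trial is not None:
            return self.drift_rate_per_trial
        return self.state_separation / 100.0


@dataclasses.dataclass
class GroundTruth:
    """Latents behind one generated session."""
    p_true: np.ndarray                    # per-trial probability of correct
    block_centres: dict[int, np.ndarray]  # block id -> latent centre (z)
    coupled_pos: list[int]
    coupled_neg: list[int]
    instantaneous: list[int]
    latent_z: np.ndarray                  # trials x neurons latent state
    rates: dict[str, np.ndarray]          # segment -> trials x neurons Hz
    baseline_hz: np.ndarray
    traj_coeffs: np.ndarray               # trials x 3 true (a, b, c)
    path_types: list[str]
    drift_direction: np.ndarray | None
    movement_weights: np.ndarray | None   # neurons x 4 feature loadings
    config: GeneratorConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "p_true": self.p_true.tolist(),
            "block_centres": {str(k): v.tolist()
                              for k, v in self.block_centres.items()},
            "coupled_pos": self.coupled_pos,
            "coupled_neg": self.coupled_neg,
            "instantaneous": self.instantaneous,
            "baseline_hz": self.baseline_hz.tolist(),
            "traj_coeffs": self.traj_coeffs.tolist(),
            "path_types": self.path_types,
            "drift_direction": (None if self.drift_direction is None
                                else self.drift_direction.tolist()),
            "rates": {k: v.tolist() for k, v in self.rates.items()},
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(self.config).items()},
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def learning_curve(block_trial: np.ndarray | int, learning_rate: float,
                   asymptote_p: float) -> np.ndarray:
    """Within-block true p(correct): logistic rise from chance to asymptote.

    The half-rise point sits at 4/learning_rate block trials, which keeps
    the curve within ~2% of chance on the first trial for any slope.
    """
    j = np.asarray(block_trial, dtype=float)
    j_half = 4.0 / learning_rate
    return 0.5 + (asymptote_p - 0.5) / (1.0 + np.exp(-learning_rate * (j - j_half)))


def _correct_goal(start_arm: str, rule_name: str) -> str:
    """The rewarded goal arm for a start under a rule."""
    for goal in session_io.GOAL_ARMS:
        if behavior.recode_outcomes([start_arm], [goal], rule_name)[0] == 1:
            return goal
    raise RuntimeError("unreachable: one goal arm is always correct")


def _lognormal_from_quartiles(q25: float, median: float, q75: float):
    """(mu, sigma) of a log-normal matched to the quartile triple."""
    mu = math.log(median)
    sigma = (math.log(q75) - math.log(q25)) / (2.0 * _Z75)
    return mu, abs(sigma)


def sample_trajectory(path_type: str, coeffs: Sequence[float], noise_sd: float,
                      n_points: int, seed: int | Generator = 0) -> np.ndarray:
    """Sample a parabolic run path in the maze frame.

    The transverse coordinate follows w = a*s^2 + b*s + c along the path's
    canonical longitudinal axis s in [0, L], plus Gaussian noise of SD
    ``noise_sd`` on w; samples are rotated into the maze frame.
    Returns an (n_points, 2) array of (x, y) cm.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    a, b, c = (float(v) for v in coeffs)
    _, _, _, L = path_frame(path_type)
    s = np.linspace(0.0, L, n_points)
    w = a * s ** 2 + b * s + c
    if noise_sd > 0:
        w = w + rng.normal(0.0, noise_sd, size=n_points)
    return from_canonical(s, w, path_type)


def _arc_length(a: float, b: float, L: float, n: int = 256) -> float:
    s = np.linspace(0.0, L, n)
    return float(np.trapezoid(np.sqrt(1.0 + (2.0 * a * s + b) ** 2), s))


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula Pearson coefficient hitting a target Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


# shared-direction fraction of each state step.  Successive states do not
# wander isotropically: part of every rule-change step points along one
# session-wide direction, so later states lie beyond earlier ones rather
# than in directions orthogonal to all previous activity.  Without this, a
# repeated rule's fresh state would occupy a direction the decoder's
# training data never sampled, where a linear classifier's output is noise.
STATE_WALK_MOMENTUM = 0.5


def _block_centres(config: GeneratorConfig, n_blocks: int,
                   rule_names: Sequence[str], rng: Generator):
    """Latent centres per block; repeats resolved by repeat_mode.

    States form a random walk with momentum: every rule change pushes the
    population by a step of length ``state_separation`` composed of a fresh
    orthogonal component and a shared session-wide direction (weight
    ``STATE_WALK_MOMENTUM``).  Adjacent rule states are exactly one
    separation apart and the centre distance of a block pair grows with the
    number of rule changes between them, separation *
    sqrt((1-g^2)*gap + g^2*gap^2).  A repeated rule under ``new_state``
    takes the next step like any new rule — ending up beyond the pool of
    intervening states rather than back at its first centre; under
    ``same_state`` it re-uses the first centre exactly.
    """
    n = config.n_neurons
    if config.repeat_mode == "drift_only":
        return [np.zeros(n) for _ in range(n_blocks)], None
    g = STATE_WALK_MOMENTUM
    raw = rng.normal(size=(n, n_blocks))
    if n >= n_blocks:
        q, _ = np.linalg.qr(raw)
        drift = q[:, 0]
        dirs = q[:, 1:n_blocks].T
    else:  # fewer neurons than steps: fall back to random unit directions
        unit = raw.T / np.linalg.norm(raw.T, axis=1, keepdims=True)
        drift, dirs = unit[0], unit[1:]
    centres = [np.zeros(n)]
    for b in range(1, n_blocks):
        u = dirs[(b - 1) % max(len(dirs), 1)] if len(dirs) else drift
        step = math.sqrt(1.0 - g * g) * u + g * drift
        centres.append(centres[-1] + config.state_separation * step)
    if config.repeat_mode == "same_state":
        first_seen: dict[str, int] = {}
        for b, name in enumerate(rule_names):
            if name in first_seen:
                centres[b] = centres[first_seen[name]].copy()
            else:
                first_seen[name] = b
    return centres, None


def synthesize_rates(p_true: np.ndarray, outcomes: np.ndarray,
                     block_labels: np.ndarray, config: GeneratorConfig,
                     rng: Generator,
                     traj_features: np.ndarray | None = None,
                     durations: dict[str, np.ndarray] | None = None):
    """Latent states and per-segment rate matrices for given behaviour.

    Exposed separately so the rate model can be checked at arbitrary trial
    counts (e.g. Spearman-coupling convergence) without running the
    behavioural loop.  Returns (rates dict, truth fields dict).
    """
    m = len(p_true)
    n = config.n_neurons
    blocks_seq = list(dict.fromkeys(int(b) for b in block_labels))
    n_blocks = len(blocks_seq)
    rule_names = getattr(config, "_rule_names_for_blocks",
                         list(config.rule_sequence)[:n_blocks])

    centres, _ = _block_centres(config, n_blocks, rule_names, rng)
    centre_by_block = {bid: centres[i] for i, bid in enumerate(blocks_seq)}

    Z = np.empty((m, n))
    for i, bid in enumerate(block_labels):
        Z[i] = centre_by_block[int(bid)]
    drift_dir = None
    if config.repeat_mode == "drift_only":
        drift_dir = rng.normal(size=n)
        drift_dir /= np.linalg.norm(drift_dir)
        Z += np.outer(np.arange(m) * config.drift_rate, drift_dir)

    # neuron roles: positively / negatively performance-coupled,
    # instantaneous-outcome coders, and unstructured
    perm = rng.permutation(n)
    n_pos = int(round(config.frac_pos_coupled * n))
    n_neg = int(round(config.frac_neg_coupled * n))
    n_inst = int(round(config.frac_instantaneous * n))
    pos_ids = sorted(int(i) for i in perm[:n_pos])
    neg_ids = sorted(int(i) for i in perm[n_pos:n_pos + n_neg])
    inst_ids = sorted(int(i) for i in perm[n_pos + n_neg:n_pos + n_neg + n_inst])

    # Gaussian scores of the latent performance (ranks -> normal quantiles):
    # a Pearson loading of 2*sin(pi*rho/6) on the score yields Spearman rho.
    # The loading is computed against the *total* non-state noise budget
    # (within-state SD plus the per-segment jitter added below), so the
    # target holds for the emitted segment rates, not just the latent state.
    r_g = _spearman_to_pearson(config.coupling_strength)
    q = norm.ppf((rankdata(p_true, method="average") - 0.5) / m)
    y_c = np.asarray(outcomes, float) - float(np.mean(outcomes))

    sd = config.within_state_sd
    v_tot = sd ** 2 + SEGMENT_JITTER_Z ** 2
    lam = r_g * math.sqrt(v_tot)
    sd_eta = math.sqrt(max(v_tot * (1.0 - r_g ** 2)
                           - SEGMENT_JITTER_Z ** 2, 0.0))
    for j in range(n):
        eta = rng.normal(size=m)
        if j in pos_ids:
            Z[:, j] += lam * q + sd_eta * eta
        elif j in neg_ids:
            Z[:, j] += -lam * q + sd_eta * eta
        elif j in inst_ids:
            Z[:, j] += sd * (config.instantaneous_strength * y_c + 0.5 * eta)
        else:
            Z[:, j] += sd * eta

    move_w = None
    if config.movement_coupling != 0.0 and traj_features is not None:
        F = np.asarray(traj_features, float)
        F = (F - F.mean(axis=0)) / np.where(F.std(axis=0) > 0, F.std(axis=0), 1.0)
        move_w = rng.normal(size=(n, F.shape[1]))
        move_w /= np.linalg.norm(move_w, axis=1, keepdims=True)
        Z += config.movement_coupling * (F @ move_w.T)

    baseline = np.exp(rng.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=n))
    rates: dict[str, np.ndarray] = {}
    for seg in ("run", "reward", "inter_trial"):
        jitter = SEGMENT_JITTER_Z * rng.normal(size=(m, n))
        rates[seg] = baseline * np.exp(LOG_RATE_PER_Z * (Z + jitter))
    if durations is not None:
        d_run = durations["run"][:, None]
        d_int = durations["inter_trial"][:, None]
        total = d_run + session_io.REWARD_DURATION_S + d_int
        rates["entire_trial"] = (rates["run"] * d_run
                                 + rates["reward"] * session_io.REWARD_DURATION_S
                                 + rates["inter_trial"] * d_int) / total

    truth_fields = dict(block_centres=centre_by_block, coupled_pos=pos_ids,
                        coupled_neg=neg_ids, instantaneous=inst_ids,
                        latent_z=Z, baseline_hz=baseline,
                        drift_direction=drift_dir, movement_weights=move_w)
    return rates, truth_fields


def _emit_spikes(rate: float, t0: float, duration: float) -> np.ndarray:
    """Evenly spaced spike train whose count encodes the segment rate."""
    count = int(round(rate * duration))
    if count <= 0:
        return np.empty(0)
    return t0 + (np.arange(count) + 0.5) * duration / count


def generate_session(config: GeneratorConfig, seed: int | None = None,
                     with_spikes: bool = True,
                     session_id: str = "synthetic") -> tuple[Session, GroundTruth]:
    """Generate one full session plus its ground truth.

    ``seed`` overrides ``config.seed``.  ``with_spikes=False`` skips spike
    emission (the ground-truth rate matrices remain available), which is the
    fast path for rate-level simulation studies.
    """
    rng = default_rng(config.seed if seed is None else seed)

    # ---- behaviour ----
    rows = []          # (rule_id, rule_name, start, chosen, correct)
    p_true_list: list[float] = []
    arm_run_len = 0
    prev_start: str | None = None
    for block_id, rule in enumerate(config.rule_sequence):
        block_outcomes: list[int] = []
        for j in range(config.max_block_trials):
            p = float(learning_curve(j, config.learning_rate, config.asymptote_p))
            if prev_start is not None and arm_run_len >= 4:
                start = "S" if prev_start == "N" else "N"
            else:
                start = "N" if rng.random() < 0.5 else "S"
            arm_run_len = arm_run_len + 1 if start == prev_start else 1
            prev_start = start
            correct = int(rng.random() < p)
            goal = _correct_goal(start, rule)
            chosen = goal if correct else ("E" if goal == "W" else "W")
            rows.append((block_id, rule, start, chosen, correct))
            p_true_list.append(p)
            block_outcomes.append(correct)
            trig = behavior.apply_rule_change_criterion(block_outcomes)
            if trig is not None and trig == j:
                break
    m = len(rows)
    p_true = np.array(p_true_list)
    block_labels = np.array([r[0] for r in rows], dtype=int)
    outcomes = np.array([r[4] for r in rows], dtype=int)

    # ---- timing ----
    mu_r, sd_r = _lognormal_from_quartiles(*config.segment_duration_quartiles["run"])
    mu_i, sd_i = _lognormal_from_quartiles(*config.segment_duration_quartiles["inter_trial"])
    run_dur = np.exp(rng.normal(mu_r, sd_r, size=m))
    inter_dur = np.exp(rng.normal(mu_i, sd_i, size=m))

    # ---- trajectories ----
    a_vals = np.empty(m); b_vals = np.empty(m); c_vals = np.empty(m)
    speeds = np.empty(m)
    path_types: list[str] = []
    trajectories: dict[int, np.ndarray] = {}
    t_cursor = 0.0
    trial_times = []  # (t_start, t_run, t_cross, t_end)
    for i, (bid, rule, start, chosen, correct) in enumerate(rows):
        ptype = path_type_of(start, chosen)
        path_types.append(ptype)
        _, _, _, L = path_frame(ptype)
        a0 = 4.0 * 35.0 / L ** 2  # base curvature: ~35 cm bulge toward centre
        a = a0 * (1.0 + 0.10 * rng.normal())
        b = -a * L + 0.05 * rng.normal() + config.trajectory_drift * i
        c = 2.0 * rng.normal()
        a_vals[i], b_vals[i], c_vals[i] = a, b, c

        t_start = t_cursor
        t_cross = t_start + run_dur[i]
        t_end = t_cross + session_io.REWARD_DURATION_S + inter_dur[i]
        trial_times.append((t_start, t_start, t_cross, t_end))
        t_cursor = t_end

        n_pts = max(8, int(round(run_dur[i] * 25.0)))  # 25 Hz tracking
        xy = sample_trajectory(ptype, (a, b, c), config.trajectory_noise_sd,
                               n_pts, rng)
        ts = np.linspace(t_start, t_cross, n_pts)
        trajectories[i] = np.column_stack([ts, xy])
        speeds[i] = _arc_length(a, b, L) / run_dur[i] / 100.0  # m/s

    # ---- rates ----
    cfg = dataclasses.replace(config)
    # rule names per realised block, for same_state centre re-use
    cfg._rule_names_for_blocks = list(config.rule_sequence)
    traj_features = np.column_stack([a_vals, b_vals, c_vals, speeds])
    durations = {"run": run_dur, "inter_trial": inter_dur}
    rates, truth_fields = synthesize_rates(p_true, outcomes, block_labels, cfg,
                                           rng, traj_features=traj_features,
                                           durations=durations)

    # ---- spikes ----
    n = config.n_neurons
    width = max(3, len(str(n - 1)))
    neuron_ids = [f"n{j:0{width}d}" for j in range(n)]
    spikes: dict[str, np.ndarray] = {}
    if with_spikes:
        for j, nid in enumerate(neuron_ids):
            parts = []
            for i in range(m):
                t_start, _, t_cross, t_end = trial_times[i]
                parts.append(_emit_spikes(rates["run"][i, j], t_start,
                                          run_dur[i]))
                parts.append(_emit_spikes(rates["reward"][i, j], t_cross,
                                          session_io.REWARD_DURATION_S))
                parts.append(_emit_spikes(
                    rates["inter_trial"][i, j],
                    t_cross + session_io.REWARD_DURATION_S, inter_dur[i]))
            spikes[nid] = np.concatenate(parts) if parts else np.empty(0)

    total_time = trial_times[-1][3] - trial_times[0][0] if m else 1.0
    neurons = [NeuronMeta(neuron_id=nid,
                          mean_rate=(len(spikes.get(nid, ())) / total_time
                                     if with_spikes
                                     else float(rates["entire_trial"][:, j].mean())))
               for j, nid in enumerate(neuron_ids)]

    trials = [
        TrialRecord(index=i, rule_id=bid, rule_name=rule, start_arm=start,
                    chosen_arm=chosen, correct=correct,
                    t_trial_start=trial_times[i][0],
                    t_run_start=trial_times[i][1],
                    t_reward_cross=trial_times[i][2],
                    t_trial_end=trial_times[i][3],
                    mean_speed=float(speeds[i]))
        for i, (bid, rule, start, chosen, correct) in enumerate(rows)
    ]

    session = Session(session_id=session_id, trials=trials, neurons=neurons,
                      rule_schedule=blocks_from_trials(trials), spikes=spikes,
                      trajectories=trajectories)
    session_io.validate_session(session)

    truth = GroundTruth(
        p_true=p_true,
        block_centres=truth_fields["block_centres"],
        coupled_pos=truth_fields["coupled_pos"],
        coupled_neg=truth_fields["coupled_neg"],
        instantaneous=truth_fields["instantaneous"],
        latent_z=truth_fields["latent_z"],
        rates=rates,
        baseline_hz=truth_fields["baseline_hz"],
        traj_coeffs=np.column_stack([a_vals, b_vals, c_vals]),
        path_types=path_types,
        drift_direction=truth_fields["drift_direction"],
        movement_weights=truth_fields["movement_weights"],
        config=config,
    )
    return session, truth
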