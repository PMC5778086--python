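"""Canonical session data model and delimited-text I/O.

A recording session of the plus-maze strategy-switching task is stored as
three CSV files:

``trials.csv``
    index,rule_id,rule_name,start_arm,chosen_arm,correct,t_trial_start,
    t_run_start,t_reward_cross,t_trial_end,mean_speed
``spikes.csv``
    neuron_id,t_spike
``trajectories.csv``
    trial_index,t,x,y

Times are seconds from session start; positions are cm in the maze frame
(origin at the maze centre, the North arm along +y).  ``rule_id`` is a
*block* identifier: a rule presented twice in one session yields two blocks
with distinct ids, matching how the analyses treat a repetition as a
separate candidate state.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ruleflux")

RULE_NAMES = ("go_east", "go_west", "go_right", "go_left")
ALLOCENTRIC = frozenset({"go_east", "go_west"})
EGOCENTRIC = frozenset({"go_right", "go_left"})
START_ARMS = ("N", "S")
GOAL_ARMS = ("E", "W")

TRIAL_COLUMNS = [
    "index", "rule_id", "rule_name", "start_arm", "chosen_arm", "correct",
    "t_trial_start", "t_run_start", "t_reward_cross", "t_trial_end",
    "mean_speed",
]
SPIKE_COLUMNS = ["neuron_id", "t_spike"]
TRAJ_COLUMNS = ["trial_index", "t", "x", "y"]

FLOAT_FORMAT = "%.9f"
REWARD_DURATION_S = 2.0  # reward segment is fixed at two seconds


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class SessionValidationError(ValueError):
    """A session invariant is violated; the message names the trial."""


@dataclasses.dataclass
class TrialRecord:
    index: int
    rule_id: int
    rule_name: str
    start_arm: str
    chosen_arm: str
    correct: int
    t_trial_start: float
    t_run_start: float
    t_reward_cross: float
    t_trial_end: float
    mean_speed: float


@dataclasses.dataclass
class NeuronMeta:
    neuron_id: str
    mean_rate: float
    spike_width: float | None = None


@dataclasses.dataclass
class RuleBlock:
    rule_id: int
    rule_name: str
    first_trial: int
    last_trial: int
    change_type_at_entry: str  # switch | reversal | session_start

    @property
    def n_trials(self) -> int:
        return self.last_trial - self.first_trial + 1

    def trial_indices(self) -> np.ndarray:
        return np.arange(self.first_trial, self.last_trial + 1)


@dataclasses.dataclass
class Session:
    session_id: str
    trials: list[TrialRecord]
    neurons: list[NeuronMeta]
    rule_schedule: list[RuleBlock]
    spikes: dict[str, np.ndarray]
    trajectories: dict[int, np.ndarray]  # trial index -> (n, 3) [t, x, y]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def trial_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.trials],
                            columns=TRIAL_COLUMNS)

    def outcomes(self) -> np.ndarray:
        return np.array([t.correct for t in self.trials], dtype=int)

    def block_labels(self) -> np.ndarray:
        return np.array([t.rule_id for t in self.trials], dtype=int)

    def block_of(self, rule_id: int) -> RuleBlock:
        for b in self.rule_schedule:
            if b.rule_id == rule_id:
                return b
        raise KeyError(f"no rule block with id {rule_id}")


def change_type(prev_rule: str | None, rule: str) -> str:
    """Classify a rule change: within-strategy = reversal, across = switch."""
    if prev_rule is None:
        return "session_start"
    prev_allo = prev_rule in ALLOCENTRIC
    return "reversal" if prev_allo == (rule in ALLOCENTRIC) else "switch"


def blocks_from_trials(trials: Sequence[TrialRecord]) -> list[RuleBlock]:
    """Reconstruct the rule schedule from consecutive runs of rule_id."""
    blocks: list[RuleBlock] = []
    prev_rule: str | None = None
    for t in trials:
        if not blocks or t.rule_id != blocks[-1].rule_id:
            blocks.append(RuleBlock(
                rule_id=t.rule_id,
                rule_name=t.rule_name,
                first_trial=t.index,
                last_trial=t.index,
                change_type_at_entry=change_type(prev_rule, t.rule_name),
            ))
            prev_rule = t.rule_name
        else:
            blocks[-1].last_trial = t.index
    return blocks


def validate_session(session: Session) -> None:
    """Check the session invariants; raise SessionValidationError on failure."""
    from . import behavior  # deferred: behavior has no session_io dependency

    trials = session.trials
    for i, t in enumerate(trials):
        if t.index != i:
            raise SessionValidationError(
                f"trial indices must be consecutive from 0; found {t.index} "
                f"at position {i}")
        if not (t.t_trial_start <= t.t_run_start < t.t_reward_cross
                < t.t_trial_end):
            raise SessionValidationError(
                f"trial {t.index}: timestamps out of order "
                f"(require trial_start <= run_start < reward_cross < trial_end)")
        if t.rule_name not in RULE_NAMES:
            raise SessionValidationError(
                f"trial {t.index}: unknown rule_name {t.rule_name!r}")
        if t.start_arm not in START_ARMS or t.chosen_arm not in GOAL_ARMS:
            raise SessionValidationError(
                f"trial {t.index}: arms must be start in {START_ARMS}, "
                f"choice in {GOAL_ARMS}")

    # blocks tile the session; adjacent blocks change rule
    blocks = session.rule_schedule
    pos = 0
    for k, b in enumerate(blocks):
        if b.first_trial != pos:
            raise SessionValidationError(
                f"rule blocks must tile the session; block {b.rule_id} starts "
                f"at {b.first_trial}, expected {pos}")
        pos = b.last_trial + 1
        if k > 0 and b.rule_name == blocks[k - 1].rule_name:
            raise SessionValidationError(
                f"adjacent blocks {blocks[k-1].rule_id} and {b.rule_id} share "
                f"rule {b.rule_name}")
    if trials and pos != len(trials):
        raise SessionValidationError("rule blocks do not cover all trials")

    # recorded outcome must match the recoding under the active rule
    if trials:
        start = np.array([t.start_arm for t in trials])
        chosen = np.array([t.chosen_arm for t in trials])
        correct = np.array([t.correct for t in trials], dtype=int)
        for b in blocks:
            sl = slice(b.first_trial, b.last_trial + 1)
            expected = behavior.recode_outcomes(start[sl], chosen[sl],
                                                b.rule_name)
            bad = np.nonzero(expected != correct[sl])[0]
            if bad.size:
                raise SessionValidationError(
                    f"trial {b.first_trial + int(bad[0])}: 'correct' does not "
                    f"match recoding under rule {b.rule_name}")

        # a start arm may not repeat more than four consecutive times
        run = 1
        for i in range(1, len(trials)):
            run = run + 1 if trials[i].start_arm == trials[i - 1].start_arm else 1
            if run > 4:
                raise SessionValidationError(
                    f"trial {i}: start arm {trials[i].start_arm} repeated "
                    f"more than four consecutive times")

    for n in session.neurons:
        if n.mean_rate < 0:
            raise SessionValidationError(
                f"neuron {n.neuron_id}: mean_rate must be >= 0")


def _require_columns(df: pd.DataFrame, cols: Iterable[str], which: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{which} is missing column(s): {', '.join(missing)}")


def read_session(trials_path: str | Path,
                 spikes_path: str | Path,
                 trajectories_path: str | Path,
                 session_id: str | None = None) -> Session:
    """Read and validate a session from its three CSV files.

    Spike times and position samples are attached per trial by timestamp
    interval at query time; spikes outside every trial are retained in the
    per-neuron arrays but belong to no segment.
    """
    trials_path = Path(trials_path)
    tdf = pd.read_csv(trials_path)
    _require_columns(tdf, TRIAL_COLUMNS, str(trials_path))
    sdf = pd.read_csv(spikes_path)
    _require_columns(sdf, SPIKE_COLUMNS, str(spikes_path))
    jdf = pd.read_csv(trajectories_path)
    _require_columns(jdf, TRAJ_COLUMNS, str(trajectories_path))

    trials = [
        TrialRecord(
            index=int(r.index), rule_id=int(r.rule_id),
            rule_name=str(r.rule_name), start_arm=str(r.start_arm),
            chosen_arm=str(r.chosen_arm), correct=int(r.correct),
            t_trial_start=float(r.t_trial_start),
            t_run_start=float(r.t_run_start),
            t_reward_cross=float(r.t_reward_cross),
            t_trial_end=float(r.t_trial_end),
            mean_speed=float(r.mean_speed),
        )
        for r in tdf.itertuples(index=False)
    ]

    spikes: dict[str, np.ndarray] = {}
    for nid, grp in sdf.groupby("neuron_id", sort=True):
        spikes[str(nid)] = np.sort(grp["t_spike"].to_numpy(dtype=float))

    if trials:
        t0 = trials[0].t_trial_start
        t1 = trials[-1].t_trial_end
        span = max(t1 - t0, 1e-12)
    else:
        span = 1.0
    neurons = [NeuronMeta(neuron_id=nid, mean_rate=len(ts) / span)
               for nid, ts in sorted(spikes.items())]

    trajectories: dict[int, np.ndarray] = {}
    for idx, grp in jdf.groupby("trial_index", sort=True):
        trajectories[int(idx)] = grp[["t", "x", "y"]].to_numpy(dtype=float)

    session = Session(
        session_id=session_id or trials_path.stem,
        trials=trials,
        neurons=neurons,
        rule_schedule=blocks_from_trials(trials),
        spikes=spikes,
        trajectories=trajectories,
    )
    validate_session(session)
    return session


def write_session(session: Session, out_dir: str | Path) -> dict[str, Path]:
    """Write trials/spikes/trajectories CSVs with deterministic formatting.

    Writing the same session twice produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.csv",
        "spikes": out / "spikes.csv",
        "trajectories": out / "trajectories.csv",
    }

    tdf = session.trial_frame()
    tdf.to_csv(paths["trials"], index=False, float_format=FLOAT_FORMAT)

    rows_s = [(nid, t) for nid in sorted(session.spikes)
              for t in session.spikes[nid]]
    sdf = pd.DataFrame(rows_s, columns=SPIKE_COLUMNS)
    sdf.to_csv(paths["spikes"], index=False, float_format=FLOAT_FORMAT)

    rows_j = []
    for idx in sorted(session.trajectories):
        for t, x, y in session.trajectories[idx]:
            rows_j.append((idx, t, x, y))
    jdf = pd.DataFrame(rows_j, columns=TRAJ_COLUMNS)
    if not rows_j:  # keep integer dtype for the empty header-only file
        jdf["trial_index"] = jdf["trial_index"].astype(int)
    jdf.to_csv(paths["trajectories"], index=False, float_format=FLOAT_FORMAT)
    return paths


def read_session_dir(directory: str | Path, session_id: str | None = None) -> Session:
    d = Path(directory)
    return read_session(d / "trials.csv", d / "spikes.csv",
                        d / "trajectories.csv",
                        session_id=session_id or d.name)


def spikes_in_interval(times: np.ndarray, t0: float, t1: float) -> int:
    """Count spikes with t0 <= t < t1 (half-open, so segments never overlap)."""
    return int(np.searchsorted(times, t1, side="left")
               - np.searchsorted(times, t0, side="left"))


# --------------------------------------------------------------------------
# Maze geometry (maze frame: origin at centre, N arm along +y, cm units)
# --------------------------------------------------------------------------

ARM_LENGTH_CM = 80.0
ARM_ENDS = {
    "N": (0.0, ARM_LENGTH_CM),
    "S": (0.0, -ARM_LENGTH_CM),
    "E": (ARM_LENGTH_CM, 0.0),
    "W": (-ARM_LENGTH_CM, 0.0),
}
PATH_TYPES = ("NE", "NW", "SE", "SW")


def path_type_of(start_arm: str, chosen_arm: str) -> str:
    """Path label (start arm + goal arm), e.g. run from South to East = 'SE'."""
    if start_arm not in START_ARMS or chosen_arm not in GOAL_ARMS:
        raise ValueError(f"invalid path {start_arm}->{chosen_arm}")
    return start_arm + chosen_arm


def path_frame(path_type: str):
    """Canonical frame of a run path.

    Longitudinal axis points from the start-arm end to the goal-arm end;
    the transverse axis is perpendicular and points away from the maze
    centre, so a run that cuts through the centre region has negative
    transverse coordinates.  Returns (origin, u_long, u_trans, length).
    """
    if path_type not in PATH_TYPES:
        raise ValueError(f"unknown path_type {path_type!r}")
    p0 = np.asarray(ARM_ENDS[path_type[0]], dtype=float)
    p1 = np.asarray(ARM_ENDS[path_type[1]], dtype=float)
    d = p1 - p0
    length = float(np.hypot(*d))
    u = d / length
    n = np.array([-u[1], u[0]])
    if np.dot(n, (p0 + p1) / 2.0) < 0:
        n = -n
    return p0, u, n, length


def to_canonical(points: np.ndarray, path_type: str) -> np.ndarray:
    """Maze-frame (x, y) samples -> canonical (longitudinal, transverse)."""
    p0, u, n, _ = path_frame(path_type)
    rel = np.asarray(points, dtype=float) - p0
    return np.column_stack([rel @ u, rel @ n])


def from_canonical(s: np.ndarray, w: np.ndarray, path_type: str) -> np.ndarray:
    """Canonical (longitudinal s, transverse w) -> maze-frame (x, y)."""
    p0, u, n, _ = path_frame(path_type)
    return p0 + np.outer(np.asarray(s, float), u) + np.outer(np.asarray(w, float), n)


def parse_config(path: str | Path) -> dict[str, str]:
    """Parse a plain-text ``key = value`` configuration file.

    Blank lines and lines starting with '#' are ignored.  Values are returned
    as strings; consumers coerce types.
    """
    cfg: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SchemaError(f"config line is not 'key = value': {raw!r}")
        key, _, val = line.partition("=")
        cfg[key.strip()] = val.strip()
    return cfg
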