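"""Generative model of the instructed probabilistic reversal-learning task.

The task: in each block the participant (or a simulated agent) must learn by
trial and error which of two stimulus-response mappings is currently correct.
Feedback is probabilistic — it matches the rule-correctness of the response
only with probability rho (the feedback reliability) — and an unannounced
rule reversal may occur once per block.  A written instruction shown before
each block manipulates the learner's beliefs: about environment volatility
(experiment 1) or about feedback reliability (experiment 2).

This module builds exactly counterbalanced block schedules for the three
experiment designs, draws trial-wise feedback, runs agents through blocks,
and round-trips trial logs as tab-delimited text.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

# --------------------------------------------------------------------------
# Labels
# --------------------------------------------------------------------------

VOLATILITY = "volatility"
STABILITY = "stability"
RELIABLE_INSTRUCTED = "reliable_instructed"
UNRELIABLE_INSTRUCTED = "unreliable_instructed"

INSTRUCTIONS = (VOLATILITY, STABILITY, RELIABLE_INSTRUCTED, UNRELIABLE_INSTRUCTED)

MAPPING_A = "A"
MAPPING_B = "B"
MAPPINGS = (MAPPING_A, MAPPING_B)

POSITIVE = "positive"
NEGATIVE = "negative"

PRE_REVERSAL = "pre_reversal"
POST_REVERSAL = "post_reversal"


def other_mapping(mapping: str) -> str:
    return MAPPING_B if mapping == MAPPING_A else MAPPING_A


class ScheduleConfigError(ValueError):
    """Counterbalancing cell counts do not divide evenly."""


class TrialLogError(ValueError):
    """A trial log file is malformed."""


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Design parameters of one experiment.

    ``condition_cells`` maps a condition label to a dict with keys
    ``instruction``, ``reliability`` and ``reversal_prob``; each cell receives
    an equal share of ``n_blocks``.  ``rounding`` controls what happens when
    the implied cell counts are not integers: ``"strict"`` raises a
    :class:`ScheduleConfigError`; ``"largest_remainder"`` rounds
    deterministically while preserving the total block count.
    """

    experiment_id: str
    n_blocks: int
    block_lengths: tuple[int, ...]
    response_feedback_interval_ms: int
    condition_cells: dict = field(default_factory=dict)
    reversal_trials: tuple[int, ...] = ()   # exp2 only; exp1 uses the midpoint
    rounding: str = "strict"
    seed: Optional[int] = None

    def __post_init__(self):
        for name, cell in self.condition_cells.items():
            if not 0.0 <= cell["reversal_prob"] <= 1.0:
                raise ValueError(f"reversal_prob out of [0,1] in cell {name!r}")
            if not 0.0 <= cell["reliability"] <= 1.0:
                raise ValueError(f"reliability out of [0,1] in cell {name!r}")
        if any(length % 2 == 0 for length in self.block_lengths):
            raise ValueError("block lengths must be odd (defined midpoint)")


def exp1_config(experiment_id: str, n_blocks: int, rfi_ms: int,
                rounding: str = "strict") -> ExperimentConfig:
    cells = {
        VOLATILITY: {"instruction": VOLATILITY, "reliability": 0.75,
                     "reversal_prob": 2 / 3},
        STABILITY: {"instruction": STABILITY, "reliability": 0.75,
                    "reversal_prob": 1 / 3},
    }
    return ExperimentConfig(experiment_id=experiment_id, n_blocks=n_blocks,
                            block_lengths=(25, 33, 41),
                            response_feedback_interval_ms=rfi_ms,
                            condition_cells=cells, rounding=rounding)


def exp1a_config() -> ExperimentConfig:
    """36 blocks, 500 ms response-feedback interval."""
    return exp1_config("exp1a", 36, 500)


def exp1b_config() -> ExperimentConfig:
    """27 blocks, 1200 ms interval (slow-wave recording variant).

    27 blocks cannot be split exactly over instruction x length x reversal
    cells, so this design uses largest-remainder rounding.
    """
    return exp1_config("exp1b", 27, 1200, rounding="largest_remainder")


def exp2_config() -> ExperimentConfig:
    """32 blocks of 33 trials; four reliability cells of 8 blocks each.

    Three objective reliability levels (0.875 / 0.75 / 0.625); the two
    intermediate cells differ only in the instruction given.  3/4 of the
    blocks contain a single reversal, equally often at trial 9, 17, or 25.
    """
    cells = {
        "high_reliability": {"instruction": RELIABLE_INSTRUCTED,
                             "reliability": 0.875, "reversal_prob": 3 / 4},
        "mid_reliable_instructed": {"instruction": RELIABLE_INSTRUCTED,
                                    "reliability": 0.75, "reversal_prob": 3 / 4},
        "mid_unreliable_instructed": {"instruction": UNRELIABLE_INSTRUCTED,
                                      "reliability": 0.75, "reversal_prob": 3 / 4},
        "low_reliability": {"instruction": UNRELIABLE_INSTRUCTED,
                            "reliability": 0.625, "reversal_prob": 3 / 4},
    }
    return ExperimentConfig(experiment_id="exp2", n_blocks=32,
                            block_lengths=(33,),
                            response_feedback_interval_ms=500,
                            condition_cells=cells,
                            reversal_trials=(9, 17, 25))


_BUILTIN_CONFIGS = {"exp1a": exp1a_config, "exp1b": exp1b_config,
                    "exp2": exp2_config}


def get_config(name_or_path: str) -> ExperimentConfig:
    """Resolve a built-in design name or load a YAML config file."""
    if name_or_path in _BUILTIN_CONFIGS:
        return _BUILTIN_CONFIGS[name_or_path]()
    return load_config(name_or_path)


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["block_lengths"] = tuple(raw["block_lengths"])
    raw["reversal_trials"] = tuple(raw.get("reversal_trials", ()))
    return ExperimentConfig(**raw)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    raw = dataclasses.asdict(config)
    raw["block_lengths"] = list(config.block_lengths)
    raw["reversal_trials"] = list(config.reversal_trials)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# --------------------------------------------------------------------------
# Schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    index: int
    condition: str
    instruction: str
    length: int
    has_reversal: bool
    reversal_trial: Optional[int]      # 1-based; None when no reversal
    reliability: float
    stimulus_pair: tuple[str, str]
    initial_mapping: str               # correct mapping on trial 1
    phase_boundary: int                # reversal trial, or notional midpoint

    def __post_init__(self):
        if self.has_reversal and self.reversal_trial is None:
            raise ValueError("reversal block without reversal_trial")
        if not self.has_reversal and self.reversal_trial is not None:
            raise ValueError("reversal_trial set on a no-reversal block")


def reversal_trial_for(length: int, experiment_id: str,
                       rng: Optional[np.random.Generator] = None) -> int:
    """Reversal position for a single block.

    Experiment 1: the deterministic midpoint (length+1)/2, i.e. trial 13, 17
    or 21 for the three block lengths.  Experiment 2: drawn uniformly from
    {9, 17, 25} (the schedule builder enforces exact equal counts).
    """
    if experiment_id in ("exp1a", "exp1b", "exp1"):
        if length not in (25, 33, 41):
            raise ValueError(f"unsupported exp1 block length {length}")
        return (length + 1) // 2
    if experiment_id == "exp2":
        if length != 33:
            raise ValueError(f"unsupported exp2 block length {length}")
        if rng is None:
            rng = np.random.default_rng()
        return int(rng.choice([9, 17, 25]))
    raise ValueError(f"unknown experiment_id {experiment_id!r}")


def _cell_counts(config: ExperimentConfig) -> dict:
    """Exact (or largest-remainder) block counts per
    condition x length x reversal cell, preserving the reversal proportion
    within each condition as closely as possible."""
    n_cond = len(config.condition_cells)
    n_len = len(config.block_lengths)
    targets = {}
    for cond, cell in config.condition_cells.items():
        for length in config.block_lengths:
            base = config.n_blocks / n_cond / n_len
            targets[(cond, length, True)] = base * cell["reversal_prob"]
            targets[(cond, length, False)] = base * (1.0 - cell["reversal_prob"])
    if all(abs(v - round(v)) < 1e-9 for v in targets.values()):
        return {k: int(round(v)) for k, v in targets.items()}
    if config.rounding != "largest_remainder":
        offender = next(k for k, v in targets.items()
                        if abs(v - round(v)) >= 1e-9)
        raise ScheduleConfigError(
            f"counterbalancing cell {offender} requires {targets[offender]:.3f} "
            f"blocks, which is not an integer; use rounding='largest_remainder' "
            f"or adjust n_blocks")
    floors = {k: int(np.floor(v + 1e-9)) for k, v in targets.items()}
    shortfall = config.n_blocks - sum(floors.values())
    order = sorted(targets, key=lambda k: (-(targets[k] - floors[k]),
                                           list(targets).index(k)))
    for k in order[:shortfall]:
        floors[k] += 1
    return floors


def build_schedule(config: ExperimentConfig,
                   seed: Optional[int] = None) -> list[BlockSpec]:
    """Build the full block schedule with exact counterbalancing.

    Counts per condition x length x reversal cell are deterministic; only the
    block order, reversal-position assignment (exp2), stimulus identities and
    initial mappings depend on the seed.
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    counts = _cell_counts(config)

    protos = []
    for (cond, length, has_rev), n in counts.items():
        protos.extend([(cond, length, has_rev)] * n)

    # exp2: assign reversal positions with exact equal counts per condition
    rev_positions: dict[str, list[int]] = {}
    if config.reversal_trials:
        for cond in config.condition_cells:
            n_rev = sum(counts[(cond, length, True)]
                        for length in config.block_lengths)
            reps = -(-n_rev // len(config.reversal_trials))
            pool = (list(config.reversal_trials) * reps)[:n_rev]
            rng.shuffle(pool)
            rev_positions[cond] = pool

    order = rng.permutation(len(protos))
    blocks = []
    for new_index, proto_idx in enumerate(order):
        cond, length, has_rev = protos[proto_idx]
        cell = config.condition_cells[cond]
        if has_rev:
            if config.reversal_trials:
                rev = rev_positions[cond].pop()
            else:
                rev = reversal_trial_for(length, config.experiment_id)
        else:
            rev = None
        midpoint = (length + 1) // 2
        blocks.append(BlockSpec(
            index=new_index,
            condition=cond,
            instruction=cell["instruction"],
            length=length,
            has_reversal=has_rev,
            reversal_trial=rev,
            reliability=cell["reliability"],
            stimulus_pair=(f"b{new_index:02d}_s1", f"b{new_index:02d}_s2"),
            initial_mapping=str(rng.choice(MAPPINGS)),
            phase_boundary=rev if rev is not None else midpoint,
        ))
    return blocks


# --------------------------------------------------------------------------
# Trials
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialRecord:
    block_index: int
    trial_index: int                   # 1-based within the block
    stimulus_id: str
    correct_mapping: str
    applied_mapping: str
    rule_correct: bool
    feedback: str
    feedback_valid: bool
    instruction: str
    phase: str
    reliability: float
    has_reversal: bool


TRIAL_LOG_COLUMNS = [f.name for f in dataclasses.fields(TrialRecord)]

_BOOL_COLUMNS = ("rule_correct", "feedback_valid", "has_reversal")


def draw_feedback(rule_correct: bool, rho: float,
                  rng: np.random.Generator) -> tuple[str, bool]:
    """Draw feedback valence; it matches rule-correctness with probability rho.

    Returns ``(feedback, feedback_valid)``.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("reliability must lie in [0,1]")
    valid = bool(rng.random() < rho)
    if valid:
        feedback = POSITIVE if rule_correct else NEGATIVE
    else:
        feedback = NEGATIVE if rule_correct else POSITIVE
    return feedback, valid


def stimulus_sequence(block: BlockSpec,
                      rng: np.random.Generator) -> list[str]:
    # each stimulus appears ceil(length/2) or floor(length/2) times
    s1, s2 = block.stimulus_pair
    seq = [s1] * ((block.length + 1) // 2) + [s2] * (block.length // 2)
    rng.shuffle(seq)
    return seq


@dataclass
class TrialContext:
    """What the agent is shown on one trial (``correct_mapping`` is consumed
    only by oracle agents used for design checks; learners must ignore it)."""
    stimulus_id: str
    correct_mapping: str


def run_block(block: BlockSpec, agent,
              rng: np.random.Generator) -> list[TrialRecord]:
    """Run one agent through one block.

    The correct mapping flips at ``reversal_trial`` and never again.  The
    agent must expose ``start_block(block)``, ``act(context) -> mapping`` and
    ``observe(feedback)``.
    """
    agent.start_block(block)
    stimuli = stimulus_sequence(block, rng)
    records = []
    for t in range(1, block.length + 1):
        if block.has_reversal and t >= block.reversal_trial:
            correct = other_mapping(block.initial_mapping)
        else:
            correct = block.initial_mapping
        applied = agent.act(TrialContext(stimuli[t - 1], correct))
        rule_correct = applied == correct
        feedback, valid = draw_feedback(rule_correct, block.reliability, rng)
        agent.observe(feedback)
        phase = PRE_REVERSAL if t < block.phase_boundary else POST_REVERSAL
        records.append(TrialRecord(
            block_index=block.index, trial_index=t,
            stimulus_id=stimuli[t - 1], correct_mapping=correct,
            applied_mapping=applied, rule_correct=rule_correct,
            feedback=feedback, feedback_valid=valid,
            instruction=block.instruction, phase=phase,
            reliability=block.reliability, has_reversal=block.has_reversal))
    return records


class OracleAgent:
    """Always applies the currently correct mapping (design-check baseline)."""

    def start_block(self, block):
        pass

    def act(self, context: TrialContext) -> str:
        return context.correct_mapping

    def observe(self, feedback: str) -> None:
        pass


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records],
                        columns=TRIAL_LOG_COLUMNS)


# --------------------------------------------------------------------------
# Trial-log I/O (tab-delimited text, one row per trial)
# --------------------------------------------------------------------------

def write_trial_log(trials: pd.DataFrame | Sequence[TrialRecord],
                    path: str | Path) -> None:
    if not isinstance(trials, pd.DataFrame):
        trials = records_to_frame(trials)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialLogError(f"trial log missing required columns: {missing}")
    trials.to_csv(path, sep="\t", index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited trial log, validating structure per line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise TrialLogError(f"{path}: empty file")
        columns = header.split("\t")
        missing = [c for c in TRIAL_LOG_COLUMNS if c not in columns]
        if missing:
            raise TrialLogError(
                f"{path}: header missing required columns {missing}")
        n_cols = len(columns)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() == "":
                continue
            if len(line.rstrip("\n").split("\t")) != n_cols:
                raise TrialLogError(
                    f"{path}: line {lineno}: expected {n_cols} fields")
    df = pd.read_csv(path, sep="\t")
    for col in _BOOL_COLUMNS:
        if df[col].dtype != bool:
            mapped = df[col].map({"True": True, "False": False,
                                  True: True, False: False})
            if mapped.isna().any():
                bad = int(df.index[mapped.isna()][0]) + 2
                raise TrialLogError(f"{path}: line {bad}: bad boolean "
                                    f"in column {col!r}")
            df[col] = mapped
    return df
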