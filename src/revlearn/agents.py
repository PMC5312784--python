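"""Learning agents for the instructed reversal task.

Two model families:

* A Bayesian hidden-Markov observer over the two candidate stimulus-response
  mappings.  The hidden state (which mapping is correct) reverses with a
  fixed per-trial hazard ``h``; feedback is a noisy emission that matches the
  rule-correctness of the response with probability ``rho``.  The observer
  tracks the posterior probability ``p`` that its currently applied mapping
  is correct, logs the surprise ``I`` (self-information of each feedback in
  bits) and the belief entropy ``H`` (bits), and abandons its mapping when
  the belief is both unfavourable (p < 0.5) and resolved (H <= alpha).  The
  entropy-aversion threshold alpha is either a single value (instruction-
  blind variant) or chosen per block instruction (instruction-sensitive
  variant) — larger alpha means the agent tolerates less accumulated
  uncertainty before switching, i.e. switches earlier.

* A model-free Rescorla-Wagner learner used as an instruction-blind control:
  one value per mapping, delta-rule updates with learning rate eta on
  rewards coded positive=1 / negative=0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import task_engine as te
from .task_engine import (MAPPING_A, NEGATIVE, POSITIVE, other_mapping)

# --------------------------------------------------------------------------
# Belief arithmetic
# --------------------------------------------------------------------------


def entropy(p: float) -> float:
    """Binary entropy in bits, with 0*log2(0) == 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability out of [0,1]")
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def transition_belief(p: float, h: float) -> float:
    """One step of the hidden-state chain: the belief contracts toward 0.5."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability out of [0,1]")
    if not 0.0 <= h <= 0.5:
        raise ValueError("hazard out of [0,0.5]")
    return p * (1.0 - h) + (1.0 - p) * h


@dataclass(frozen=True)
class BeliefState:
    """Posterior that the applied mapping is correct, with its entropy H and
    the surprise I of the feedback that produced it (both in bits)."""
    p: float
    H: float
    I: float


def update_belief(p_prior: float, feedback: str, rho: float) -> BeliefState:
    """Bayesian update of the belief in the applied mapping.

    Likelihood of the observed feedback is rho under "applied mapping
    correct" for positive feedback (1-rho for negative), and the complement
    under "applied mapping incorrect".  Surprise I is the self-information
    -log2 of the predictive probability of the feedback.
    """
    if not 0.0 <= p_prior <= 1.0:
        raise ValueError("probability out of [0,1]")
    like = rho if feedback == POSITIVE else 1.0 - rho
    like_bar = 1.0 - like
    predictive = p_prior * like + (1.0 - p_prior) * like_bar
    if predictive <= 0.0:
        raise ZeroDivisionError("feedback has zero predictive probability")
    p_post = p_prior * like / predictive
    return BeliefState(p=p_post, H=entropy(p_post),
                       I=-math.log2(predictive))


def decide_mapping(belief: BeliefState, alpha: float,
                   current_mapping: str) -> str:
    """Entropy-aversion switch rule.

    Switch to the alternative mapping iff the belief disfavours the current
    one (p < 0.5) AND its entropy has fallen to the aversion threshold
    (H <= alpha).  Larger alpha therefore produces earlier switching.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha out of [0,1]")
    if belief.p < 0.5 and belief.H <= alpha:
        return other_mapping(current_mapping)
    return current_mapping


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentParams:
    """Parameters shared by the agent variants.

    alpha is the instruction-blind entropy-aversion threshold; alpha_v /
    alpha_s are the thresholds the instruction-sensitive variant applies
    under volatility-type vs stability-type instructions.  h is the assumed
    per-trial reversal hazard, rho the assumed feedback reliability, eta the
    RL learning rate, epsilon the response lapse rate.
    """
    alpha: float = 0.6
    alpha_v: float = 0.7
    alpha_s: float = 0.52
    h: float = 0.03
    rho: float = 0.75
    eta: float = 0.5
    epsilon: float = 0.0

    def __post_init__(self):
        for a in (self.alpha, self.alpha_v, self.alpha_s):
            if not 0.0 <= a <= 1.0:
                raise ValueError("alpha out of [0,1]")
        if not 0.0 <= self.h <= 0.5:
            raise ValueError("hazard out of [0,0.5]")
        if not 0.5 < self.rho <= 1.0:
            raise ValueError("assumed reliability out of (0.5,1]")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("learning rate out of [0,1]")
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError("lapse rate out of [0,0.5]")

    def alpha_for(self, instruction: str, variant: str) -> float:
        if variant == "blind":
            return self.alpha
        if variant == "instruction_sensitive":
            if instruction in (te.VOLATILITY, te.RELIABLE_INSTRUCTED):
                return self.alpha_v
            return self.alpha_s
        raise ValueError(f"unknown variant {variant!r}")


# --------------------------------------------------------------------------
# HMM agent
# --------------------------------------------------------------------------

class HmmAgent:
    """Threshold-switching Bayesian observer.

    Per trial: belief transition (hazard) -> act on the current mapping
    (with optional lapse) -> observe feedback -> Bayes update -> entropy-
    aversion decision for the next trial.  Belief resets to 0.5 at every
    block start (new stimuli, no carry-over).
    """

    def __init__(self, params: AgentParams, variant: str = "blind",
                 lapse_rng: Optional[np.random.Generator] = None):
        self.params = params
        self.variant = variant
        self.lapse_rng = lapse_rng
        self._alpha = params.alpha
        self.p = 0.5
        self.mapping = MAPPING_A
        self.last_belief: Optional[BeliefState] = None

    def start_block(self, block) -> None:
        self.p = 0.5
        self.mapping = MAPPING_A
        self._alpha = self.params.alpha_for(block.instruction, self.variant)
        self.last_belief = None

    def act(self, context) -> str:
        self.p = transition_belief(self.p, self.params.h)
        intended = self.mapping
        if (self.lapse_rng is not None and self.params.epsilon > 0.0
                and self.lapse_rng.random() < self.params.epsilon):
            intended = other_mapping(intended)
        # the agent conditions on what it actually did
        if intended != self.mapping:
            self.p = 1.0 - self.p
            self.mapping = intended
        return intended

    def observe(self, feedback: str) -> None:
        belief = update_belief(self.p, feedback, self.params.rho)
        self.last_belief = belief
        new_mapping = decide_mapping(belief, self._alpha, self.mapping)
        if new_mapping != self.mapping:
            self.p = 1.0 - belief.p
            self.mapping = new_mapping
        else:
            self.p = belief.p


# --------------------------------------------------------------------------
# Model-free RL
# --------------------------------------------------------------------------

@dataclass
class QState:
    """Two-armed value state for the Rescorla-Wagner control model."""
    q: dict = field(default_factory=lambda: {m: 0.5 for m in te.MAPPINGS})
    last_delta: float = 0.0


def rl_step(q: float, reward: float, eta: float) -> tuple[float, float]:
    """One delta-rule update: returns (signed RPE delta, updated value)."""
    delta = reward - q
    return delta, q + eta * delta


def replay_rl(log: pd.DataFrame, eta: float = 0.5,
              q0: float = 0.5) -> np.ndarray:
    """Replay the model-free learner over a trial log.

    Values reset at each block start; only the chosen mapping's value is
    updated.  Returns the per-trial signed RPE.
    """
    deltas = np.empty(len(log), dtype=float)
    state: QState = QState()
    prev_block = None
    for i, row in enumerate(log.itertuples(index=False)):
        if row.block_index != prev_block:
            state = QState(q={m: q0 for m in te.MAPPINGS})
            prev_block = row.block_index
        reward = 1.0 if row.feedback == POSITIVE else 0.0
        delta, q_new = rl_step(state.q[row.applied_mapping], reward, eta)
        state.q[row.applied_mapping] = q_new
        state.last_delta = delta
        deltas[i] = delta
    return deltas


# --------------------------------------------------------------------------
# Subject simulation
# --------------------------------------------------------------------------

def simulate_subject(config: te.ExperimentConfig, params: AgentParams,
                     variant: str = "blind", seed: int = 0,
                     subject_id: Optional[str] = None) -> pd.DataFrame:
    """Simulate one subject through a full experiment schedule.

    Returns the trial log in the task-engine schema plus the model variables
    p (posterior that the applied mapping is correct, post-update), H, I,
    and the model-free RPE delta (eta from ``params``).
    """
    ss = np.random.SeedSequence(seed)
    sched_seed, feedback_seed, lapse_seed = ss.spawn(3)
    schedule = te.build_schedule(config,
                                 seed=int(sched_seed.generate_state(1)[0]))
    feedback_rng = np.random.default_rng(feedback_seed)
    lapse_rng = np.random.default_rng(lapse_seed)
    agent = HmmAgent(params, variant=variant, lapse_rng=lapse_rng)

    frames = []
    for block in schedule:
        beliefs: list[BeliefState] = []

        class _Recorder:
            def start_block(self, b):
                agent.start_block(b)

            def act(self, ctx):
                return agent.act(ctx)

            def observe(self, fb):
                agent.observe(fb)
                beliefs.append(agent.last_belief)

        records = te.run_block(block, _Recorder(), feedback_rng)
        frame = te.records_to_frame(records)
        frame["p"] = [b.p for b in beliefs]
        frame["H"] = [b.H for b in beliefs]
        frame["I"] = [b.I for b in beliefs]
        frames.append(frame)
    log = pd.concat(frames, ignore_index=True)
    log["delta"] = replay_rl(log, eta=params.eta)
    log.insert(0, "subject_id",
               subject_id if subject_id is not None else f"sim{seed:04d}")
    return log


def simulate_group(config: te.ExperimentConfig, params: AgentParams,
                   variant: str, n_subjects: int, seed: int) -> pd.DataFrame:
    """Simulate ``n_subjects`` independent subjects (one sub-seed each)."""
    ss = np.random.SeedSequence(seed)
    logs = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        logs.append(simulate_subject(config, params, variant, seed=sub_seed,
                                     subject_id=f"s{i:02d}"))
    return pd.concat(logs, ignore_index=True)


AGENT_REGISTRY = {
    "hmm_blind": ("blind", HmmAgent),
    "hmm_sensitive": ("instruction_sensitive", HmmAgent),
}
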