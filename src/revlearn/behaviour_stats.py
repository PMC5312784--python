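"""Behavioural measures and statistics for instructed reversal learning.

Measures are computed per subject and instruction condition from trial
logs: accuracy (percent rule-correct responses) before and after the
(actual or notional) reversal point, trials-to-repetition — the number of
trials from a reference point until the correct rule is first applied on
two consecutive trials — the probability of switching the mapping after a
surprising negative feedback (negative feedback on a rule-correct trial),
and the negative-feedback rate.  Group inference uses two-tailed paired
t-tests with Cohen's d for paired data, and 2x2 repeated-measures ANOVAs.

The matched-trial convention of the task design is honoured through the
phase labels in the log: pre-reversal comparisons use the first halves of
all blocks (no-reversal blocks carry a notional midpoint); post-reversal
accuracy contrasts second halves of reversal vs non-reversal blocks.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from . import task_engine as te


# --------------------------------------------------------------------------
# Trial-level measures
# --------------------------------------------------------------------------

def trials_to_repetition(rule_correct_sequence: Sequence[bool]
                         ) -> Optional[int]:
    """1-based index of the second trial of the first pair of consecutive
    rule-correct trials, or None when no such pair exists."""
    seq = list(rule_correct_sequence)
    for i in range(1, len(seq)):
        if seq[i] and seq[i - 1]:
            return i + 1
    return None


def accuracy(log: pd.DataFrame, phase: str,
             instruction: Optional[str] = None,
             reversal_blocks: Optional[bool] = None) -> float:
    """Percent of trials in the selected cell where the applied mapping
    equals the correct mapping.  Returns NaN when the cell is empty."""
    if phase not in (te.PRE_REVERSAL, te.POST_REVERSAL):
        raise ValueError(f"unknown phase {phase!r}")
    sel = log["phase"] == phase
    if instruction is not None:
        sel &= log["instruction"] == instruction
    if reversal_blocks is not None:
        sel &= log["has_reversal"] == reversal_blocks
    if not sel.any():
        return float("nan")
    return 100.0 * float(log.loc[sel, "rule_correct"].mean())


def switch_probability_after_negative(log: pd.DataFrame,
                                      phase: str = te.PRE_REVERSAL,
                                      instruction: Optional[str] = None
                                      ) -> float:
    """P(apply the alternative mapping next | surprising negative feedback).

    Surprising negative feedback = negative feedback on a rule-correct
    trial.  Qualifying trials must have a successor in the same block
    (block-final events are excluded from the denominator).  NaN when no
    trial qualifies.
    """
    n_qual = 0
    n_switch = 0
    for _, block in log.groupby(
            [c for c in ("subject_id", "block_index") if c in log.columns],
            sort=False):
        block = block.sort_values("trial_index")
        if instruction is not None \
                and block["instruction"].iloc[0] != instruction:
            continue
        applied = block["applied_mapping"].to_numpy()
        qualifies = ((block["feedback"] == te.NEGATIVE)
                     & block["rule_correct"]
                     & (block["phase"] == phase)).to_numpy()
        for t in np.flatnonzero(qualifies[:-1]):
            n_qual += 1
            n_switch += applied[t + 1] != applied[t]
    if n_qual == 0:
        return float("nan")
    return n_switch / n_qual


def _block_ttr(block: pd.DataFrame, start: str) -> Optional[int]:
    """Trials-to-repetition from block start or from the first
    post-reversal trial."""
    block = block.sort_values("trial_index")
    if start == "block_start":
        seq = block["rule_correct"].to_numpy()
    elif start == "post_reversal":
        if not bool(block["has_reversal"].iloc[0]):
            return None
        seq = block.loc[block["phase"] == te.POST_REVERSAL,
                        "rule_correct"].to_numpy()
    else:
        raise ValueError(f"unknown reference point {start!r}")
    if len(seq) == 0:
        return None
    return trials_to_repetition(seq)


def mean_trials_to_repetition(log: pd.DataFrame, start: str = "block_start",
                              instruction: Optional[str] = None,
                              block_selector: str = "all"
                              ) -> tuple[float, int]:
    """Mean trials-to-repetition over blocks, with the exclusion count.

    Blocks where the repetition never occurs are excluded from the mean
    (their number is returned alongside).  ``block_selector`` restricts the
    computation to the ``"first"`` or ``"last"`` qualifying reversal block
    per condition, for the early-vs-late instruction-effect contrast.
    """
    values = []
    n_excluded = 0
    keys = [c for c in ("subject_id", "block_index") if c in log.columns]
    blocks = [b for _, b in log.groupby(keys, sort=False)
              if instruction is None or b["instruction"].iloc[0] == instruction]
    if start == "post_reversal" or block_selector != "all":
        blocks = [b for b in blocks if bool(b["has_reversal"].iloc[0])]
    if block_selector == "first":
        blocks = blocks[:1]
    elif block_selector == "last":
        blocks = blocks[-1:]
    elif block_selector != "all":
        raise ValueError(f"unknown block_selector {block_selector!r}")
    for b in blocks:
        ttr = _block_ttr(b, start)
        if ttr is None:
            n_excluded += 1
        else:
            values.append(ttr)
    mean = float(np.mean(values)) if values else float("nan")
    return mean, n_excluded


# --------------------------------------------------------------------------
# Subject x condition summary
# --------------------------------------------------------------------------

def behaviour_summary(log: pd.DataFrame) -> pd.DataFrame:
    """The study's behavioural measures per subject x instruction."""
    if "subject_id" not in log.columns:
        log = log.assign(subject_id="subject")
    rows = []
    for (sid, instr), sub in log.groupby(["subject_id", "instruction"],
                                         sort=True):
        ttr_i, excl_i = mean_trials_to_repetition(sub, "block_start")
        ttr_p, excl_p = mean_trials_to_repetition(sub, "post_reversal")
        pre = sub["phase"] == te.PRE_REVERSAL
        rows.append({
            "subject_id": sid,
            "instruction": instr,
            "accuracy_pre": accuracy(sub, te.PRE_REVERSAL),
            "accuracy_post": accuracy(sub, te.POST_REVERSAL,
                                      reversal_blocks=True),
            "accuracy_post_no_reversal": accuracy(sub, te.POST_REVERSAL,
                                                  reversal_blocks=False),
            "ttr_initial": ttr_i,
            "ttr_post": ttr_p,
            "ttr_excluded_initial": excl_i,
            "ttr_excluded_post": excl_p,
            "p_switch_after_negative":
                switch_probability_after_negative(sub),
            "negative_feedback_rate":
                100.0 * float((sub.loc[pre, "feedback"]
                               == te.NEGATIVE).mean()) if pre.any()
                else float("nan"),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Group statistics
# --------------------------------------------------------------------------

def paired_t(x: Sequence[float], y: Sequence[float]
             ) -> tuple[float, int, float]:
    """Two-tailed paired-sample t-test: returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired test needs >= 2 complete pairs")
    diff = x - y
    if diff.std(ddof=1) == 0.0 and diff.mean() == 0.0:
        return 0.0, len(x) - 1, 1.0     # identical samples: no effect
    res = stats.ttest_rel(x, y)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def cohen_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d for paired data: mean difference / SD of the differences."""
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if len(diff) < 2:
        raise ValueError("paired effect size needs >= 2 pairs")
    sd = diff.std(ddof=1)
    if sd == 0.0:
        return 0.0
    return float(diff.mean() / sd)


def rm_anova_2x2(cells: pd.DataFrame, dv: str, within: Sequence[str],
                 subject: str = "subject_id") -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on a long-format complete-cell table.

    Returns one row per effect (two main effects and the interaction) with
    columns F, df1, df2, p.
    """
    if cells[dv].isna().any():
        raise ValueError("incomplete cells: NaN in dependent variable")
    res = AnovaRM(cells, depvar=dv, subject=subject,
                  within=list(within)).fit()
    table = res.anova_table.rename(columns={
        "F Value": "F", "Num DF": "df1", "Den DF": "df2", "Pr > F": "p"})
    return table[["F", "df1", "df2", "p"]]
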