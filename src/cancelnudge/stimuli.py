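"""Published stimulus sets for the four framing experiments.

These fixtures are the exact experimental materials: a single voucher
pair for the field experiment, 20 gain pairs and 20 loss pairs for the
two lab experiments (each with its published per-condition choice rates,
kept here as reference data), the 20 convex-time-budget allocation
tasks, and the 9-option retirement-benefit menu in both framings.

Conventions: all delays in days; the partitioned ("cancellation")
presentation of a gain pair separates the full earlier amount as the
common component (e.g. $3 + $0 today vs $3 + $1 in a week); loss pairs
separate the smaller earlier loss the same way, against a $10 endowment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import pandas as pd

from .cbs import CBSTask
from .model import ChoicePair, Domain, TimedAmount

__all__ = [
    "MenuOption",
    "experiment1_pair",
    "experiment1_summary",
    "experiment2_stimuli",
    "experiment2_results_table",
    "experiment3_stimuli",
    "experiment3_results_table",
    "experiment4_menu",
    "experiment4_choice_shares",
    "cbt_tasks",
    "LOSS_ENDOWMENT",
]

LOSS_ENDOWMENT = 10.0

# field experiment: $2 voucher today vs $3 voucher in a week; the
# cancellation presentation separates a common $1 voucher.
_EXP1 = dict(earlier=2.0, later=3.0, common=1.0)

# published summary statistics of the field experiment (inputs for
# reconstructing the underlying counts from the printed report)
_EXP1_SUMMARY = dict(
    n_total=147,
    pct_later_cancellation=77.8,
    pct_later_baseline=52.0,
    ci_cancellation=(66.9, 85.8),
    ci_baseline=(40.9, 62.9),
)

# gains: (row, earlier, later, t, baseline %, cancellation %, Fisher p)
_TABLE1 = [
    (1, 3, 4, 0, 65.0, 94.29, 0.002),
    (2, 4, 5, 0, 67.5, 91.43, 0.02),
    (3, 5, 6, 0, 67.5, 94.29, 0.004),
    (4, 7, 8, 0, 67.5, 94.29, 0.004),
    (5, 8, 9, 0, 65.0, 88.57, 0.03),
    (6, 3, 5, 0, 85.0, 94.29, 0.27),
    (7, 4, 6, 0, 85.0, 97.14, 0.11),
    (8, 5, 7, 0, 87.5, 97.14, 0.21),
    (9, 7, 9, 0, 85.0, 94.29, 0.27),
    (10, 8, 10, 0, 85.0, 94.29, 0.27),
    (11, 3, 4, 7, 42.5, 77.14, 0.004),
    (12, 4, 5, 7, 45.0, 74.29, 0.02),
    (13, 5, 6, 7, 45.0, 77.14, 0.005),
    (14, 7, 8, 7, 45.0, 77.14, 0.005),
    (15, 8, 9, 7, 50.0, 77.14, 0.02),
    (16, 3, 5, 7, 80.0, 88.57, 0.36),
    (17, 4, 6, 7, 82.5, 91.43, 0.32),
    (18, 5, 7, 7, 80.0, 85.71, 0.56),
    (19, 7, 9, 7, 77.5, 91.43, 0.12),
    (20, 8, 10, 7, 80.0, 82.86, 0.77),
]

# losses: (row, earlier_loss, later_loss, t, baseline %, cancellation %, Fisher p)
# A Fisher p of None marks the row where both observed rates were zero.
_TABLE3 = [
    (1, 6, 7, 0, 20.37, 11.54, 0.29),
    (2, 5, 6, 0, 12.96, 5.77, 0.32),
    (3, 4, 5, 0, 11.11, 5.77, 0.48),
    (4, 2, 3, 0, 5.56, 1.92, 0.61),
    (5, 1, 2, 0, 9.26, 3.85, 0.43),
    (6, 5, 7, 0, 7.41, 1.92, 0.36),
    (7, 4, 6, 0, 5.56, 0.0, 0.24),
    (8, 3, 5, 0, 3.70, 0.0, 0.49),
    (9, 1, 3, 0, 0.0, 0.0, None),
    (10, 0, 2, 0, 1.85, 1.92, 1.0),
    (11, 6, 7, 7, 16.67, 3.85, 0.05),
    (12, 5, 6, 7, 9.26, 1.92, 0.20),
    (13, 4, 5, 7, 22.22, 0.0, 0.001),
    (14, 2, 3, 7, 7.41, 0.0, 0.11),
    (15, 1, 2, 7, 5.56, 1.92, 0.61),
    (16, 5, 7, 7, 5.56, 1.92, 0.61),
    (17, 4, 6, 7, 3.70, 0.0, 0.49),
    (18, 3, 5, 7, 1.85, 0.0, 1.0),
    (19, 1, 3, 7, 1.85, 0.0, 1.0),
    (20, 0, 2, 7, 0.0, 5.77, 0.11),
]

# retirement menu: age, annual benefit (baseline frame), supplement
# (cancellation frame; base held at $9400), and the published percentage
# of under-62 respondents choosing each start age per condition.
_TABLE4 = [
    (62, 9400, 0, 16, 6),
    (63, 10000, 600, 5, 6),
    (64, 10700, 1300, 4, 4),
    (65, 11600, 2200, 16, 14),
    (66, 12500, 3100, 19, 11),
    (67, 13400, 4000, 12, 18),
    (68, 14400, 5000, 7, 7),
    (69, 15500, 6100, 1, 2),
    (70, 16600, 7100, 20, 32),
]

_RETIREMENT_BASE = 9400.0

# convex-time-budget token values (early, late), 50 tokens per task
_CBT_PAIRS = [(0.19, 0.20), (0.18, 0.20), (0.16, 0.20), (0.14, 0.20), (0.20, 0.25)]


@dataclass(frozen=True)
class MenuOption:
    """One row of the retirement-claiming menu."""

    start_age: int
    base_benefit: float
    supplement: float

    @property
    def total_benefit(self) -> float:
        return self.base_benefit + self.supplement


def experiment1_pair() -> ChoicePair:
    """The cafeteria voucher pair: $2 today vs $3 in a week, common $1."""
    return ChoicePair(
        earlier=TimedAmount(_EXP1["earlier"], 0),
        later=TimedAmount(_EXP1["later"], 7),
        common_amount=_EXP1["common"],
    )


def experiment1_summary() -> dict:
    """Published summary statistics of the field experiment.

    Per-condition later-choice percentages (1 decimal place), total N,
    and the printed Wilson 95% CIs — enough to reconstruct the
    underlying 2x2 counts exactly.
    """
    return dict(_EXP1_SUMMARY)


def experiment2_stimuli() -> List[ChoicePair]:
    """The 20 gain pairs (k = 7 days; t in {0, 7}; common = earlier amount)."""
    pairs = []
    for _, x0, xk, t, *_ in _TABLE1:
        pairs.append(ChoicePair(
            earlier=TimedAmount(float(x0), t),
            later=TimedAmount(float(xk), t + 7),
            common_amount=float(x0),
        ))
    return pairs


def experiment2_results_table() -> pd.DataFrame:
    """Published per-row choice rates for the gain experiment."""
    return pd.DataFrame(
        _TABLE1,
        columns=["row", "earlier", "later", "t_days",
                 "pct_later_baseline", "pct_later_cancellation", "fisher_p"],
    )


def experiment3_stimuli() -> List[ChoicePair]:
    """The 20 loss pairs against the $10 endowment (common = earlier loss)."""
    pairs = []
    for _, le, ll, t, *_ in _TABLE3:
        pairs.append(ChoicePair(
            earlier=TimedAmount(float(le), t),
            later=TimedAmount(float(ll), t + 7),
            common_amount=float(le),
            domain=Domain.LOSS,
            endowment=LOSS_ENDOWMENT,
        ))
    return pairs


def experiment3_results_table() -> pd.DataFrame:
    """Published per-row later-loss rates for the loss experiment."""
    return pd.DataFrame(
        _TABLE3,
        columns=["row", "earlier_loss", "later_loss", "t_days",
                 "pct_later_baseline", "pct_later_cancellation", "fisher_p"],
    )


def experiment4_menu(frame: str = "baseline") -> List[MenuOption]:
    """The 9-option retirement menu.

    In the baseline frame each age carries a single benefit figure; in
    the cancellation frame the age-62 benefit ($9400) is held constant
    as the base and only the supplement varies.
    """
    opts = []
    for age, benefit, supplement, _, _ in _TABLE4:
        if frame == "baseline":
            opts.append(MenuOption(age, float(benefit), 0.0))
        elif frame == "cancellation":
            opts.append(MenuOption(age, _RETIREMENT_BASE, float(supplement)))
        else:
            raise ValueError(f"unknown frame {frame!r}")
    return opts


def experiment4_choice_shares(condition: str) -> dict[int, float]:
    """Published percentage of respondents choosing each start age."""
    col = {"baseline": 3, "cancellation": 4}[condition]
    return {row[0]: float(row[col]) for row in _TABLE4}


def cbt_tasks() -> List[CBSTask]:
    """The 20 convex-time-budget tasks: 5 token-value pairs x t in {0, 7}
    x k in {35, 70}, 50 tokens each."""
    tasks = []
    task_id = 0
    for t in (0, 7):
        for k in (35, 70):
            for a_t, a_tk in _CBT_PAIRS:
                tasks.append(CBSTask(a_t=a_t, a_tk=a_tk, t_days=t,
                                     k_days=k, task_id=task_id))
                task_id += 1
    return tasks
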