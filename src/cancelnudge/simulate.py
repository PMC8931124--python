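"""Simulated runs of the four framing experiments on synthetic agents.

Each simulator drives the decision model over a stimulus set and emits
tidy trial-level tables (one row per agent x stimulus) matching the
fixed CSV layouts consumed by the statistical layer. Condition
assignment is between-subjects, as in the experiments themselves: a
caller assigns each agent a single frame (the pipeline splits a
population at random and runs each half under one frame).
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .cbs import CBSTask, foc_allocation
from .model import ChoicePair, Domain, Frame, Preferences, instant_utility, prob_later
from .stimuli import MenuOption

__all__ = [
    "simulate_binary_experiment",
    "simulate_cbs",
    "simulate_retirement",
    "write_trials_csv",
    "write_allocations_csv",
    "write_population_csv",
    "population_frame",
]

TRIALS_COLUMNS = [
    "subject_id", "condition", "trial_id", "earlier_amount", "later_amount",
    "earlier_delay_days", "later_delay_days", "common_amount", "domain",
    "t0", "choice_later",
]
ALLOCATIONS_COLUMNS = [
    "subject_id", "task_id", "a_t", "a_tk", "t_days", "k_days", "tokens_early",
]
POPULATION_COLUMNS = ["subject_id", "alpha", "beta", "delta"]

_CONDITION_OF_FRAME = {Frame.INTEGRATED: "baseline", Frame.PARTITIONED: "cancellation"}


def simulate_binary_experiment(
    population: Sequence[Preferences],
    stimuli: Sequence[ChoicePair],
    frame: Union[Frame, str],
    seed: int = 0,
    subject_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """One trial record per agent x pair, all agents under one frame.

    Deterministic given the seed; the seed only matters for agents with
    a positive noise temperature.
    """
    frame = Frame(frame)
    condition = _CONDITION_OF_FRAME[frame]
    framed = [p.with_frame(frame) for p in stimuli]
    if subject_ids is None:
        subject_ids = range(len(population))
    rng = np.random.default_rng(seed)
    rows = []
    for sid, prefs in zip(subject_ids, population):
        for trial_id, pair in enumerate(framed):
            p = prob_later(pair, prefs)
            choice = int(rng.random() < p) if prefs.noise_temperature > 0 \
                else int(p >= 0.5)
            rows.append((
                sid, condition, trial_id,
                pair.earlier.amount, pair.later.amount,
                pair.earlier.delay_days, pair.later.delay_days,
                pair.common_amount, pair.domain.value,
                int(pair.earlier.delay_days == 0), choice,
            ))
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


def simulate_cbs(
    population: Sequence[Preferences],
    tasks: Sequence[CBSTask],
    integer_rounding: bool = False,
    seed: int = 0,
    subject_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Utility-maximizing token allocations for every agent x task.

    Allocations are the continuous FOC solutions by default; with
    ``integer_rounding`` they are rounded to the nearest whole token to
    mimic real responses. (The seed argument is accepted for interface
    symmetry; the allocation rule itself is deterministic.)
    """
    del seed
    if subject_ids is None:
        subject_ids = range(len(population))
    rows = []
    for sid, prefs in zip(subject_ids, population):
        for task in tasks:
            n = foc_allocation(prefs, task)
            if integer_rounding:
                n = float(np.round(n))
            rows.append((sid, task.task_id, task.a_t, task.a_tk,
                         task.t_days, task.k_days, n))
    return pd.DataFrame(rows, columns=ALLOCATIONS_COLUMNS)


def _stream_value(prefs: Preferences, annual_amount: float,
                  start_age: int, horizon_age: int, decision_age: int = 62) -> float:
    """Discounted CRRA value of an annual payment stream.

    Payments of ``annual_amount`` arrive each year from ``start_age``
    through ``horizon_age`` inclusive; a payment due ``j`` years after
    the decision is discounted by delta**(365 j), with the present-bias
    multiplier applied to every non-immediate payment.
    """
    u = instant_utility(annual_amount, prefs.alpha)
    total = 0.0
    for age in range(start_age, horizon_age + 1):
        t_days = 365 * (age - decision_age)
        w = prefs.delta ** t_days
        if t_days > 0:
            w *= prefs.beta
        total += w * u
    return total


def simulate_retirement(
    population: Sequence[Preferences],
    menu: Sequence[MenuOption],
    frame: Union[Frame, str],
    horizon_age: int = 85,
) -> np.ndarray:
    """Chosen benefit start age for each agent.

    Baseline frame: each agent maximizes the discounted utility of the
    full annual benefit stream from the start age to the horizon.
    Cancellation frame: the constant base payment is mentally cancelled
    across all options first, so only the supplement stream is valued
    (the predicted mental representation of the partitioned menu).
    Ties go to the later start age. The valuation model (and its
    default 85-year horizon) is this package's own extension; the menu
    itself specifies no valuation rule.
    """
    frame = Frame(frame)
    if not menu:
        raise ValueError("menu must contain at least one option")
    if horizon_age <= max(o.start_age for o in menu):
        raise ValueError("horizon_age must exceed the latest start age")
    ages = np.empty(len(population), dtype=int)
    for idx, prefs in enumerate(population):
        best_age, best_val = None, -np.inf
        for opt in menu:
            amount = opt.supplement if frame is Frame.PARTITIONED \
                else opt.total_benefit
            val = _stream_value(prefs, amount, opt.start_age, horizon_age)
            if val >= best_val:  # >= implements the later-age tie rule
                best_age, best_val = opt.start_age, val
        ages[idx] = best_age
    return ages


def population_frame(population: Iterable[Preferences],
                     subject_ids: Sequence[int] | None = None) -> pd.DataFrame:
    population = list(population)
    if subject_ids is None:
        subject_ids = range(len(population))
    return pd.DataFrame(
        [(sid, p.alpha, p.beta, p.delta)
         for sid, p in zip(subject_ids, population)],
        columns=POPULATION_COLUMNS,
    )


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.loc[:, TRIALS_COLUMNS].to_csv(path, index=False)


def write_allocations_csv(allocations: pd.DataFrame, path) -> None:
    allocations.loc[:, ALLOCATIONS_COLUMNS].to_csv(path, index=False)


def write_population_csv(population: pd.DataFrame, path) -> None:
    population.loc[:, POPULATION_COLUMNS].to_csv(path, index=False)
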