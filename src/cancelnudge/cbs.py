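"""Convex-time-budget (CTB) allocation and structural estimation.

In a CTB task an agent splits a 50-token budget between an earlier date
(token value ``a_t``) and a later date ``k`` days further out (token
value ``a_tk > a_t``). Under the beta-delta CRRA model the optimal
interior split satisfies the first-order condition

    (c_t / c_{t+k})**(alpha - 1) = beta**I * delta**k * (a_tk / a_t)

with c_t = n * a_t, c_{t+k} = (50 - n) * a_tk and I = 1 iff t = 0.
Taking logs linearizes the condition in the task design variables,

    ln(c_t / c_{t+k}) = b0 * I + b1 * k + b2 * ln(a_tk / a_t),

so a least-squares fit over a subject's interior allocations exactly
identifies the preferences via alpha = 1 + 1/b2, delta = exp(b1/b2),
beta = exp(b0/b2). Corner allocations (all tokens on one date) do not
satisfy the FOC and are excluded from the fit but counted. Subjects
whose choices are too price-inelastic to be consistent with concave
utility come out with a negative alpha-hat; the estimate is reported
and flagged — never clipped — and a filter drops flagged subjects
before any downstream regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import Preferences

__all__ = [
    "CBSTask",
    "AllocationRecord",
    "EstimationResult",
    "foc_allocation",
    "estimate_preferences",
    "estimate_all",
    "exclusion_filter",
    "write_estimates_csv",
]

_CORNER_TOL = 1e-6


@dataclass(frozen=True)
class CBSTask:
    """One convex-time-budget menu."""

    a_t: float
    a_tk: float
    t_days: int
    k_days: int
    budget_tokens: float = 50.0
    task_id: int = 0

    def __post_init__(self) -> None:
        if not self.a_tk > self.a_t > 0:
            raise ValueError("requires a_tk > a_t > 0")
        if self.t_days < 0 or self.k_days < 1:
            raise ValueError("requires t_days >= 0 and k_days >= 1")
        if self.budget_tokens <= 0:
            raise ValueError("budget_tokens must be > 0")


@dataclass(frozen=True)
class AllocationRecord:
    """Observed tokens placed on the earlier date for one task."""

    task: CBSTask
    tokens_early: float

    def __post_init__(self) -> None:
        if not 0 <= self.tokens_early <= self.task.budget_tokens:
            raise ValueError("tokens_early must lie in [0, budget_tokens]")


@dataclass(frozen=True)
class EstimationResult:
    """Per-subject structural estimates from CTB allocations."""

    alpha_hat: float
    beta_hat: float
    delta_hat: float
    n_interior: int
    n_corner: int
    residual_sse: float
    subject_id: int = -1

    @property
    def negative_alpha_flag(self) -> bool:
        return self.alpha_hat < 0


def foc_allocation(prefs: Preferences, task: CBSTask) -> float:
    """Utility-maximizing tokens on the earlier date.

    Interior solution of the FOC for alpha < 1; for linear utility
    (alpha = 1) the optimum is a corner decided by comparing the
    discounted per-token returns (ties go to the later date). The
    result is clamped to [0, budget].
    """
    i = 1 if task.t_days == 0 else 0
    gross = (prefs.beta ** i) * prefs.delta ** task.k_days * task.a_tk
    if prefs.alpha == 1.0:
        return 0.0 if gross >= task.a_t else task.budget_tokens
    # consumption ratio c_t / c_{t+k} implied by the FOC, in logs so that
    # alpha -> 1 degrades gracefully into the linear-utility corner
    log_ratio = np.log(gross / task.a_t) / (prefs.alpha - 1.0)
    if log_ratio > 700.0:
        return task.budget_tokens
    if log_ratio < -700.0:
        return 0.0
    ratio = np.exp(log_ratio)
    n = task.budget_tokens * ratio * task.a_tk / (task.a_t + ratio * task.a_tk)
    return float(np.clip(n, 0.0, task.budget_tokens))


def _is_interior(rec: AllocationRecord) -> bool:
    return _CORNER_TOL < rec.tokens_early < rec.task.budget_tokens - _CORNER_TOL


def estimate_preferences(records: Sequence[AllocationRecord],
                         subject_id: int = -1) -> EstimationResult:
    """Least-squares fit of the log-linearized FOC with exact inversion.

    Requires at least 3 interior allocations spanning both values of the
    immediacy indicator and at least two k values; raises ValueError for
    under-identified or all-corner data.
    """
    interior = [r for r in records if _is_interior(r)]
    n_corner = len(records) - len(interior)
    if len(interior) < 3:
        raise ValueError(
            f"under-identified: {len(interior)} interior allocations (need >= 3)")
    ts = {r.task.t_days == 0 for r in interior}
    ks = {r.task.k_days for r in interior}
    if len(ts) < 2 or len(ks) < 2:
        raise ValueError(
            "under-identified: interior allocations must span both immediacy "
            "values and at least two delay lengths k")

    y = np.array([
        np.log((r.tokens_early * r.task.a_t)
               / ((r.task.budget_tokens - r.tokens_early) * r.task.a_tk))
        for r in interior
    ])
    X = np.array([
        [1.0 if r.task.t_days == 0 else 0.0,
         float(r.task.k_days),
         np.log(r.task.a_tk / r.task.a_t)]
        for r in interior
    ])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    b0, b1, b2 = coef
    if b2 == 0:
        raise ValueError("degenerate fit: no price response (b2 = 0)")
    sse = float(np.sum((y - X @ coef) ** 2))
    return EstimationResult(
        alpha_hat=float(1.0 + 1.0 / b2),
        beta_hat=float(np.exp(b0 / b2)),
        delta_hat=float(np.exp(b1 / b2)),
        n_interior=len(interior),
        n_corner=n_corner,
        residual_sse=sse,
        subject_id=subject_id,
    )


def estimate_all(allocations: pd.DataFrame) -> pd.DataFrame:
    """Estimate preferences subject by subject from an allocations table.

    Expects the ``allocations.csv`` layout (subject_id, task_id, a_t,
    a_tk, t_days, k_days, tokens_early). Returns the ``estimates.csv``
    layout; subjects whose data are under-identified are skipped with
    a note column rather than aborting the batch.
    """
    rows = []
    for sid, grp in allocations.groupby("subject_id"):
        recs = [
            AllocationRecord(
                task=CBSTask(a_t=row.a_t, a_tk=row.a_tk, t_days=int(row.t_days),
                             k_days=int(row.k_days), task_id=int(row.task_id)),
                tokens_early=float(row.tokens_early),
            )
            for row in grp.itertuples()
        ]
        try:
            res = estimate_preferences(recs, subject_id=int(sid))
        except ValueError:
            continue
        rows.append({
            "subject_id": res.subject_id,
            "alpha_hat": res.alpha_hat,
            "beta_hat": res.beta_hat,
            "delta_hat": res.delta_hat,
            "n_interior": res.n_interior,
            "n_corner": res.n_corner,
            "negative_alpha_flag": res.negative_alpha_flag,
        })
    return pd.DataFrame(rows, columns=[
        "subject_id", "alpha_hat", "beta_hat", "delta_hat",
        "n_interior", "n_corner", "negative_alpha_flag",
    ])


def exclusion_filter(results: Iterable[EstimationResult],
                     ) -> Tuple[List[EstimationResult], int]:
    """Drop negative-alpha subjects before downstream analysis.

    Returns (retained results, number excluded). An empty retained set
    is legal but warned about.
    """
    results = list(results)
    retained = [r for r in results if not r.negative_alpha_flag]
    n_excluded = len(results) - len(retained)
    if results and not retained:
        import warnings
        warnings.warn("all subjects flagged with negative alpha; nothing retained")
    return retained, n_excluded


def write_estimates_csv(estimates: pd.DataFrame, path) -> None:
    cols = ["subject_id", "alpha_hat", "beta_hat", "delta_hat",
            "n_interior", "n_corner", "negative_alpha_flag"]
    estimates.loc[:, cols].to_csv(path, index=False)
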