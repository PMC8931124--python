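"""Statistical layer: contingency tests, effect sizes, rank tests,
power analysis, count reconstruction, and OLS moderation.

The implementations follow the exact textbook variants used in the
experiments being replicated: the *uncorrected* Pearson chi-square (no
Yates continuity correction), the two-sided Fisher exact test summing
hypergeometric probabilities no larger than the observed table's, the
Mann-Whitney U with mid-ranks and a tie-corrected normal approximation,
Cohen's w = sqrt(chi2/N) and Cohen's d with the (n-1)-weighted pooled
SD, one-tailed df=1 chi-square sizing via the equivalent one-sided
two-proportion z-test, and two-sample t sizing by exact noncentral-t
power iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "Chi2Result",
    "MannWhitneyResult",
    "PowerSpec",
    "ReconstructionResult",
    "pearson_chi2",
    "fisher_exact_2x2",
    "mann_whitney",
    "cohen_d_pooled",
    "cohen_d_from_samples",
    "wilson_ci",
    "required_n",
    "required_n_chi2_df1",
    "required_n_two_sample_t",
    "weighted_mean_age",
    "reconstruct_counts",
    "ols_moderation",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = condition and columns = (later, earlier)."""

    a: int  # condition 1, later
    b: int  # condition 1, earlier
    c: int  # condition 2, later
    d: int  # condition 2, earlier

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> Tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    w: float
    dof: int
    n: int


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    z: float
    p: float


def pearson_chi2(table: ContingencyTable2x2) -> Chi2Result:
    """Uncorrected Pearson chi-square and Cohen's w for a 2x2 table."""
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        raise ValueError("chi-square undefined with a zero margin")
    num = table.n * (table.a * table.d - table.b * table.c) ** 2
    stat = num / (r1 * r2 * c1 * c2)
    return Chi2Result(statistic=stat, w=math.sqrt(stat / table.n),
                      dof=1, n=table.n)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    all tables with the observed margins that are no more probable than
    the observed one."""
    r1, r2, c1, _ = table.margins
    if 0 in table.margins:
        raise ValueError("Fisher test undefined with a zero margin")
    n = table.n
    rv = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(table.a)
    # relative tolerance guards against ties broken by rounding noise
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0)


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 method: str = "asymptotic") -> MannWhitneyResult:
    """Mann-Whitney U with mid-ranks and a two-sided p.

    U is reported for the first sample; z carries the sign of
    (U - its null mean), so a positive z means the first sample tends
    to be larger. ``method="asymptotic"`` (the default, and the variant
    the replication analyses use) takes the tie-corrected normal
    approximation; ``method="exact"`` enumerates every assignment of
    the pooled observations to the two groups (a permutation-exact p,
    valid with ties, limited to small samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # mid-ranks for ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        z = 0.0
    else:
        z = (u1 - mean_u) / math.sqrt(var_u)
    if method == "asymptotic":
        p = 2.0 * sps.norm.sf(abs(z)) if var_u > 0 else 1.0
    elif method == "exact":
        if n > 14:
            raise ValueError("exact enumeration limited to n1 + n2 <= 14")
        from itertools import combinations
        obs_dev = abs(u1 - mean_u)
        hits = total = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n), n1):
            u = ranks[list(idx)].sum() - offset
            total += 1
            hits += abs(u - mean_u) >= obs_dev - 1e-12
        p = hits / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return MannWhitneyResult(u=float(u1), z=float(z), p=float(min(p, 1.0)))


def cohen_d_pooled(mean1: float, sd1: float, n1: int,
                   mean2: float, sd2: float, n2: int) -> float:
    """Cohen's d with the (n-1)-weighted pooled standard deviation."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("sds must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    pooled_var = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD")
    return (mean1 - mean2) / math.sqrt(pooled_var)


def cohen_d_from_samples(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohen_d_pooled(x.mean(), x.std(ddof=1), x.size,
                          y.mean(), y.std(ddof=1), y.size)


def wilson_ci(successes: int, n: int, conf: float = 0.95) -> Tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if not 0 <= successes <= n or n == 0:
        raise ValueError("requires 0 <= successes <= n, n > 0")
    z = sps.norm.ppf(0.5 + conf / 2.0)
    p = successes / n
    denom = 1 + z ** 2 / n
    center = (p + z ** 2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return (center - half, center + half)


@dataclass(frozen=True)
class PowerSpec:
    """A priori sample-size specification."""

    family: str  # "chi2_df1" or "two_sample_t"
    effect_size: float  # Cohen's w or |d|
    alpha_level: float = 0.05
    tails: int = 2
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.family not in ("chi2_df1", "two_sample_t"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def required_n_chi2_df1(w: float, alpha: float = 0.05, power: float = 0.80,
                        tails: int = 2) -> int:
    """Total N for a df=1 chi-square (two-proportion) comparison.

    One-tailed: the closed-form one-sided two-proportion z-test size,
    N = ceil(((z_{1-alpha} + z_{power}) / w)**2). Two-tailed: smallest N
    whose noncentral chi-square power (df=1, lambda = N w^2) at the
    central critical value reaches the target.
    """
    PowerSpec("chi2_df1", w, alpha, tails, power)  # validate
    if tails == 1:
        z = sps.norm.ppf(1 - alpha) + sps.norm.ppf(power)
        return int(math.ceil((z / w) ** 2))
    crit = sps.chi2.ppf(1 - alpha, df=1)
    n = 2
    while sps.ncx2.sf(crit, df=1, nc=n * w * w) < power:
        n += 1
    return n


def required_n_two_sample_t(d: float, alpha: float = 0.05,
                            power: float = 0.80, tails: int = 2) -> int:
    """Per-group n for a two-sample t-test, by exact noncentral-t power.

    Iterates n upward; at each n the power of the (one- or two-sided)
    test at level alpha is computed under the noncentral t with
    noncentrality |d| sqrt(n/2) and df = 2n - 2.
    """
    d = abs(d)
    PowerSpec("two_sample_t", d, alpha, tails, power)  # validate
    n = 2
    while True:
        df = 2 * n - 2
        ncp = d * math.sqrt(n / 2.0)
        if tails == 2:
            crit = sps.t.ppf(1 - alpha / 2, df)
            pw = sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp)
        else:
            crit = sps.t.ppf(1 - alpha, df)
            pw = sps.nct.sf(crit, df, ncp)
        if pw >= power:
            return n
        n += 1


def required_n(spec: PowerSpec) -> int:
    """Dispatch on the test family; chi2_df1 returns total N,
    two_sample_t returns n per group."""
    if spec.family == "chi2_df1":
        return required_n_chi2_df1(spec.effect_size, spec.alpha_level,
                                   spec.target_power, spec.tails)
    return required_n_two_sample_t(spec.effect_size, spec.alpha_level,
                                   spec.target_power, spec.tails)


def weighted_mean_age(distribution: Mapping[int, float],
                      tol: float = 1.0) -> float:
    """Percentage-weighted mean start age; percentages must total
    100 +/- tol (rounding slack)."""
    if not distribution:
        raise ValueError("empty distribution")
    total = float(sum(distribution.values()))
    if abs(total - 100.0) > tol:
        raise ValueError(f"percentages sum to {total}, expected ~100")
    return sum(age * pct for age, pct in distribution.items()) / total


@dataclass(frozen=True)
class ReconstructionResult:
    tables: Tuple[ContingencyTable2x2, ...]
    unique: bool

    @property
    def table(self) -> ContingencyTable2x2:
        if not self.unique:
            raise ValueError(
                f"{len(self.tables)} candidate tables; reconstruction not unique")
        return self.tables[0]


def reconstruct_counts(
    pct_condition1: float,
    pct_condition2: float,
    total_n: int,
    decimal_places: int = 1,
    printed_cis: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None,
) -> ReconstructionResult:
    """Recover 2x2 counts from rounded per-condition percentages.

    Enumerates every split of ``total_n`` into two condition sizes and
    every count whose percentage rounds (at ``decimal_places``) to the
    printed value. When ``printed_cis`` is given — the two published
    Wilson 95% CIs in percent, rounded to the same precision — only
    candidates reproducing those CIs are kept, which typically makes
    the solution unique. Raises if no consistent table exists.
    """
    def matches(count: int, size: int, target: float) -> bool:
        return round(100.0 * count / size, decimal_places) == round(
            target, decimal_places)

    def ci_matches(count: int, size: int, target: Tuple[float, float]) -> bool:
        lo, hi = wilson_ci(count, size)
        return (round(100 * lo, decimal_places) == round(target[0], decimal_places)
                and round(100 * hi, decimal_places) == round(target[1], decimal_places))

    candidates: List[ContingencyTable2x2] = []
    for n1 in range(1, total_n):
        n2 = total_n - n1
        hits1 = [a for a in range(n1 + 1) if matches(a, n1, pct_condition1)]
        if not hits1:
            continue
        hits2 = [c for c in range(n2 + 1) if matches(c, n2, pct_condition2)]
        for a in hits1:
            for c in hits2:
                if printed_cis is not None:
                    if not (ci_matches(a, n1, printed_cis[0])
                            and ci_matches(c, n2, printed_cis[1])):
                        continue
                candidates.append(ContingencyTable2x2(a, n1 - a, c, n2 - c))
    if not candidates:
        raise ValueError("no table consistent with the printed percentages")
    return ReconstructionResult(tables=tuple(candidates),
                                unique=len(candidates) == 1)


def ols_moderation(data: pd.DataFrame, outcome: str = "chosen_age",
                   condition: str = "cancellation",
                   covariates: Sequence[str] = ("age", "income")):
    """OLS of the outcome on condition, covariates, and their
    condition interactions; returns the fitted statsmodels results.

    Warns (statsmodels condition-number machinery) rather than failing
    on near-collinear designs.
    """
    for col in (outcome, condition, *covariates):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
        if data[col].isna().any():
            raise ValueError(f"column {col!r} has missing values")
    terms = [condition] + [f"{c} * {condition}" for c in covariates]
    formula = f"{outcome} ~ " + " + ".join(terms)
    return smf.ols(formula, data=data).fit()
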