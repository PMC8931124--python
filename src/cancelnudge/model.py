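"""Decision model: CRRA utility, beta-delta discounting, cancellation framing.

An agent evaluates a timed payoff ``x`` delivered after ``t`` days as
``D(t) * u(x)`` with the power (CRRA) kernel ``u(x) = x**alpha / alpha``
(``0 < alpha <= 1``) and quasi-hyperbolic discounting
``D(t) = delta**t``, with the present-bias multiplier ``beta`` applied to
the *delayed* option only when the earlier option is immediate (t = 0).

In a binary choice between a smaller-earlier amount ``x0`` and a
larger-later amount ``xk`` (``k`` days further out), the agent picks the
later amount iff ``delta >= delta_star``, where

    delta_star = [ (1/beta) * (x0/xk)**alpha ] ** (1/k)

Partitioned ("cancellation") framing splits both amounts into a seemingly
identical component ``c`` plus residuals ``y0 = x0 - c``, ``yk = xk - c``;
an agent applying the cancellation heuristic compares only the residuals,
which lowers the threshold (delta_star_cancelled < delta_star whenever
0 < c < x0), so patient choice becomes more likely under partitioning.
Because a fixed absolute difference looms larger at smaller amounts under
a concave utility, the lower-alpha (more curved) agents shift the most.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "Domain",
    "Frame",
    "Preferences",
    "TimedAmount",
    "ChoicePair",
    "ThresholdReport",
    "instant_utility",
    "discounted_utility",
    "delta_star",
    "delta_star_cancelled",
    "threshold_report",
    "threshold_sensitivity",
    "option_utilities",
    "prob_later",
    "decide",
    "loss_to_gain_frame",
]


class Frame(str, enum.Enum):
    """How the option pair is presented."""

    INTEGRATED = "integrated"
    PARTITIONED = "partitioned"


class Domain(str, enum.Enum):
    """Whether the amounts are received (gain) or surrendered (loss)."""

    GAIN = "gain"
    LOSS = "loss"


@dataclass(frozen=True)
class Preferences:
    """An agent's time-preference parameters.

    Parameters
    ----------
    alpha : float
        CRRA curvature exponent, in (0, 1]. Lower alpha = faster
        diminishing marginal utility.
    beta : float
        Present-bias multiplier (> 0) applied to delayed payoffs when an
        immediate payoff is on the table. beta = 1 removes present bias.
    delta : float
        Per-day discount factor, in (0, 1].
    noise_temperature : float
        Fechner noise scale (>= 0) for stochastic choice. 0 means the
        deterministic rule; otherwise the probability of choosing the
        later option is logistic in the utility difference divided by
        the temperature. The deterministic model is the baseline; noise
        is an extension used by the simulator.
    """

    alpha: float
    beta: float
    delta: float
    noise_temperature: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.beta > 0.0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not (0.0 < self.delta <= 1.0):
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")
        if self.noise_temperature < 0.0:
            raise ValueError("noise_temperature must be >= 0")


@dataclass(frozen=True)
class TimedAmount:
    """A currency amount delivered ``delay_days`` days from today."""

    amount: float
    delay_days: int

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be >= 0")
        if self.delay_days < 0 or int(self.delay_days) != self.delay_days:
            raise ValueError("delay_days must be a non-negative integer")


@dataclass(frozen=True)
class ChoicePair:
    """A binary intertemporal choice, optionally partitioned.

    ``common_amount`` is the seemingly identical component c separated
    from both options in the partitioned frame (0 = integrated
    presentation). In the loss domain both amounts are read as amounts
    surrendered out of ``endowment``.

    ``kept_wealth`` marks pairs produced by :func:`loss_to_gain_frame`,
    where the *earlier* option carries the larger payoff, so the usual
    gain-domain ordering check is deliberately not applied.
    """

    earlier: TimedAmount
    later: TimedAmount
    common_amount: float = 0.0
    frame: Frame = Frame.INTEGRATED
    domain: Domain = Domain.GAIN
    endowment: Optional[float] = None
    kept_wealth: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame", Frame(self.frame))
        object.__setattr__(self, "domain", Domain(self.domain))
        if self.later.delay_days <= self.earlier.delay_days:
            raise ValueError("later option must be strictly more delayed")
        if self.common_amount < 0:
            raise ValueError("common_amount must be >= 0")
        if self.common_amount > min(self.earlier.amount, self.later.amount):
            raise ValueError("common_amount must leave non-negative residuals")
        if self.domain is Domain.LOSS:
            if self.endowment is None:
                raise ValueError("loss-domain pairs require an endowment")
            if self.later.amount <= self.earlier.amount:
                raise ValueError("later loss must exceed earlier loss")
            if self.later.amount > self.endowment:
                raise ValueError("losses may not exceed the endowment")
        elif not self.kept_wealth and self.later.amount <= self.earlier.amount:
            raise ValueError("gain-domain pairs require later.amount > earlier.amount")

    @property
    def k_days(self) -> int:
        return self.later.delay_days - self.earlier.delay_days

    @property
    def residual_earlier(self) -> float:
        return self.earlier.amount - self.common_amount

    @property
    def residual_later(self) -> float:
        return self.later.amount - self.common_amount

    def with_frame(self, frame: Union[Frame, str]) -> "ChoicePair":
        frame = Frame(frame)
        return ChoicePair(
            self.earlier, self.later, self.common_amount, frame, self.domain,
            self.endowment, self.kept_wealth,
        )


@dataclass(frozen=True)
class ThresholdReport:
    """Indifference thresholds and their curvature sensitivity."""

    delta_star: float
    delta_star_cancelled: float
    sensitivity: float  # d(delta_star)/d(alpha), evaluated on the totals


def instant_utility(amount: float, alpha: float) -> float:
    """CRRA instantaneous utility ``amount**alpha / alpha``.

    Strictly increasing and concave in ``amount`` for alpha in (0, 1).
    alpha = 0 (the log-utility limit) is rejected.
    """
    if alpha == 0:
        raise ValueError("alpha = 0 (log utility) is not supported")
    amount = np.asarray(amount, dtype=float)
    if np.any(amount < 0):
        raise ValueError("amount must be >= 0")
    out = np.power(amount, alpha) / alpha
    return float(out) if out.ndim == 0 else out


def _beta_exponent(earlier_delay: int) -> int:
    # beta multiplies the delayed term only when the earlier payoff is
    # immediate; for t > 0 the present-bias term is simply inactive.
    return 1 if earlier_delay == 0 else 0


def discounted_utility(earlier: TimedAmount, later: TimedAmount,
                       prefs: Preferences) -> float:
    """Discounted utility of the (earlier, later) payoff bundle.

    ``delta**t * u(x_t) + beta**I * delta**(t+k) * u(x_{t+k})`` where the
    indicator I is 1 iff the earlier payoff is immediate (t = 0).
    """
    if later.delay_days < earlier.delay_days:
        raise ValueError("later payoff must not precede the earlier payoff")
    i = _beta_exponent(earlier.delay_days)
    u_t = prefs.delta ** earlier.delay_days * instant_utility(earlier.amount, prefs.alpha)
    u_tk = (prefs.beta ** i) * prefs.delta ** later.delay_days \
        * instant_utility(later.amount, prefs.alpha)
    return u_t + u_tk


def delta_star(x0: float, xk: float, k: int, alpha: float, beta: float) -> float:
    """Indifference discount factor for x0 now-ish vs xk after k more days.

    Agents with delta >= delta_star choose the later amount (ties go to
    the later option).
    """
    if not 0 < x0 < xk:
        raise ValueError("requires 0 < x0 < xk")
    if k < 1:
        raise ValueError("k must be >= 1 day")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return ((1.0 / beta) * (x0 / xk) ** alpha) ** (1.0 / k)


def delta_star_cancelled(pair: ChoicePair, alpha: float, beta: float) -> float:
    """Indifference threshold after cancelling the common component.

    Computed on the residuals (y0, yk); the present-bias factor is
    carried through exactly as in the uncancelled threshold. When the
    earlier residual is zero the later option is always preferred, so
    the threshold is 0.
    """
    y0, yk = pair.residual_earlier, pair.residual_later
    if pair.common_amount <= 0:
        raise ValueError("pair has no common component to cancel")
    if not yk > y0 >= 0:
        raise ValueError("residuals must satisfy yk > y0 >= 0")
    if y0 == 0:
        return 0.0
    return delta_star(y0, yk, pair.k_days, alpha, beta)


def threshold_sensitivity(delta_star_value: float, k: int, z: float) -> float:
    """d(delta_star)/d(alpha) = (delta_star / k) * ln(z), with z = x0/xk < 1.

    Always negative: the threshold falls as curvature vanishes
    (alpha rises), and faster the smaller the amount ratio z — which is
    why cancellation amplifies the effect of curvature on choice.
    """
    if not 0 < z < 1:
        raise ValueError("z must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1 day")
    return delta_star_value / k * math.log(z)


def threshold_report(pair: ChoicePair, alpha: float, beta: float) -> ThresholdReport:
    """delta_star on the totals and the residuals, plus the alpha-sensitivity."""
    if pair.domain is not Domain.GAIN or pair.kept_wealth:
        raise ValueError("threshold_report applies to ordinary gain pairs")
    ds = delta_star(pair.earlier.amount, pair.later.amount, pair.k_days, alpha, beta)
    if pair.common_amount > 0:
        dsc = delta_star_cancelled(pair, alpha, beta)
    else:
        dsc = ds
    z = pair.earlier.amount / pair.later.amount
    return ThresholdReport(ds, dsc, threshold_sensitivity(ds, pair.k_days, z))


def loss_to_gain_frame(earlier_loss: float, later_loss: float,
                       endowment: float) -> ChoicePair:
    """Map a loss pair to the equivalent gain pair on kept wealth.

    Paying the smaller loss earlier keeps ``endowment - earlier_loss``
    from the earlier date; deferring to the larger later loss keeps
    ``endowment - later_loss`` from the later date. The earlier option
    now carries the larger payoff, so "choose the later loss" maps to
    "choose the smaller, later kept amount".
    """
    if not (endowment >= later_loss > earlier_loss >= 0):
        raise ValueError("requires endowment >= later_loss > earlier_loss >= 0")
    return ChoicePair(
        earlier=TimedAmount(endowment - earlier_loss, 0),
        later=TimedAmount(endowment - later_loss, 7),
        kept_wealth=True,
    )


def option_utilities(pair: ChoicePair, prefs: Preferences) -> tuple[float, float]:
    """(U_earlier, U_later) under the pair's frame and domain.

    Gains, integrated: compare discounted utilities of the totals.
    Gains, partitioned: cancel ``common_amount`` and compare residuals.
    Losses: options are valued through the wealth kept out of the
    endowment (the earlier option keeps more, but sooner is also
    better, so only agents with beta > 1 ever defer a loss). Under
    partitioned framing the two kept amounts share a seemingly
    identical component — the smaller kept amount — whose cancellation
    leaves residuals (later_loss - earlier_loss, 0).
    """
    t_e, t_l = pair.earlier.delay_days, pair.later.delay_days
    i = _beta_exponent(t_e)
    disc_e = prefs.delta ** t_e
    disc_l = (prefs.beta ** i) * prefs.delta ** t_l
    if pair.domain is Domain.GAIN:
        if pair.frame is Frame.PARTITIONED and pair.common_amount > 0:
            amt_e, amt_l = pair.residual_earlier, pair.residual_later
        else:
            amt_e, amt_l = pair.earlier.amount, pair.later.amount
    else:
        kept_e = pair.endowment - pair.earlier.amount
        kept_l = pair.endowment - pair.later.amount
        if pair.frame is Frame.PARTITIONED and pair.common_amount > 0:
            amt_e, amt_l = kept_e - kept_l, 0.0
        else:
            amt_e, amt_l = kept_e, kept_l
    u_e = disc_e * instant_utility(amt_e, prefs.alpha)
    u_l = disc_l * instant_utility(amt_l, prefs.alpha)
    return u_e, u_l


def prob_later(pair: ChoicePair, prefs: Preferences) -> float:
    """Probability of choosing the later option.

    Deterministic (noise 0): 1.0 if U_later >= U_earlier else 0.0 (ties
    go to the later option). With noise, a logistic (Fechner) function
    of the utility difference over the temperature; the probability is
    exactly 0.5 at indifference.
    """
    u_e, u_l = option_utilities(pair, prefs)
    if prefs.noise_temperature == 0.0:
        return 1.0 if u_l >= u_e else 0.0
    x = (u_l - u_e) / prefs.noise_temperature
    # numerically safe logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def decide(pair: ChoicePair, prefs: Preferences,
           rng: Union[int, np.random.Generator, None] = None) -> str:
    """Realized choice, "earlier" or "later".

    Deterministic when ``prefs.noise_temperature`` is 0; otherwise a
    seeded Bernoulli draw from :func:`prob_later` (``rng`` may be a seed
    or a Generator).
    """
    p = prob_later(pair, prefs)
    if prefs.noise_temperature == 0.0:
        return "later" if p >= 0.5 else "earlier"
    if rng is None:
        raise ValueError("stochastic choice requires a seed or Generator")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return "later" if rng.random() < p else "earlier"
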