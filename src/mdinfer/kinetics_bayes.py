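"""Bayesian single-exponential rate inference for censored trajectory data.

A set of fixed-length simulation trajectories started from the same
configuration either shows a transition (an "observed" outcome at the
event time) or runs out without one (a right-censored outcome).  Under
single-exponential kinetics with rate ``k`` the likelihood of such data is

    l(k | D) = k^n * exp(-k * Theta)

where ``n`` counts the observed transitions and ``Theta`` is the total
exposure time: the sum of the event times of transitioning trajectories
plus the full lengths of the censored ones.  With a uniform prior the
posterior for ``k`` is a Gamma(n + 1, Theta) density; with the
scale-invariant Jeffreys prior (proportional to 1/k) it is
Gamma(n, Theta), proper only when at least one transition was observed.

The module also provides the Bayes factor (odds ratio) comparing the
hypothesis that two datasets were generated by two distinct rate
processes against a single common process, together with the standard
Jeffreys-scale interpretation of its value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log, pi, exp
from typing import Literal, Sequence

from scipy import stats

PriorKind = Literal["uniform", "jeffreys"]

__all__ = [
    "TrajectoryOutcome",
    "TransitionData",
    "RatePosterior",
    "BayesFactorResult",
    "sufficient_statistics",
    "posterior",
    "credible_interval",
    "bayes_factor",
    "interpret_bayes_factor",
]


@dataclass(frozen=True)
class TrajectoryOutcome:
    """Outcome of one trajectory: a transition at ``event_time`` or censoring.

    ``total_time`` is the trajectory length.  For a censored trajectory
    (``observed=False``) ``event_time`` must be ``None``; the trajectory
    contributes its full length to the exposure time.
    """

    observed: bool
    event_time: float | None
    total_time: float

    def __post_init__(self) -> None:
        if self.total_time <= 0:
            raise ValueError(f"total_time must be positive, got {self.total_time}")
        if self.observed:
            if self.event_time is None:
                raise ValueError("observed outcome requires an event_time")
            if not (0 < self.event_time <= self.total_time):
                raise ValueError(
                    f"event_time {self.event_time} outside (0, {self.total_time}]"
                )
        elif self.event_time is not None:
            raise ValueError("censored outcome must not carry an event_time")

    @property
    def exposure(self) -> float:
        """Time this trajectory contributes to Theta."""
        return self.event_time if self.observed else self.total_time


@dataclass(frozen=True)
class TransitionData:
    """A collection of per-trajectory transition outcomes in one time unit."""

    outcomes: tuple[TrajectoryOutcome, ...]
    time_unit: str = "us"

    def __init__(self, outcomes: Sequence[TrajectoryOutcome], time_unit: str = "us"):
        object.__setattr__(self, "outcomes", tuple(outcomes))
        object.__setattr__(self, "time_unit", time_unit)
        if not self.outcomes:
            raise ValueError("TransitionData requires at least one outcome")

    @property
    def n_observed(self) -> int:
        return sum(o.observed for o in self.outcomes)

    @property
    def n_total(self) -> int:
        return len(self.outcomes)

    @property
    def theta(self) -> float:
        return float(sum(o.exposure for o in self.outcomes))

    def __add__(self, other: "TransitionData") -> "TransitionData":
        if other.time_unit != self.time_unit:
            raise ValueError(
                f"cannot pool data in {self.time_unit} with data in {other.time_unit}"
            )
        return TransitionData(self.outcomes + other.outcomes, self.time_unit)

    @staticmethod
    def from_times(
        event_times: Sequence[float] = (),
        censored_times: Sequence[float] = (),
        time_unit: str = "us",
        total_time: float | None = None,
    ) -> "TransitionData":
        """Build from lists of event times and censoring times.

        ``total_time`` sets the trajectory length for observed outcomes;
        by default each observed trajectory's length equals its event time
        (the trajectory is stopped at the transition).
        """
        outs = [
            TrajectoryOutcome(True, t, total_time if total_time is not None else t)
            for t in event_times
        ]
        outs += [TrajectoryOutcome(False, None, t) for t in censored_times]
        return TransitionData(outs, time_unit)


def sufficient_statistics(data: TransitionData) -> tuple[int, float]:
    """Return ``(n, Theta)``: transition count and total exposure time.

    Theta sums the event times of transitioning trajectories and the full
    lengths of non-transitioning ones; together with ``n`` it fully
    determines the single-exponential likelihood.
    """
    return data.n_observed, data.theta


@dataclass(frozen=True)
class RatePosterior:
    """Closed-form Gamma posterior over the transition rate ``k``.

    Shape is ``n + 1`` for the uniform prior and ``n`` for the Jeffreys
    prior; the rate (inverse-scale) parameter is ``Theta``.  Rates are in
    the inverse of ``time_unit``.
    """

    prior: PriorKind
    n: int
    theta: float
    time_unit: str = "us"

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"Theta must be positive, got {self.theta}")
        if self.n < 0:
            raise ValueError(f"n must be non-negative, got {self.n}")
        if self.prior == "jeffreys" and self.n < 1:
            raise ValueError(
                "the Jeffreys prior yields a proper posterior only when at "
                "least one barrier crossing event is observed (n >= 1); "
                "use the uniform prior for n = 0"
            )
        if self.prior not in ("uniform", "jeffreys"):
            raise ValueError(f"unknown prior kind {self.prior!r}")

    @property
    def shape(self) -> int:
        return self.n + 1 if self.prior == "uniform" else self.n

    @property
    def dist(self) -> stats.rv_continuous:
        """The frozen scipy Gamma distribution of the rate."""
        return stats.gamma(a=self.shape, scale=1.0 / self.theta)

    @property
    def mean(self) -> float:
        """Posterior mean: (n+1)/Theta (uniform) or n/Theta (Jeffreys)."""
        return self.shape / self.theta

    @property
    def variance(self) -> float:
        """Posterior variance: (n+1)/Theta^2 (uniform) or n/Theta^2."""
        return self.shape / self.theta**2

    def pdf(self, k):
        return self.dist.pdf(k)

    def interval(self, level: float = 0.95, method: str = "central"):
        return credible_interval(self, level, method=method)


def posterior(data: TransitionData, prior: PriorKind = "uniform") -> RatePosterior:
    """Posterior over the rate from censored transition data.

    With ``prior='uniform'`` inference is possible even with zero observed
    transitions; ``prior='jeffreys'`` requires ``n >= 1``.
    """
    n, theta = sufficient_statistics(data)
    return RatePosterior(prior=prior, n=n, theta=theta, time_unit=data.time_unit)


def credible_interval(
    post: RatePosterior, level: float = 0.95, method: str = "central"
) -> tuple[float, float]:
    """Credible interval of the rate posterior.

    ``method='central'`` (default) returns the equal-tailed interval;
    ``method='hpd'`` returns the highest-posterior-density interval,
    found by sliding the lower tail mass.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    d = post.dist
    if method == "central":
        a = (1.0 - level) / 2.0
        return float(d.ppf(a)), float(d.ppf(a + level))
    if method == "hpd":
        if post.shape <= 1:
            # mode at 0: HPD is the one-sided interval [0, q_level]
            return 0.0, float(d.ppf(level))

        def width(a: float) -> float:
            return d.ppf(a + level) - d.ppf(a)

        from scipy.optimize import minimize_scalar

        res = minimize_scalar(width, bounds=(1e-12, 1 - level - 1e-12), method="bounded")
        a = float(res.x)
        return float(d.ppf(a)), float(d.ppf(a + level))
    raise ValueError(f"unknown interval method {method!r}")


@dataclass(frozen=True)
class BayesFactorResult:
    """Odds ratio favouring "two distinct rate processes" over one.

    ``data_a``/``data_b`` hold the per-dataset sufficient statistics
    ``(n, Theta)``; ``pooled`` their sums.  ``label`` is the Jeffreys-scale
    interpretation of the odds.
    """

    odds_two_processes: float
    data_a: tuple[int, float]
    data_b: tuple[int, float]
    pooled: tuple[int, float] = field(init=False)
    label: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "pooled",
            (self.data_a[0] + self.data_b[0], self.data_a[1] + self.data_b[1]),
        )
        object.__setattr__(self, "label", interpret_bayes_factor(self.odds_two_processes))


def _log_bayes_factor(n1: int, t1: float, n2: int, t2: float) -> float:
    n = n1 + n2
    t = t1 + t2
    if n == 0:
        raise ValueError(
            "the odds ratio is undefined when neither dataset contains an "
            "observed transition"
        )
    # log[(2/pi) * (n/Theta) / (n1^2/Theta1^2 + n2^2/Theta2^2)]
    s = (n1 / t1) ** 2 + (n2 / t2) ** 2
    log_pref = log(2.0 / pi) + log(n / t) - log(s)
    # log[(n1! n2! / n!) * Theta^(n+1) / (Theta1^(n1+1) Theta2^(n2+1))]
    log_comb = lgamma(n1 + 1) + lgamma(n2 + 1) - lgamma(n + 1)
    log_theta = (n + 1) * log(t) - (n1 + 1) * log(t1) - (n2 + 1) * log(t2)
    return log_pref + log_comb + log_theta


def bayes_factor(data_a: TransitionData, data_b: TransitionData) -> BayesFactorResult:
    """Odds ratio for two distinct rate processes vs one common process.

    Evaluates the closed-form marginal-likelihood ratio for
    single-exponential kinetics in log space (log-Gamma in place of
    factorials, so large ``n`` cannot overflow).  Datasets with zero
    observed transitions are supported on either side (uniform-prior
    branch); at least one transition must be present overall.  The result
    is symmetric under swapping the two datasets.
    """
    n1, t1 = sufficient_statistics(data_a)
    n2, t2 = sufficient_statistics(data_b)
    odds = exp(_log_bayes_factor(n1, t1, n2, t2))
    return BayesFactorResult(odds_two_processes=odds, data_a=(n1, t1), data_b=(n2, t2))


#: Jeffreys-scale band (lower, upper) for "barely worth mentioning"
JEFFREYS_BAND = (1.0 / 3.0, 3.0)

LABEL_ONE_PROCESS = "substantial evidence for one process"
LABEL_INCONCLUSIVE = "barely worth mentioning"
LABEL_TWO_PROCESSES = "substantial evidence for two processes"


def interpret_bayes_factor(odds: float) -> str:
    """Jeffreys-scale interpretation of an odds ratio for two processes.

    Odds below 1/3 give substantial evidence for a single shared process,
    odds above 3 substantial evidence for two distinct processes, and the
    band between is inconclusive ("barely worth mentioning").
    """
    if odds <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds}")
    lo, hi = JEFFREYS_BAND
    if odds < lo:
        return LABEL_ONE_PROCESS
    if odds > hi:
        return LABEL_TWO_PROCESSES
    return LABEL_INCONCLUSIVE
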