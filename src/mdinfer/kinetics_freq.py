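"""Frequentist transition-rate estimation from trajectory ensembles.

The workhorse is the survival curve: the fraction of trajectories that
have not yet made the transition as a function of time.  For a
single-exponential process S(t) = exp(-t/τ) and the half-life is
t_1/2 = τ ln 2.  The module fits the curve, attaches bootstrap standard
errors, traces how the estimate and its uncertainty evolve with the
number of trajectories (the SE of an i.i.d. mean must fall as N^(-1/2)),
and enumerates the probability of each qualitative "which boxes show a
transition" conclusion an N = 1 study could have reached.

When a dataset contains no observed transition at all the frequentist
fit is impossible; those cases belong to the Bayesian estimator in
:mod:`mdinfer.kinetics_bayes`, and the errors raised here say so.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import log
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .kinetics_bayes import TransitionData

LN2 = log(2.0)

__all__ = [
    "SurvivalEstimate",
    "SampleSizeCurve",
    "BoxOutcomeCounts",
    "classify_endstate",
    "survival_curve",
    "bootstrap_half_life",
    "rate_vs_sample_size",
    "conclusion_probabilities",
]


def classify_endstate(dist_to_R: float, dist_to_T: float) -> str:
    """Classify a trajectory endpoint as 'R' or 'T' by proximity.

    A trajectory started in T counts as transitioned iff its endpoint is
    strictly closer to the R reference than to the T reference; ties are
    assigned to 'T', the conservative no-transition call.
    """
    if dist_to_R < 0 or dist_to_T < 0:
        raise ValueError("distances must be non-negative")
    return "R" if dist_to_R < dist_to_T else "T"


@dataclass(frozen=True)
class SurvivalEstimate:
    """Empirical survival curve with its exponential fit.

    ``times``/``survival`` trace the step function S(t); ``tau`` is the
    fitted time constant, ``tau_mle`` the censored maximum-likelihood
    alternative Θ/n, and ``half_life = tau * ln 2``.  ``se_half_life`` is
    populated by the bootstrap wrapper and NaN otherwise.
    """

    times: np.ndarray
    survival: np.ndarray
    tau: float
    tau_mle: float
    half_life: float
    se_half_life: float = float("nan")
    estimators_disagree: bool = False


def _empirical_survival(data: TransitionData) -> tuple[np.ndarray, np.ndarray]:
    event_times = np.sort(
        [o.event_time for o in data.outcomes if o.observed]
    ).astype(float)
    n = data.n_total
    times = np.concatenate([[0.0], event_times])
    surv = 1.0 - np.arange(len(event_times) + 1) / n
    return times, surv


def survival_curve(data: TransitionData, se_tolerance: float = 2.0) -> SurvivalEstimate:
    """Survival fraction over time with a single-exponential fit.

    Censored trajectories stay in the "surviving" pool for their whole
    length, so the curve never drops for them.  The time constant comes
    from a nonlinear least-squares fit of exp(-t/τ) to the curve; the
    censored-data maximum-likelihood estimate Θ/n is reported alongside,
    and the two are flagged when they disagree by more than
    ``se_tolerance`` approximate standard errors (τ/√n).
    """
    n_obs = data.n_observed
    if n_obs == 0:
        raise ValueError(
            "no transitions observed: the survival-curve fit is undefined; "
            "use the Bayesian rate estimator (kinetics_bayes.posterior with "
            "the uniform prior) for such data"
        )
    times, surv = _empirical_survival(data)
    tau_mle = data.theta / n_obs

    def model(t, tau):
        return np.exp(-t / tau)

    # fit at plotting positions 1 - (i - 1/2)/N so the last event does not
    # pin the curve at exactly zero (which no exponential can reach)
    event_times = times[1:]
    n_tot = data.n_total
    s_fit = 1.0 - (np.arange(1, n_obs + 1) - 0.5) / n_tot
    t_fit = np.concatenate([[0.0], event_times])
    s_pts = np.concatenate([[1.0], s_fit])
    (tau_fit,), _ = optimize.curve_fit(
        model, t_fit, s_pts, p0=[tau_mle], bounds=(1e-300, np.inf), maxfev=10_000
    )
    se_approx = tau_mle / np.sqrt(n_obs)
    disagree = bool(abs(tau_fit - tau_mle) > se_tolerance * se_approx)
    return SurvivalEstimate(
        times=times,
        survival=surv,
        tau=float(tau_fit),
        tau_mle=float(tau_mle),
        half_life=float(tau_fit) * LN2,
        estimators_disagree=disagree,
    )


def bootstrap_half_life(
    data: TransitionData,
    n_boot: int = 1000,
    seed: int = 0,
    max_redraw_fraction: float = 0.5,
) -> tuple[float, float]:
    """Half-life with a bootstrap standard error.

    Trajectories are resampled with replacement ``n_boot`` times; each
    resample is refit and the SE is the standard deviation of the
    bootstrap half-life distribution.  Resamples containing no observed
    transition cannot be fit and are redrawn; if they would exceed half
    of all draws the data are too sparse for the frequentist route and
    an error recommends the Bayesian estimator instead.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    base = survival_curve(data)
    outcomes = data.outcomes
    n = len(outcomes)
    rng = np.random.default_rng(seed)
    observed_mask = np.array([o.observed for o in outcomes])
    estimates = []
    n_redrawn = 0
    max_attempts = int(np.ceil(n_boot / (1.0 - max_redraw_fraction))) + n_boot
    attempts = 0
    while len(estimates) < n_boot:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"more than {max_redraw_fraction:.0%} of bootstrap resamples "
                "contain no transition; the data are too sparse for the "
                "bootstrap — use the Bayesian rate estimator"
            )
        idx = rng.integers(0, n, n)
        if not observed_mask[idx].any():
            n_redrawn += 1
            continue
        resample = TransitionData([outcomes[i] for i in idx], data.time_unit)
        estimates.append(survival_curve(resample).half_life)
    if n_redrawn > max_redraw_fraction * (len(estimates) + n_redrawn):
        raise ValueError(
            "over half of the bootstrap resamples had no transitions; "
            "use the Bayesian rate estimator for such sparse data"
        )
    se = float(np.std(estimates, ddof=1))
    return base.half_life, se


@dataclass(frozen=True)
class SampleSizeCurve:
    """Estimate and uncertainty as a function of sample size N.

    ``scaling_exponent`` is the log–log slope of SE versus N; for i.i.d.
    transition samples this must approach −1/2 (the SE of a mean falls
    as N^(-1/2)), whatever shorthand a figure caption may use for it.
    ``degenerate`` flags sizes where the SE is undefined (a single
    resample of the full pool).
    """

    sizes: np.ndarray
    estimates: np.ndarray
    ses: np.ndarray
    scaling_exponent: float
    degenerate: np.ndarray


def rate_vs_sample_size(
    pool: TransitionData,
    sizes: Sequence[int],
    n_resample: int = 100,
    seed: int = 0,
) -> SampleSizeCurve:
    """Mean time-constant estimate and its SE for growing subset sizes.

    For each size, ``n_resample`` subsets are drawn without replacement
    from the pool (independently across resamples); each subset yields
    the censored maximum-likelihood time constant Θ/n, and the spread of
    those estimates across resamples gives the SE.  The log–log slope of
    SE against N is returned as the scaling exponent.
    """
    sizes = np.asarray(sizes, dtype=int)
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("sizes must be strictly increasing")
    if sizes.max() > pool.n_total:
        raise ValueError(
            f"requested subset size {sizes.max()} exceeds pool size {pool.n_total}"
        )
    rng = np.random.default_rng(seed)
    exposures = np.array([o.exposure for o in pool.outcomes])
    observed = np.array([o.observed for o in pool.outcomes])
    n_pool = pool.n_total
    est = np.empty(len(sizes))
    ses = np.empty(len(sizes))
    degenerate = np.zeros(len(sizes), dtype=bool)
    for i, size in enumerate(sizes):
        vals = []
        for _ in range(n_resample):
            idx = rng.choice(n_pool, size=size, replace=False)
            n_obs = observed[idx].sum()
            if n_obs == 0:
                continue
            vals.append(exposures[idx].sum() / n_obs)
        vals = np.asarray(vals)
        est[i] = vals.mean() if vals.size else float("nan")
        if len(vals) < 2 or (size == n_pool and n_resample == 1):
            ses[i] = 0.0
            degenerate[i] = True
        else:
            ses[i] = vals.std(ddof=1)
    ok = ~degenerate & (ses > 0)
    if ok.sum() >= 2:
        slope, _ = np.polyfit(np.log(sizes[ok]), np.log(ses[ok]), 1)
    else:
        slope = float("nan")
    return SampleSizeCurve(
        sizes=sizes, estimates=est, ses=ses, scaling_exponent=float(slope),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class BoxOutcomeCounts:
    """Transition tallies per condition: {label: (n_transitioned, n_total)}."""

    counts: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("at least one condition is required")
        for lab, (k, n) in self.counts.items():
            if n < 1:
                raise ValueError(f"condition {lab!r} has zero trajectories")
            if not 0 <= k <= n:
                raise ValueError(f"condition {lab!r}: need 0 <= {k} <= {n}")

    @property
    def labels(self) -> tuple:
        return tuple(self.counts.keys())


def conclusion_probabilities(
    counts: BoxOutcomeCounts, pooled: bool = False
) -> dict[tuple[bool, ...], float]:
    """Probability of each qualitative conclusion an N = 1 study could draw.

    Were a single trajectory run per condition, the study would conclude
    one of 2^B patterns of "a transition occurs in condition b".  With
    per-condition empirical transition probability p_b = n_b/N_b (or the
    pooled common probability Σn_b/ΣN_b under the hypothesis that all
    conditions share one transition probability), the chance of pattern
    (b_1, …, b_B) is the product over conditions of p_b or 1−p_b.  The
    returned probabilities sum to one.
    """
    labels = counts.labels
    if pooled:
        tot_k = sum(k for k, _ in counts.counts.values())
        tot_n = sum(n for _, n in counts.counts.values())
        ps = {lab: tot_k / tot_n for lab in labels}
    else:
        ps = {lab: k / n for lab, (k, n) in counts.counts.items()}
    out: dict[tuple[bool, ...], float] = {}
    for pattern in product([True, False], repeat=len(labels)):
        prob = 1.0
        for lab, hit in zip(labels, pattern):
            prob *= ps[lab] if hit else 1.0 - ps[lab]
        out[pattern] = prob
    return out
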