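"""Free-energy estimation and sampling-quality diagnostics.

Two estimators form the core:

* ``crooks_mle_dg`` — the maximum-likelihood free-energy difference from
  forward and reverse non-equilibrium work values.  By the Crooks
  fluctuation theorem the forward and (mirrored) reverse work densities
  cross at ΔG; the MLE is the Bennett acceptance-ratio equation, solved
  self-consistently, with a bootstrap standard error.
* ``mbar_pmf`` — a potential of mean force from umbrella-sampling
  windows by multistate reweighting: the window free energies solve the
  self-consistent multistate equations over the pooled samples, after
  which each sample carries an unbiased weight and the PMF is the
  negative log of the weighted coordinate histogram.

Around these sit convergence diagnostics (profiles from growing data
fractions with replicate-based errors), autocorrelation analysis with
the statistical inefficiency g = 1 + 2 Σ ρ(τ), and replicate summary
statistics with confidence intervals and a trend test across ordered
conditions.

Sign convention for work: the forward work is the work to drive the
system A → B, the reverse work the work to drive B → A, so a consistent
pair has W_f ≈ ΔG and W_r ≈ −ΔG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp
from statsmodels.tsa.stattools import acf as _sm_acf

from ._units import kt_kj_per_mol

__all__ = [
    "WorkSet",
    "CrooksEstimate",
    "UmbrellaWindow",
    "FreeEnergyProfile",
    "AcfResult",
    "ReplicateSummary",
    "TrendReport",
    "crooks_mle_dg",
    "mbar_pmf",
    "neighbor_overlap",
    "profile_convergence",
    "acf",
    "replicate_statistics",
    "trend_significance",
]


# ---------------------------------------------------------------------------
# non-equilibrium work -> ΔG (Crooks / Bennett acceptance ratio)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkSet:
    """Forward and reverse non-equilibrium work samples in kJ/mol."""

    forward_works: np.ndarray
    reverse_works: np.ndarray
    temperature: float = 298.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "forward_works", np.asarray(self.forward_works, dtype=float)
        )
        object.__setattr__(
            self, "reverse_works", np.asarray(self.reverse_works, dtype=float)
        )
        if self.forward_works.size == 0 or self.reverse_works.size == 0:
            raise ValueError(
                "the two-sided estimator needs at least one work value per direction"
            )
        if not (
            np.all(np.isfinite(self.forward_works))
            and np.all(np.isfinite(self.reverse_works))
        ):
            raise ValueError("work values must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def swapped(self) -> "WorkSet":
        """The same data with the direction labels exchanged."""
        return WorkSet(self.reverse_works, self.forward_works, self.temperature)


@dataclass(frozen=True)
class CrooksEstimate:
    """ΔG estimate (kJ/mol) with bootstrap SE and an overlap warning flag."""

    dg: float
    se: float
    n_forward: int
    n_reverse: int
    low_overlap: bool = False


def _bar_equation(dg: float, wf: np.ndarray, wr: np.ndarray, beta: float, m: float):
    # Bennett self-consistency: sum_F fermi(M + beta(W_f - dG))
    #                         = sum_R fermi(-M + beta(W_r + dG))
    lhs = np.sum(stats.logistic.cdf(-(m + beta * (wf - dg))))
    rhs = np.sum(stats.logistic.cdf(-(-m + beta * (wr + dg))))
    return lhs - rhs


def _solve_bar(wf: np.ndarray, wr: np.ndarray, beta: float) -> float:
    m = np.log(len(wf) / len(wr))
    lo = min(wf.min(), (-wr).min()) - 10.0 / beta
    hi = max(wf.max(), (-wr).max()) + 10.0 / beta
    f_lo = _bar_equation(lo, wf, wr, beta, m)
    f_hi = _bar_equation(hi, wf, wr, beta, m)
    span = hi - lo
    while f_lo * f_hi > 0 and span < 1e6:
        lo -= span
        hi += span
        span = hi - lo
        f_lo = _bar_equation(lo, wf, wr, beta, m)
        f_hi = _bar_equation(hi, wf, wr, beta, m)
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    return optimize.brentq(
        _bar_equation, lo, hi, args=(wf, wr, beta, m), xtol=1e-12, rtol=1e-14
    )


def crooks_mle_dg(works: WorkSet, n_boot: int = 1000, seed: int = 0) -> CrooksEstimate:
    """Maximum-likelihood ΔG from two-sided non-equilibrium work values.

    Solves the Bennett acceptance-ratio equation (the Crooks-theorem MLE)
    for ΔG in kJ/mol; the standard error is the standard deviation of
    ``n_boot`` bootstrap re-estimates over resampled work values.  When
    the forward and mirrored reverse work distributions are separated by
    more than 50 kT the estimate is flagged as low-overlap.
    """
    wf, wr = works.forward_works, works.reverse_works
    beta = 1.0 / kt_kj_per_mol(works.temperature)
    dg = _solve_bar(wf, wr, beta)
    gap = wf.min() - (-wr).max()
    low_overlap = bool(gap * beta > 50.0)

    rng = np.random.default_rng(seed)
    if n_boot >= 2:
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bf = wf[rng.integers(0, len(wf), len(wf))]
            br = wr[rng.integers(0, len(wr), len(wr))]
            boots[b] = _solve_bar(bf, br, beta)
        se = float(np.std(boots, ddof=1))
    else:
        se = float("nan")
    return CrooksEstimate(
        dg=float(dg), se=se, n_forward=len(wf), n_reverse=len(wr), low_overlap=low_overlap
    )


# ---------------------------------------------------------------------------
# umbrella sampling -> PMF (multistate reweighting)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UmbrellaWindow:
    """Reaction-coordinate samples under one harmonic restraint.

    ``force_constant`` is in kJ/mol per squared coordinate unit;
    ``discard_fraction`` drops the leading equilibration part of the
    series before any estimation.
    """

    center: float
    force_constant: float
    samples: np.ndarray
    discard_fraction: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")
        if not 0 <= self.discard_fraction < 1:
            raise ValueError("discard_fraction must be in [0, 1)")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D series")

    @property
    def production_samples(self) -> np.ndarray:
        """Samples after dropping the leading ``discard_fraction``."""
        n0 = int(self.discard_fraction * self.samples.size)
        return self.samples[n0:]


@dataclass(frozen=True)
class FreeEnergyProfile:
    """PMF on a bin grid, aligned so that its minimum is exactly zero.

    ``se`` is the standard error of each bin's ΔG relative to the
    reference (minimum) bin.  ``window_free_energies`` are the converged
    relative window free energies (kJ/mol, first window = 0) and
    ``residual`` the final self-consistency residual of the reweighting
    equations.
    """

    bin_centers: np.ndarray
    dg: np.ndarray
    se: np.ndarray
    alignment: str = "min-zero"
    window_free_energies: np.ndarray | None = None
    residual: float | None = None

    def __post_init__(self) -> None:
        for name in ("bin_centers", "dg", "se"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")


def _coord_delta(x: np.ndarray, c: float, period: float | None) -> np.ndarray:
    d = x - c
    if period is not None:
        d = d - period * np.round(d / period)
    return d


def _mbar_solve(
    bias_kt: np.ndarray, counts: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int]:
    """Solve the multistate self-consistency for reduced free energies.

    ``bias_kt[k, i]`` is the reduced bias of state k evaluated at pooled
    sample i.  Minimizes the convex multistate objective with L-BFGS,
    then polishes with damped Newton steps (the objective's Hessian is
    cheap for a handful of states) until the self-consistent-update
    residual — the largest relative change of any f_k per sweep — falls
    below ``tol``.  Falls back to plain self-consistent iteration where
    a Newton step does not reduce the residual.
    """
    n_states = bias_kt.shape[0]
    # per-sample offset keeps every Boltzmann factor in range; it cancels
    # from both the self-consistency equations and the relative weights
    bmin = bias_kt.min(axis=0)
    boltz = np.exp(-(bias_kt - bmin))  # K x N, entries in (0, 1]

    def sc_update(f):
        denom = (counts * np.exp(f)) @ boltz  # N
        f_new = -np.log(boltz @ (1.0 / denom))
        return f_new - f_new[0]

    def sc_residual(f):
        f_new = sc_update(f)
        return float(np.max(np.abs(f_new - f) / np.maximum(1.0, np.abs(f_new)))), f_new

    f = np.zeros(n_states)
    residual, f_sc = sc_residual(f)
    for it in range(max_iter):
        if residual < tol:
            return f, residual, it
        if it < 2:
            # a couple of plain fixed-point sweeps before trusting Newton
            f = f_sc
            residual, f_sc = sc_residual(f)
            continue
        # damped Newton on the convex multistate objective (gauge f_0 = 0)
        denom = (counts * np.exp(f)) @ boltz
        w = (counts * np.exp(f))[:, None] * boltz / denom
        grad = w.sum(axis=1) - counts
        hess = np.diag(w.sum(axis=1)) - w @ w.T
        try:
            step = np.linalg.solve(
                hess[1:, 1:] + 1e-12 * np.eye(n_states - 1), -grad[1:]
            )
            f_newton = f.copy()
            f_newton[1:] += step
            res_newton, f_sc_newton = sc_residual(f_newton)
        except np.linalg.LinAlgError:
            res_newton = np.inf
        if res_newton < residual:
            f, residual, f_sc = f_newton, res_newton, f_sc_newton
        else:
            f = f_sc
            residual, f_sc = sc_residual(f)
    raise RuntimeError(
        f"multistate reweighting did not converge in {max_iter} iterations "
        f"(residual {residual:.3e})"
    )


def neighbor_overlap(windows: Sequence[UmbrellaWindow], bins: int = 50) -> np.ndarray:
    """Histogram overlap coefficient between adjacent windows (0..1).

    Windows are sorted by center; for each adjacent pair the overlap is
    the shared area of the two normalized sample histograms on a common
    grid.  Values ≳ 0.3 indicate comfortably overlapping windows.
    """
    ws = sorted(windows, key=lambda w: w.center)
    out = []
    for a, b in zip(ws[:-1], ws[1:]):
        xa, xb = a.production_samples, b.production_samples
        lo = min(xa.min(), xb.min())
        hi = max(xa.max(), xb.max())
        edges = np.linspace(lo, hi, bins + 1)
        ha, _ = np.histogram(xa, bins=edges, density=False)
        hb, _ = np.histogram(xb, bins=edges, density=False)
        pa = ha / ha.sum()
        pb = hb / hb.sum()
        out.append(float(np.minimum(pa, pb).sum()))
    return np.array(out)


def mbar_pmf(
    windows: Sequence[UmbrellaWindow],
    temperature: float = 298.0,
    bins: int = 50,
    periodic: bool = False,
    period: float = 360.0,
    coord_range: tuple[float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    n_se_blocks: int = 10,
    min_bin_count: int = 10,
) -> FreeEnergyProfile:
    """Unbiased PMF from umbrella windows by multistate reweighting.

    The window free energies are solved self-consistently over the
    pooled production samples to relative tolerance ``tol``; each sample
    then carries an unbiased weight and the PMF is −kT log of the
    weighted histogram on ``bins`` uniform bins over the sampled range,
    aligned so that the minimum is exactly zero.  Bin standard errors
    (relative to the minimum bin) come from ``n_se_blocks`` contiguous
    block replicates of every window's series, which respects the serial
    correlation of the sampler; bins visited in fewer than two blocks
    fall back to a multinomial counting error with the effective sample
    count reduced by the windows' statistical inefficiency.

    For a periodic coordinate (a dihedral, say) pass ``periodic=True``
    and the ``period``; restraint displacements and binning then use the
    minimum-image distance.
    """
    windows = list(windows)
    if len(windows) < 1:
        raise ValueError("at least one umbrella window is required")
    per = period if periodic else None
    xs = [w.production_samples for w in windows]
    if len(windows) >= 2 and not periodic:
        order = np.argsort([w.center for w in windows])
        for i, j in zip(order[:-1], order[1:]):
            if xs[i].max() < xs[j].min() or xs[j].max() < xs[i].min():
                raise ValueError(
                    "no sample overlap between adjacent windows centered at "
                    f"{windows[i].center} and {windows[j].center}; add windows "
                    "or soften restraints"
                )

    kt = kt_kj_per_mol(temperature)
    pooled = np.concatenate(xs)
    if coord_range is not None:
        lo, hi = coord_range
    elif len(windows) >= 2 and not periodic:
        # default to the restrained region: beyond the outermost centers
        # the unbiased weights grow like exp(+bias) and sparse bins get
        # strongly biased free energies
        ws = sorted(windows, key=lambda w: w.center)
        sig_lo = np.sqrt(kt / ws[0].force_constant)
        sig_hi = np.sqrt(kt / ws[-1].force_constant)
        lo = max(pooled.min(), ws[0].center - 2 * sig_lo)
        hi = min(pooled.max(), ws[-1].center + 2 * sig_hi)
    else:
        lo, hi = pooled.min(), pooled.max()
    edges = np.linspace(lo, hi, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k_red = np.array([w.force_constant for w in windows]) / kt
    ctr = np.array([w.center for w in windows])

    dg_raw, p, raw_counts, f, residual = _reweighted_histogram(
        xs, k_red, ctr, per, kt, edges, tol, max_iter
    )
    # bins visited by only a handful of samples carry huge reweighting
    # factors and unreliable free energies; they are dropped, as umbrella
    # post-processing tools conventionally do with a minimum-count cut
    occupied = (p > 0) & (raw_counts >= min_bin_count)
    if not np.any(occupied):
        raise ValueError("no samples fall inside the requested coordinate range")
    dg_raw[~occupied] = np.nan
    ref = int(np.nanargmin(dg_raw))
    dg = dg_raw - dg_raw[ref]

    # block-replicate standard errors relative to the reference bin
    block_dg = []
    if n_se_blocks >= 2 and min(x.size for x in xs) >= 2 * n_se_blocks:
        for b in range(n_se_blocks):
            xs_b = []
            for x in xs:
                m = x.size // n_se_blocks
                xs_b.append(x[b * m : (b + 1) * m])
            try:
                dg_b, p_b, _, _, _ = _reweighted_histogram(
                    xs_b, k_red, ctr, per, kt, edges, tol, max_iter
                )
            except (RuntimeError, ValueError):
                continue
            if p_b[ref] > 0:
                block_dg.append(dg_b - dg_b[ref])
    se = np.full(bins, np.nan)
    if len(block_dg) >= 2:
        mat = np.vstack(block_dg)
        n_ok = np.sum(np.isfinite(mat), axis=0)
        good = n_ok >= 2
        if np.any(good):
            with np.errstate(invalid="ignore"):
                sd = np.nanstd(
                    np.where(np.isfinite(mat[:, good]), mat[:, good], np.nan),
                    axis=0,
                    ddof=1,
                )
            se[good] = sd / np.sqrt(n_ok[good])
    # fallback for bins the blocks missed: multinomial counting error with
    # autocorrelation-deflated effective sample count
    need = occupied & ~np.isfinite(se)
    if np.any(need):
        g_mean = float(
            np.average(
                [_inefficiency_or_one(x) for x in xs], weights=[x.size for x in xs]
            )
        )
        n_eff = pooled.size / g_mean
        pr = p[ref]
        with np.errstate(divide="ignore", invalid="ignore"):
            var = (1 - p) / (p * n_eff) + (1 - pr) / (pr * n_eff) + 2.0 / n_eff
        se[need] = kt * np.sqrt(np.maximum(var[need], 0.0))
    se[ref] = 0.0

    keep = occupied
    return FreeEnergyProfile(
        bin_centers=centers[keep],
        dg=dg[keep],
        se=se[keep],
        alignment="min-zero",
        window_free_energies=f * kt,
        residual=residual,
    )


def _reweighted_histogram(
    xs: list[np.ndarray],
    k_red: np.ndarray,
    centers: np.ndarray,
    per: float | None,
    kt: float,
    edges: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Solve the reweighting equations and histogram the unbiased weights.

    Returns (-kT log p per bin with NaN where empty, weight mass per bin,
    reduced window free energies, final residual).  The unrestrained part
    of the potential is common to all states and cancels from the
    denominators, so only the harmonic biases enter.
    """
    pooled = np.concatenate(xs)
    counts = np.array([x.size for x in xs], dtype=float)
    bias_kt = np.vstack(
        [0.5 * k * _coord_delta(pooled, c, per) ** 2 for k, c in zip(k_red, centers)]
    )
    if len(xs) == 1:
        f = np.zeros(1)
        residual = 0.0
    else:
        f, residual, _ = _mbar_solve(bias_kt, counts, tol, max_iter)
    bmin = bias_kt.min(axis=0)
    denom = (counts * np.exp(f)) @ np.exp(-(bias_kt - bmin))
    log_w = bmin - np.log(denom)
    log_w -= logsumexp(log_w)
    w = np.exp(log_w)

    bins = len(edges) - 1
    idx = np.clip(np.digitize(pooled, edges) - 1, 0, bins - 1)
    inside = (pooled >= edges[0]) & (pooled <= edges[-1])
    p = np.bincount(idx[inside], weights=w[inside], minlength=bins)
    raw = np.bincount(idx[inside], minlength=bins)
    dg = np.full(bins, np.nan)
    occ = p > 0
    dg[occ] = -kt * np.log(p[occ])
    return dg, p, raw, f, residual


def _inefficiency_or_one(x: np.ndarray) -> float:
    if x.size < 10 or np.std(x) == 0:
        return 1.0
    max_lag = min(x.size // 3, 1000)
    try:
        return acf(x, max_lag=max_lag).inefficiency
    except ValueError:
        return 1.0


def profile_convergence(
    windows: Sequence[UmbrellaWindow],
    fractions: Sequence[float],
    n_rep: int = 10,
    temperature: float = 298.0,
    bins: int = 50,
    **pmf_kwargs,
) -> list[FreeEnergyProfile]:
    """PMFs from growing leading fractions of each window's data.

    For each fraction the profile is estimated from the leading slice of
    every window; its per-bin standard error is the spread over ``n_rep``
    profiles built from disjoint contiguous blocks of that slice, which
    play the role of independent repeats.  A common bin grid (the full
    sampled range) makes the profiles directly comparable.
    """
    windows = list(windows)
    fractions = list(fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    full = np.concatenate([w.production_samples for w in windows])
    rng_lo, rng_hi = full.min(), full.max()
    out = []
    for frac in fractions:
        sliced = []
        for w in windows:
            x = w.production_samples
            m = int(round(frac * x.size))
            if m < 1:
                raise ValueError(
                    f"fraction {frac} leaves an empty window at center {w.center}"
                )
            sliced.append(
                UmbrellaWindow(w.center, w.force_constant, x[:m], 0.0)
            )
        prof = mbar_pmf(
            sliced,
            temperature=temperature,
            bins=bins,
            coord_range=(rng_lo, rng_hi),
            **pmf_kwargs,
        )
        # replicate profiles from disjoint contiguous blocks
        reps = []
        for r in range(n_rep):
            block = []
            ok = True
            for w in sliced:
                x = w.samples
                m = x.size // n_rep
                if m < 1:
                    ok = False
                    break
                block.append(
                    UmbrellaWindow(w.center, w.force_constant, x[r * m : (r + 1) * m], 0.0)
                )
            if not ok:
                break
            try:
                reps.append(
                    mbar_pmf(
                        block,
                        temperature=temperature,
                        bins=bins,
                        coord_range=(rng_lo, rng_hi),
                        **pmf_kwargs,
                    )
                )
            except (ValueError, RuntimeError):
                continue
        if len(reps) >= 2:
            grid = prof.bin_centers
            mat = np.full((len(reps), grid.size), np.nan)
            for i, rp in enumerate(reps):
                # bins are on identical grids; match by center
                pos = {round(float(c), 12): j for j, c in enumerate(rp.bin_centers)}
                for j, c in enumerate(grid):
                    jj = pos.get(round(float(c), 12))
                    if jj is not None:
                        mat[i, j] = rp.dg[jj]
            n_ok = np.sum(~np.isnan(mat), axis=0)
            se = np.full(mat.shape[1], np.nan)
            enough = n_ok >= 2
            if np.any(enough):
                with np.errstate(invalid="ignore"):
                    se[enough] = np.nanstd(mat[:, enough], axis=0, ddof=1) / np.sqrt(
                        n_ok[enough]
                    )
            prof = FreeEnergyProfile(
                bin_centers=prof.bin_centers,
                dg=prof.dg,
                se=se,
                alignment=prof.alignment,
                window_free_energies=prof.window_free_energies,
                residual=prof.residual,
            )
        out.append(prof)
    return out


# ---------------------------------------------------------------------------
# autocorrelation / statistical inefficiency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcfResult:
    """Normalized autocorrelation with integrated time and inefficiency.

    ``integrated_time`` is τ_int = 1/2 + Σ ρ(τ) in units of the sampling
    interval, with the sum truncated at the first non-positive ρ;
    ``inefficiency`` is g = 1 + 2 Σ ρ(τ) = 2 τ_int, the factor by which
    autocorrelation reduces the effective number of independent samples.
    """

    lags: np.ndarray
    acf: np.ndarray
    integrated_time: float
    inefficiency: float


def acf(series, max_lag: int) -> AcfResult:
    """Autocorrelation function of an observable series up to ``max_lag``.

    Requires ``len(series) > 2 * max_lag`` so every lag is well estimated;
    a constant series has no defined autocorrelation and is rejected.
    """
    x = np.asarray(series, dtype=float)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if x.size <= 2 * max_lag:
        raise ValueError(
            f"series of length {x.size} is too short for max_lag={max_lag} "
            "(need length > 2*max_lag)"
        )
    if np.std(x) == 0:
        raise ValueError("constant series: autocorrelation undefined (zero variance)")
    rho = _sm_acf(x, nlags=max_lag, fft=True)
    # truncate the sum at the first non-positive value (initial positive sequence)
    pos = rho[1:]
    nonpos = np.nonzero(pos <= 0)[0]
    cut = nonpos[0] if nonpos.size else pos.size
    s = float(np.sum(pos[:cut]))
    g = 1.0 + 2.0 * s
    return AcfResult(
        lags=np.arange(max_lag + 1),
        acf=rho,
        integrated_time=0.5 + s,
        inefficiency=g,
    )


# ---------------------------------------------------------------------------
# replicate statistics and trend assessment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and confidence interval over replicate estimates."""

    values: np.ndarray
    mean: float
    se: float
    ci: tuple[float, float]
    level: float = 0.95
    method: str = "t"


def replicate_statistics(
    values, level: float = 0.95, method: str = "t"
) -> ReplicateSummary:
    """Mean, SE = SD/sqrt(n) and confidence interval of replicate values.

    ``method='t'`` uses the Student-t quantile with n−1 degrees of
    freedom (default); ``method='normal'`` uses the normal quantile, the
    convention of reporting CIs "assuming a normal distribution" from a
    handful of repeats.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(
            "N = 1 statistics: at least two replicates are required for an "
            "uncertainty estimate; a single value carries no error bar"
        )
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    mean = float(np.mean(v))
    se = float(np.std(v, ddof=1) / np.sqrt(v.size))
    if method == "t":
        q = stats.t.ppf(0.5 + level / 2.0, df=v.size - 1)
    elif method == "normal":
        q = stats.norm.ppf(0.5 + level / 2.0)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return ReplicateSummary(
        values=v, mean=mean, se=se, ci=(mean - q * se, mean + q * se), level=level,
        method=method,
    )


@dataclass(frozen=True)
class TrendReport:
    """Assessment of a monotone trend across ordered conditions."""

    condition_labels: tuple
    summaries: tuple
    anova_p: float
    slope: float
    slope_ci: tuple[float, float]
    trend_significant: bool
    alpha: float = 0.05


def trend_significance(
    condition_values: Mapping, level: float = 0.95, alpha: float = 0.05
) -> TrendReport:
    """Is there a significant monotone trend across ordered conditions?

    Each condition must carry at least two replicates (single-replicate
    "anecdotal" input is refused).  Reports per-condition confidence
    intervals, a one-way ANOVA across conditions, and the least-squares
    slope of value versus condition index with its CI; the trend is
    called significant only when that CI excludes zero.
    """
    labels = tuple(condition_values.keys())
    if len(labels) < 2:
        raise ValueError("need at least two conditions to assess a trend")
    groups = [np.asarray(condition_values[lab], dtype=float) for lab in labels]
    for lab, g in zip(labels, groups):
        if g.size < 2:
            raise ValueError(
                f"condition {lab!r} has a single replicate: N = 1 statistics "
                "do not support a trend assessment; provide repeats"
            )
    summaries = tuple(replicate_statistics(g, level=level) for g in groups)
    _, anova_p = stats.f_oneway(*groups)
    xs = np.concatenate([np.full(g.size, i, dtype=float) for i, g in enumerate(groups)])
    ys = np.concatenate(groups)
    fit = stats.linregress(xs, ys)
    q = stats.t.ppf(0.5 + level / 2.0, df=xs.size - 2)
    ci = (fit.slope - q * fit.stderr, fit.slope + q * fit.stderr)
    significant = bool(ci[0] > 0 or ci[1] < 0)
    return TrendReport(
        condition_labels=labels,
        summaries=summaries,
        anova_p=float(anova_p),
        slope=float(fit.slope),
        slope_ci=(float(ci[0]), float(ci[1])),
        trend_significant=significant,
        alpha=alpha,
    )
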