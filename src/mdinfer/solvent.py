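"""Finite-size-aware solvent observables: diffusion and radial structure.

Self-diffusion coefficients computed in a periodic box carry a
systematic hydrodynamic finite-size bias; for a cubic box it is removed
by the additive Yeh–Hummer correction

    D_corrected = D_PBC + xi * k_B * T / (6 * pi * eta * L)

with xi = 2.837297 the cubic-lattice self-interaction constant, eta the
shear viscosity and L the box edge.  For protein-containing boxes, where
the protein-restricted water fraction varies with box size, a weighted
average with bulk-water diffusion extrapolates small-box values to a
common reference box.

Radial distribution functions are biased when normalized by the naive
box density while part of the box (the protein) is inaccessible to
solvent: the apparent g(r) is inflated by exactly
V_box / (V_box - V_protein).  ``rdf_spherical`` supports box or
spherical normalization volumes with an explicit excluded volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._units import (
    KB_J_PER_K,
    M2_PER_S_TO_1E5_CM2_PER_S,
    M2_PER_S_TO_NM2_PER_PS,
)

XI_CUBIC = 2.837297  # cubic-lattice hydrodynamic self-interaction constant

__all__ = [
    "DiffusionEstimate",
    "RdfResult",
    "XI_CUBIC",
    "msd_diffusion",
    "yeh_hummer_correction",
    "yeh_hummer_correct",
    "extrapolate_diffusion",
    "rdf_spherical",
]


@dataclass(frozen=True)
class DiffusionEstimate:
    """Self-diffusion estimate (nm^2/ps) from an MSD fit.

    ``chunk_estimates`` are per-chunk diffusion coefficients whose spread
    (``chunk_sd``) serves as an uncertainty scale; ``fit_window`` is the
    lag-time range (ps) used for the linear fit.
    """

    d_pbc: float
    chunk_estimates: np.ndarray
    chunk_sd: float
    fit_window: tuple[float, float]
    msd_times: np.ndarray
    msd: np.ndarray

    @property
    def d_pbc_1e5_cm2_per_s(self) -> float:
        return self.d_pbc / M2_PER_S_TO_NM2_PER_PS * M2_PER_S_TO_1E5_CM2_PER_S


def _msd_fft(pos: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD per lag for one particle track (T, 3)."""
    n = pos.shape[0]
    # standard FFT decomposition: msd(m) = S1(m) - 2*S2(m)
    sq = np.sum(pos**2, axis=1)
    s2 = np.zeros(n)
    for d in range(pos.shape[1]):
        f = np.fft.rfft(pos[:, d], 2 * n)
        acf = np.fft.irfft(f * np.conjugate(f))[:n]
        s2 += acf.real
    sumsq = 2.0 * sq.sum()
    cums_head = np.concatenate([[0.0], np.cumsum(sq)])
    cums_tail = np.concatenate([[0.0], np.cumsum(sq[::-1])])
    s1 = sumsq - cums_head[:n] - cums_tail[:n]
    counts = n - np.arange(n)
    return s1 / counts - 2.0 * s2 / counts


def msd_diffusion(
    positions: np.ndarray,
    dt: float,
    fit_range: tuple[float, float] = (0.1, 0.5),
    n_chunks: int = 5,
    l_box: float | None = None,
) -> DiffusionEstimate:
    """Diffusion coefficient from the ensemble/time-averaged MSD slope.

    ``positions`` must be *unwrapped* coordinates of shape
    (n_frames, n_particles, 3); times in ps, lengths in nm.  The MSD is
    averaged over all time origins and particles, and D is the
    least-squares slope over the ``fit_range`` fraction of the maximal
    lag divided by 6 (three dimensions).  The trajectory is also split
    into ``n_chunks`` pieces fitted independently; their spread is a
    simple uncertainty scale.

    If ``l_box`` is given, any single-step displacement larger than half
    the box triggers an error: such jumps indicate wrapped coordinates,
    which would corrupt the MSD and must be unwrapped by the caller.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3 or pos.shape[2] != 3:
        raise ValueError("positions must have shape (n_frames, n_particles, 3)")
    n_frames = pos.shape[0]
    if n_frames < 100:
        raise ValueError("need at least 100 frames for an MSD fit")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if l_box is not None:
        max_step = np.max(np.abs(np.diff(pos, axis=0)))
        if max_step > l_box / 2:
            raise ValueError(
                "single-step displacement exceeds half the box edge: the "
                "coordinates look wrapped; provide unwrapped positions "
                "(no unwrapping heuristic is applied here)"
            )
    f0, f1 = fit_range
    if not 0 <= f0 < f1 <= 1:
        raise ValueError("fit_range must satisfy 0 <= lo < hi <= 1")

    def fit_d(p: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        n = p.shape[0]
        msd = np.mean([_msd_fft(p[:, i, :]) for i in range(p.shape[1])], axis=0)
        lags = np.arange(n) * dt
        lo = max(1, int(f0 * (n - 1)))
        hi = max(lo + 2, int(f1 * (n - 1)))
        slope, _ = np.polyfit(lags[lo:hi], msd[lo:hi], 1)
        return slope / 6.0, lags, msd

    d_all, lags, msd = fit_d(pos)
    chunk_ds = []
    size = n_frames // n_chunks
    if size >= 10:
        for c in range(n_chunks):
            chunk = pos[c * size : (c + 1) * size]
            chunk_ds.append(fit_d(chunk)[0])
    chunk_ds = np.asarray(chunk_ds)
    sd = float(np.std(chunk_ds, ddof=1)) if chunk_ds.size >= 2 else float("nan")
    n = n_frames
    return DiffusionEstimate(
        d_pbc=float(d_all),
        chunk_estimates=chunk_ds,
        chunk_sd=sd,
        fit_window=(max(1, int(f0 * (n - 1))) * dt, max(int(f1 * (n - 1)), 3) * dt),
        msd_times=lags,
        msd=msd,
    )


def yeh_hummer_correction(
    l_box: float, temperature: float, viscosity: float, xi: float = XI_CUBIC
) -> float:
    """Additive finite-size correction xi*kB*T/(6*pi*eta*L) in nm^2/ps.

    ``l_box`` in nm, ``temperature`` in K, ``viscosity`` in kg/(m s).
    """
    if l_box <= 0 or temperature <= 0:
        raise ValueError("l_box and temperature must be positive")
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    corr_si = xi * KB_J_PER_K * temperature / (6.0 * np.pi * viscosity * l_box * 1e-9)
    return corr_si * M2_PER_S_TO_NM2_PER_PS


def yeh_hummer_correct(
    d_pbc: float,
    l_box: float,
    temperature: float,
    viscosity: float,
    xi: float = XI_CUBIC,
) -> float:
    """Finite-size-corrected diffusion coefficient (nm^2/ps).

    Adds the positive hydrodynamic correction for a cubic periodic box,
    so the corrected value is independent of the box edge for a fluid
    whose raw D follows the 1/L law.
    """
    return d_pbc + yeh_hummer_correction(l_box, temperature, viscosity, xi=xi)


def extrapolate_diffusion(
    d_small: float, n_small: int, d_bulk: float, n_added: int
) -> float:
    """Volume-weighted extrapolation of a small-box D to a larger box.

    Combines the diffusion coefficient measured in the small box
    (``n_small`` water molecules) with the bulk-water coefficient for the
    ``n_added`` molecules a larger box would add:
    (n_small*d_small + n_added*d_bulk) / (n_small + n_added).  This is a
    deliberately simple average of uncorrected coefficients.
    """
    if d_small < 0 or d_bulk < 0:
        raise ValueError("diffusion coefficients must be non-negative")
    if n_small <= 0 or n_added < 0:
        raise ValueError("counts must be positive (n_added may be zero)")
    return (n_small * d_small + n_added * d_bulk) / (n_small + n_added)


@dataclass(frozen=True)
class RdfResult:
    """Radial distribution function with explicit normalization bookkeeping."""

    r: np.ndarray
    g: np.ndarray
    normalization: str
    v_norm: float
    v_excluded: float
    n_frames: int


def rdf_spherical(
    frames,
    l_box: float,
    r_max: float,
    bin_width: float,
    reference: np.ndarray | str = "center",
    normalization: str = "box",
    sphere_radius: float = 4.25,
    v_excluded: float = 0.0,
) -> RdfResult:
    """g(r) around a reference point with box or spherical normalization.

    ``frames`` is a sequence of (N, 3) point configurations in a cubic
    box of edge ``l_box`` (lengths in nm).  Pair counts per shell are
    divided by the shell volume and by the reference density, computed as
    the mean point count over the chosen normalization volume minus
    ``v_excluded`` — the volume inaccessible to the points (a protein,
    say).  Normalization ``'box'`` uses V = l_box^3 and requires
    ``r_max <= l_box/2``; ``'sphere'`` uses V = 4/3 pi R^3 with
    R = ``sphere_radius`` and requires ``r_max <= R``, which makes g(r)
    from differently sized boxes directly comparable.

    Ignoring a genuinely excluded volume (leaving ``v_excluded`` at 0 for
    a protein-containing box) under-states the reference density and
    inflates the apparent g(r) by exactly V/(V - v_excl); stating an
    excluded volume that is not there deflates it by the same factor.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if normalization == "box":
        if r_max > l_box / 2:
            raise ValueError("box normalization requires r_max <= l_box/2")
        v_norm = l_box**3
    elif normalization == "sphere":
        if r_max > sphere_radius:
            raise ValueError("sphere normalization requires r_max <= sphere_radius")
        v_norm = 4.0 / 3.0 * np.pi * sphere_radius**3
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if v_excluded >= v_norm:
        raise ValueError("v_excluded must be smaller than the normalization volume")

    if isinstance(reference, str):
        if reference != "center":
            raise ValueError("reference must be 'center' or an explicit point")
        ref = np.full(3, l_box / 2.0)
    else:
        ref = np.asarray(reference, dtype=float)

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(len(edges) - 1)
    n_points = 0
    n_frames = 0
    for frame in frames:
        pts = np.asarray(frame, dtype=float)
        d = pts - ref
        d -= l_box * np.round(d / l_box)  # minimum image
        r = np.linalg.norm(d, axis=1)
        if normalization == "sphere":
            n_points += int(np.sum(r <= sphere_radius))
        else:
            n_points += len(pts)
        h, _ = np.histogram(r, bins=edges)
        counts += h
        n_frames += 1
    if n_frames == 0:
        raise ValueError("no frames provided")
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = (n_points / n_frames) / (v_norm - v_excluded)
    g = (counts / n_frames) / (shell_vol * rho)
    r_mid = 0.5 * (edges[1:] + edges[:-1])
    return RdfResult(
        r=r_mid,
        g=g,
        normalization=normalization,
        v_norm=float(v_norm),
        v_excluded=float(v_excluded),
        n_frames=n_frames,
    )
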