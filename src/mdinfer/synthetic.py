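"""Synthetic data with the statistical structure of MD-derived observables.

Every generator draws from a closed-form model of the corresponding
simulation observable, so downstream estimators can be validated by
parameter recovery against a known ground truth:

* censored exponential transition times (fixed-length trajectories that
  either cross a barrier or run out),
* Gaussian forward/reverse non-equilibrium work distributions that
  satisfy the Crooks fluctuation relation exactly,
* Boltzmann (Metropolis Monte Carlo) samples of a double-well potential
  under harmonic umbrella restraints,
* stationary AR(1) series as a stand-in for autocorrelated reaction
  coordinates,
* independent Brownian walkers in a periodic box,
* uniform point configurations with a central excluded sphere (a solvent
  box with a "protein" volume carved out),
* i.i.d. Gaussian replicate free-energy estimates.

All generators take an integer seed and are deterministic: a call with
the same seed and parameters returns identical arrays.  Randomness is
consumed in single vectorized draws, so the output does not depend on
any iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from ._units import kt_kj_per_mol
from .kinetics_bayes import TrajectoryOutcome, TransitionData
from .free_energy import UmbrellaWindow, WorkSet

__all__ = [
    "DoubleWellModel",
    "BrownianTrajectory",
    "gen_transition_data",
    "gen_gaussian_work",
    "gen_umbrella_samples",
    "gen_ar1",
    "gen_brownian_box",
    "gen_excluded_config",
    "gen_replicate_dg",
]


@dataclass(frozen=True)
class DoubleWellModel:
    """Quartic double-well potential U(x) = a (x^2 - x0^2)^2 in kT units.

    ``barrier_height`` is the barrier at x = 0 relative to the wells at
    +-``well_separation`` (x0), in units of kT at ``temperature``.  This
    is the minimal model of a system hopping between two conformations.
    """

    barrier_height: float  # kT
    well_separation: float = 1.0  # reduced length, wells at +- this value
    temperature: float = 298.0  # K

    def __post_init__(self) -> None:
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be >= 0")
        if self.well_separation <= 0:
            raise ValueError("well_separation must be positive")

    @property
    def a(self) -> float:
        """Quartic coefficient so that U(0) - U(x0) = barrier_height."""
        return self.barrier_height / self.well_separation**4

    def potential_kt(self, x):
        """U(x) in kT units."""
        x = np.asarray(x, dtype=float)
        return self.a * (x**2 - self.well_separation**2) ** 2

    def potential_kj_per_mol(self, x):
        return self.potential_kt(x) * kt_kj_per_mol(self.temperature)


def gen_transition_data(
    rate: float,
    n_traj: int,
    t_max: float,
    seed: int,
    time_unit: str = "us",
) -> TransitionData:
    """Censored exponential transition outcomes for fixed-length runs.

    Each of ``n_traj`` trajectories draws an exponential waiting time
    with the given ``rate``; draws exceeding ``t_max`` are censored at
    ``t_max`` (type-I censoring at the fixed trajectory length), the
    rest are observed transitions.  ``rate=0`` yields all-censored data.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if n_traj < 1:
        raise ValueError(f"n_traj must be >= 1, got {n_traj}")
    if t_max <= 0:
        raise ValueError(f"t_max must be positive, got {t_max}")
    rng = np.random.default_rng(seed)
    if rate == 0:
        waits = np.full(n_traj, np.inf)
    else:
        waits = rng.exponential(scale=1.0 / rate, size=n_traj)
    outcomes = [
        TrajectoryOutcome(True, float(w), t_max)
        if w <= t_max
        else TrajectoryOutcome(False, None, t_max)
        for w in waits
    ]
    return TransitionData(outcomes, time_unit)


def gen_gaussian_work(
    dg_true: float,
    sigma: float,
    n_fwd: int,
    n_rev: int,
    temperature: float = 298.0,
    seed: int = 0,
) -> WorkSet:
    """Crooks-consistent Gaussian work distributions (energies in kJ/mol).

    Forward works are drawn from Normal(dg_true + beta*sigma^2/2, sigma^2)
    and reverse works (work for the reverse transformation) from
    Normal(-dg_true + beta*sigma^2/2, sigma^2).  For Gaussian work this
    offset of beta*sigma^2/2 (the dissipated work) makes the forward and
    mirrored reverse densities satisfy the Crooks fluctuation relation
    exactly, with crossing point at dg_true.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if n_fwd < 1 or n_rev < 1:
        raise ValueError("work sample counts must be >= 1")
    beta = 1.0 / kt_kj_per_mol(temperature)
    diss = beta * sigma**2 / 2.0
    rng = np.random.default_rng(seed)
    fwd = rng.normal(dg_true + diss, sigma, size=n_fwd)
    rev = rng.normal(-dg_true + diss, sigma, size=n_rev)
    return WorkSet(forward_works=fwd, reverse_works=rev, temperature=temperature)


def _metropolis_windows(
    energy_kt,
    centers: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    step0: float,
    burn_fraction: float = 0.10,
    target_acceptance: float = 0.40,
) -> np.ndarray:
    """Vectorized Metropolis chains, one per window; returns (K, n_samples).

    ``energy_kt(x)`` maps a vector of per-window positions to reduced
    energies.  Step sizes adapt during burn-in towards the target
    acceptance rate, then stay fixed so production sampling is exactly
    Boltzmann.
    """
    n_windows = len(centers)
    n_burn = max(1, int(round(burn_fraction * n_samples)))
    x = centers.astype(float).copy()
    e = energy_kt(x)
    step = np.full(n_windows, step0)
    out = np.empty((n_windows, n_samples))
    accepted = np.zeros(n_windows)
    adapt_every = 50
    total = n_burn + n_samples
    for i in range(total):
        prop = x + rng.uniform(-1.0, 1.0, size=n_windows) * step
        e_prop = energy_kt(prop)
        accept = rng.random(n_windows) < np.exp(np.minimum(0.0, e - e_prop))
        x = np.where(accept, prop, x)
        e = np.where(accept, e_prop, e)
        if i < n_burn:
            accepted += accept
            if (i + 1) % adapt_every == 0:
                frac = accepted / adapt_every
                step *= np.exp(frac - target_acceptance)
                accepted[:] = 0.0
        else:
            out[:, i - n_burn] = x
    return out


def gen_umbrella_samples(
    model: DoubleWellModel,
    centers,
    force_constant: float,
    n_samples: int,
    seed: int = 0,
) -> list[UmbrellaWindow]:
    """Umbrella-sampling windows on a double well via Metropolis MC.

    Each window samples exp(-[U(x) + K/2 (x - c)^2] / kT) with the
    harmonic restraint centred at ``c``.  ``force_constant`` is in
    kJ/mol per squared reduced-length unit; it is converted to kT with
    the model temperature.  Chains are adapted during a 10% burn-in to
    roughly 40% acceptance and the burn-in is discarded.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size < 1:
        raise ValueError("at least one umbrella center is required")
    if force_constant <= 0:
        raise ValueError("force_constant must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    kt = kt_kj_per_mol(model.temperature)
    k_red = force_constant / kt  # kT per length^2

    def energy(x):
        return model.potential_kt(x) + 0.5 * k_red * (x - centers) ** 2

    rng = np.random.default_rng(seed)
    # natural step scale: restrained-harmonic width
    step0 = 2.0 / np.sqrt(k_red)
    samples = _metropolis_windows(energy, centers, n_samples, rng, step0)
    return [
        UmbrellaWindow(
            center=float(c),
            force_constant=force_constant,
            samples=samples[i],
            discard_fraction=0.0,
        )
        for i, c in enumerate(centers)
    ]


def gen_ar1(phi: float, sigma: float, n: int, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) series x_t = phi x_{t-1} + eps_t, eps ~ N(0, sigma^2)."""
    if not abs(phi) < 1:
        raise ValueError(f"|phi| must be < 1 for stationarity, got {phi}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=n)
    # start from the stationary distribution so the whole series is stationary
    x0 = rng.normal(0.0, sigma / np.sqrt(1.0 - phi**2))
    zi = np.array([phi * x0])
    series, _ = lfilter([1.0], [1.0, -phi], eps, zi=zi)
    return series


@dataclass(frozen=True)
class BrownianTrajectory:
    """Position series of independent Brownian walkers in a cubic box.

    ``unwrapped`` has shape (n_steps + 1, n_particles, 3) in box length
    units; ``wrapped`` is the same trajectory folded into [0, l_box).
    """

    unwrapped: np.ndarray
    wrapped: np.ndarray
    l_box: float
    dt: float

    @property
    def n_steps(self) -> int:
        return self.unwrapped.shape[0] - 1

    @property
    def n_particles(self) -> int:
        return self.unwrapped.shape[1]


def gen_brownian_box(
    d_true: float,
    l_box: float,
    n_particles: int,
    n_steps: int,
    dt: float,
    seed: int = 0,
) -> BrownianTrajectory:
    """Independent 3-D Gaussian random walks with diffusion ``d_true``.

    Per-step displacements are Normal(0, 2*d_true*dt) in each dimension.
    Lengths in nm, times in ps by convention (D in nm^2/ps).
    """
    if d_true < 0:
        raise ValueError("d_true must be >= 0")
    if l_box <= 0 or n_particles < 1 or n_steps < 1 or dt <= 0:
        raise ValueError("l_box, n_particles, n_steps and dt must be positive")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, l_box, size=(1, n_particles, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * d_true * dt), size=(n_steps, n_particles, 3))
    unwrapped = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    wrapped = np.mod(unwrapped, l_box)
    return BrownianTrajectory(unwrapped=unwrapped, wrapped=wrapped, l_box=l_box, dt=dt)


def gen_excluded_config(
    density: float,
    l_box: float,
    r_excl: float,
    n_frames: int,
    seed: int = 0,
) -> list[np.ndarray]:
    """Uniform point frames in a box with a central excluded sphere.

    Returns ``n_frames`` arrays of shape (N_f, 3) with points uniform over
    the box minus a sphere of radius ``r_excl`` around the box centre.
    Counts are Poisson with mean density * accessible volume, so the
    achieved density over the accessible volume matches the target.
    """
    if density <= 0 or l_box <= 0 or n_frames < 1:
        raise ValueError("density, l_box and n_frames must be positive")
    if r_excl < 0 or 2 * r_excl >= l_box:
        raise ValueError(f"excluded sphere (r={r_excl}) must fit inside the box")
    rng = np.random.default_rng(seed)
    v_acc = l_box**3 - 4.0 / 3.0 * np.pi * r_excl**3
    center = np.full(3, l_box / 2.0)
    frames = []
    for _ in range(n_frames):
        n_target = rng.poisson(density * v_acc)
        pts = np.empty((0, 3))
        while len(pts) < n_target:
            # rejection sampling; accessible fraction bounds the retry count
            need = n_target - len(pts)
            cand = rng.uniform(0.0, l_box, size=(int(need * 1.5) + 8, 3))
            ok = np.linalg.norm(cand - center, axis=1) >= r_excl
            pts = np.vstack([pts, cand[ok]])
        frames.append(pts[:n_target])
    return frames


def gen_replicate_dg(mu: float, sigma: float, n_rep: int, seed: int = 0) -> np.ndarray:
    """i.i.d. Normal(mu, sigma^2) replicate free-energy estimates (kJ/mol)."""
    if n_rep < 2:
        raise ValueError(f"n_rep must be >= 2 for replicate statistics, got {n_rep}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.normal(mu, sigma, size=n_rep)
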