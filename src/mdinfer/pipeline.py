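"""Configuration and end-to-end orchestration of the analysis stages.

An :class:`AnalysisConfig` names the stages to run, the input files and
the per-stage parameters; :func:`run_pipeline` executes the stages in
order and writes one machine-readable JSON report plus a short
human-readable text summary, embedding seeds and parameters so a run is
reproducible from its report alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import free_energy, io, kinetics_bayes, kinetics_freq, solvent

KNOWN_STAGES = (
    "rates_bayes",
    "rates_freq",
    "anecdote_risk",
    "dg_neq",
    "pmf",
    "acf",
    "replicates",
    "diffusion",
    "rdf",
)

__all__ = ["AnalysisConfig", "run_pipeline", "KNOWN_STAGES"]


@dataclass
class AnalysisConfig:
    """Validated pipeline configuration with Methods-matching defaults."""

    stages: list[str] = field(default_factory=list)
    inputs: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    prior: str = "both"  # uniform | jeffreys | both
    level: float = 0.95
    n_boot: int = 1000
    sizes: list[int] = field(default_factory=lambda: [10, 50, 100, 200, 500])
    n_resample: int = 100
    temperature: float = 298.0
    bins: int = 50
    max_lag: int = 100
    fit_range: tuple[float, float] = (0.1, 0.5)
    dt: float = 1.0
    l_box: float | None = None
    viscosity: float = 3.08e-4  # kg/(m s), shear viscosity of the water model
    r_max: float = 1.0
    bin_width: float = 0.02
    normalization: str = "box"
    sphere_radius: float = 4.25  # nm, spherical RDF normalization radius
    v_excluded: float = 0.0
    pooled: bool = False

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in KNOWN_STAGES:
                raise ValueError(
                    f"unknown stage {stage!r}; known stages: {KNOWN_STAGES}"
                )
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def _require_input(config: AnalysisConfig, key: str, stage: str) -> str:
    try:
        return config.inputs[key]
    except KeyError:
        raise ValueError(f"stage {stage!r} requires input {key!r}") from None


def _stage_rates_bayes(config: AnalysisConfig) -> dict:
    data = io.read_transitions(_require_input(config, "transitions", "rates_bayes"))
    n, theta = kinetics_bayes.sufficient_statistics(data)
    out = {"n": n, "theta": theta, "time_unit": data.time_unit, "priors": {}}
    priors = ["uniform", "jeffreys"] if config.prior == "both" else [config.prior]
    for prior in priors:
        if prior == "jeffreys" and n == 0:
            out["priors"][prior] = {"error": "jeffreys prior requires n >= 1"}
            continue
        post = kinetics_bayes.posterior(data, prior)
        lo, hi = post.interval(config.level)
        out["priors"][prior] = {
            "mean": post.mean,
            "variance": post.variance,
            "interval": [lo, hi],
            "level": config.level,
        }
    if "transitions_b" in config.inputs:
        other = io.read_transitions(config.inputs["transitions_b"])
        bf = kinetics_bayes.bayes_factor(data, other)
        out["comparison"] = {
            "odds_two_processes": bf.odds_two_processes,
            "label": bf.label,
            "pooled": list(bf.pooled),
        }
    return out


def _stage_rates_freq(config: AnalysisConfig) -> dict:
    data = io.read_transitions(_require_input(config, "transitions", "rates_freq"))
    half_life, se = kinetics_freq.bootstrap_half_life(
        data, n_boot=config.n_boot, seed=config.seed
    )
    fit = kinetics_freq.survival_curve(data)
    out = {
        "tau": fit.tau,
        "tau_mle": fit.tau_mle,
        "half_life": half_life,
        "se_half_life": se,
        "n_boot": config.n_boot,
        "time_unit": data.time_unit,
    }
    sizes = [s for s in config.sizes if s <= data.n_total]
    if len(sizes) >= 2:
        curve = kinetics_freq.rate_vs_sample_size(
            data, sizes, n_resample=config.n_resample, seed=config.seed
        )
        out["sample_size_curve"] = {
            "sizes": curve.sizes.tolist(),
            "estimates": curve.estimates.tolist(),
            "ses": curve.ses.tolist(),
            "scaling_exponent": curve.scaling_exponent,
        }
    return out


def _stage_anecdote_risk(config: AnalysisConfig) -> dict:
    path = _require_input(config, "outcome_counts", "anecdote_risk")
    import pandas as pd

    df = pd.read_csv(path)
    counts = kinetics_freq.BoxOutcomeCounts(
        {
            str(row.condition): (int(row.n_transitioned), int(row.n_total))
            for row in df.itertuples()
        }
    )
    out = {}
    for pooled in (False, True):
        probs = kinetics_freq.conclusion_probabilities(counts, pooled=pooled)
        key = "pooled" if pooled else "empirical"
        out[key] = {
            "".join("T" if b else "-" for b in pattern): p
            for pattern, p in probs.items()
        }
    out["conditions"] = list(counts.labels)
    return out


def _stage_dg_neq(config: AnalysisConfig) -> dict:
    works = io.read_works(_require_input(config, "works", "dg_neq"))
    est = free_energy.crooks_mle_dg(works, n_boot=config.n_boot, seed=config.seed)
    return {
        "dg_kj_per_mol": est.dg,
        "se_kj_per_mol": est.se,
        "n_forward": est.n_forward,
        "n_reverse": est.n_reverse,
        "low_overlap": est.low_overlap,
        "temperature_K": works.temperature,
    }


def _stage_pmf(config: AnalysisConfig) -> dict:
    windows = io.read_windows_manifest(_require_input(config, "windows", "pmf"))
    prof = free_energy.mbar_pmf(
        windows, temperature=config.temperature, bins=config.bins
    )
    return {
        "bin_centers": prof.bin_centers.tolist(),
        "dg_kj_per_mol": prof.dg.tolist(),
        "se_kj_per_mol": prof.se.tolist(),
        "alignment": prof.alignment,
        "residual": prof.residual,
    }


def _stage_acf(config: AnalysisConfig) -> dict:
    series = io.read_window_series(_require_input(config, "series", "acf"))
    res = free_energy.acf(series, max_lag=min(config.max_lag, (len(series) - 1) // 2))
    return {
        "acf": res.acf.tolist(),
        "integrated_time": res.integrated_time,
        "inefficiency": res.inefficiency,
    }


def _stage_replicates(config: AnalysisConfig) -> dict:
    values = io.read_replicates(_require_input(config, "replicates", "replicates"))
    summary = free_energy.replicate_statistics(values, level=config.level)
    return {
        "mean": summary.mean,
        "se": summary.se,
        "ci": list(summary.ci),
        "level": summary.level,
        "n_rep": len(summary.values),
    }


def _stage_diffusion(config: AnalysisConfig) -> dict:
    positions = io.read_positions(_require_input(config, "positions", "diffusion"))
    est = solvent.msd_diffusion(
        positions, dt=config.dt, fit_range=config.fit_range, l_box=config.l_box
    )
    out = {
        "d_pbc_nm2_per_ps": est.d_pbc,
        "chunk_sd_nm2_per_ps": est.chunk_sd,
        "d_pbc_1e5_cm2_per_s": est.d_pbc_1e5_cm2_per_s,
    }
    if config.l_box is not None:
        out["d_corrected_nm2_per_ps"] = solvent.yeh_hummer_correct(
            est.d_pbc, config.l_box, config.temperature, config.viscosity
        )
        out["correction_nm2_per_ps"] = solvent.yeh_hummer_correction(
            config.l_box, config.temperature, config.viscosity
        )
    return out


def _stage_rdf(config: AnalysisConfig) -> dict:
    positions = io.read_positions(_require_input(config, "positions", "rdf"))
    if config.l_box is None:
        raise ValueError("stage 'rdf' requires l_box")
    res = solvent.rdf_spherical(
        list(positions),
        l_box=config.l_box,
        r_max=config.r_max,
        bin_width=config.bin_width,
        normalization=config.normalization,
        sphere_radius=config.sphere_radius,
        v_excluded=config.v_excluded,
    )
    return {
        "r": res.r.tolist(),
        "g": res.g.tolist(),
        "normalization": res.normalization,
        "v_norm": res.v_norm,
        "v_excluded": res.v_excluded,
    }


_STAGE_FUNCS = {
    "rates_bayes": _stage_rates_bayes,
    "rates_freq": _stage_rates_freq,
    "anecdote_risk": _stage_anecdote_risk,
    "dg_neq": _stage_dg_neq,
    "pmf": _stage_pmf,
    "acf": _stage_acf,
    "replicates": _stage_replicates,
    "diffusion": _stage_diffusion,
    "rdf": _stage_rdf,
}


def run_pipeline(config: AnalysisConfig, out_dir) -> dict:
    """Run the configured stages; write JSON + text reports to ``out_dir``.

    Returns the report dictionary.  Any stage failure is re-raised with
    the stage name and its inputs attached.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }
    for stage in config.stages:
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed on inputs {config.inputs}: {exc}"
            ) from exc
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    lines = [f"mdinfer report (seed={config.seed})"]
    for stage, res in report["stages"].items():
        lines.append(f"[{stage}]")
        for key, val in res.items():
            if isinstance(val, (int, float, str, bool)):
                lines.append(f"  {key}: {val}")
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
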