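"""Reading and writing the plain tabular formats the analyses consume.

All formats are plain CSV/TSV so that observables exported from any MD
engine (or the synthetic generators) can be fed in without binary
trajectory parsing:

* transitions CSV: ``trajectory_id, observed, event_time, total_time, unit``
* works CSV: ``direction, work`` (kJ/mol) with a ``# temperature_K=...``
  comment header
* window series TSV: two columns ``time  value`` (comment lines starting
  with ``#`` or ``@`` are ignored, so xvg-style exports load directly),
  plus a manifest CSV ``file, center, force_constant, discard_fraction``
* endstate-distance CSV: ``trajectory_id, dist_to_R, dist_to_T``
* positions CSV: ``frame, particle, x, y, z``
* replicates CSV: one ``value`` column
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .free_energy import UmbrellaWindow, WorkSet
from .kinetics_bayes import TrajectoryOutcome, TransitionData

__all__ = [
    "read_endstate_distances",
    "read_transitions",
    "write_transitions",
    "read_works",
    "write_works",
    "read_window_series",
    "write_window_series",
    "read_windows_manifest",
    "write_windows_manifest",
    "read_positions",
    "write_positions",
    "read_replicates",
    "write_replicates",
]


def read_transitions(path) -> TransitionData:
    """Load censored per-trajectory transition outcomes from CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"trajectory_id", "observed", "event_time", "total_time", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no trajectories in file")
    if df["trajectory_id"].duplicated().any():
        dupes = df["trajectory_id"][df["trajectory_id"].duplicated()].tolist()
        warnings.warn(
            f"{path}: duplicated trajectory_id values {dupes}; rows kept",
            stacklevel=2,
        )
    units = df["unit"].unique()
    if len(units) != 1:
        raise ValueError(f"{path}: mixed time units {list(units)}")
    outcomes = []
    for row in df.itertuples():
        observed = bool(row.observed)
        event = row.event_time
        if observed and (event is None or (isinstance(event, float) and np.isnan(event))):
            raise ValueError(
                f"{path} row {row.Index + 2}: observed=true but event_time is missing"
            )
        try:
            outcomes.append(
                TrajectoryOutcome(
                    observed,
                    float(event) if observed else None,
                    float(row.total_time),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {row.Index + 2}: {exc}") from exc
    return TransitionData(outcomes, time_unit=str(units[0]))


def write_transitions(data: TransitionData, path) -> None:
    rows = [
        {
            "trajectory_id": i,
            "observed": o.observed,
            "event_time": repr(float(o.event_time)) if o.observed else "",
            "total_time": repr(float(o.total_time)),
            "unit": data.time_unit,
        }
        for i, o in enumerate(data.outcomes)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_endstate_distances(path) -> pd.DataFrame:
    """Load endpoint distances to the two reference states and classify.

    Expects columns ``trajectory_id, dist_to_R, dist_to_T``; returns the
    table with an added ``endstate`` column ('R' iff strictly closer to
    R, ties conservatively 'T').
    """
    from .kinetics_freq import classify_endstate

    df = pd.read_csv(path, float_precision="round_trip")
    required = {"trajectory_id", "dist_to_R", "dist_to_T"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    df = df.copy()
    df["endstate"] = [
        classify_endstate(r, t) for r, t in zip(df["dist_to_R"], df["dist_to_T"])
    ]
    return df


def read_works(path) -> WorkSet:
    """Load forward/reverse work values (kJ/mol) from CSV."""
    temperature = 298.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "temperature_K" in first:
        temperature = float(first.split("=")[1])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if not {"direction", "work"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns direction, work")
    fwd = df.loc[df["direction"] == "forward", "work"].to_numpy(float)
    rev = df.loc[df["direction"] == "reverse", "work"].to_numpy(float)
    return WorkSet(forward_works=fwd, reverse_works=rev, temperature=temperature)


def write_works(works: WorkSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature_K={works.temperature}\n")
        fh.write("direction,work\n")
        for w in works.forward_works:
            fh.write(f"forward,{float(w)!r}\n")
        for w in works.reverse_works:
            fh.write(f"reverse,{float(w)!r}\n")


def read_window_series(path) -> np.ndarray:
    """Read a two-column "time value" series; '#'/'@' comments ignored."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: expected 'time value' rows, got {line!r}")
            values.append(float(parts[1]))
    if not values:
        raise ValueError(f"{path}: empty series")
    return np.asarray(values)


def write_window_series(samples: np.ndarray, path, dt: float = 1.0) -> None:
    with open(path, "w") as fh:
        fh.write("# time value\n")
        for i, v in enumerate(np.asarray(samples)):
            fh.write(f"{float(i * dt)!r}\t{float(v)!r}\n")


def read_windows_manifest(path) -> list[UmbrellaWindow]:
    """Load umbrella windows from a manifest CSV referencing series files.

    Columns: ``file`` (path relative to the manifest), ``center``,
    ``force_constant`` (kJ/mol per coordinate^2), ``discard_fraction``.
    """
    base = Path(path).parent
    df = pd.read_csv(path)
    required = {"file", "center", "force_constant", "discard_fraction"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    windows = []
    for row in df.itertuples():
        samples = read_window_series(base / str(row.file))
        windows.append(
            UmbrellaWindow(
                center=float(row.center),
                force_constant=float(row.force_constant),
                samples=samples,
                discard_fraction=float(row.discard_fraction),
            )
        )
    return windows


def write_windows_manifest(
    windows: Sequence[UmbrellaWindow], directory, prefix: str = "window"
) -> Path:
    """Write each window's series plus a manifest CSV; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        name = f"{prefix}_{i:03d}.tsv"
        write_window_series(w.samples, directory / name)
        rows.append(
            {
                "file": name,
                "center": w.center,
                "force_constant": w.force_constant,
                "discard_fraction": w.discard_fraction,
            }
        )
    manifest = directory / f"{prefix}_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_positions(path) -> np.ndarray:
    """Load a particle position series CSV into (n_frames, n_particles, 3)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "particle", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    frames = np.sort(df["frame"].unique())
    particles = np.sort(df["particle"].unique())
    df = df.set_index(["frame", "particle"]).sort_index()
    arr = df[["x", "y", "z"]].to_numpy(float).reshape(len(frames), len(particles), 3)
    return arr


def write_positions(positions: np.ndarray, path) -> None:
    n_frames, n_particles, _ = positions.shape
    fi, pi = np.meshgrid(np.arange(n_frames), np.arange(n_particles), indexing="ij")
    df = pd.DataFrame(
        {
            "frame": fi.ravel(),
            "particle": pi.ravel(),
            "x": positions[..., 0].ravel(),
            "y": positions[..., 1].ravel(),
            "z": positions[..., 2].ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_replicates(path) -> np.ndarray:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "value" not in df.columns:
        raise ValueError(f"{path}: expected a 'value' column")
    return df["value"].to_numpy(float)


def write_replicates(values, path) -> None:
    pd.DataFrame({"value": np.asarray(values)}).to_csv(path, index=False)
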