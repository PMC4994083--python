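"""Readers and writers for run artefacts.

Formats: tab-separated trajectories (`generation  species_id  abundance`),
JSON-lines event logs (one generation event per line), JSON manifests
echoing the full configuration and master seed, tab-separated payoff
matrices with a leading ``species_id`` column, and tidy tab-separated sweep
tables.  Decimal separator is always '.'.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import GenerationEvent, Trajectory
from .errors import InvalidParameterError
from .experiments import SweepResult

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_events",
    "write_manifest",
    "read_manifest",
    "write_payoff_matrix",
    "read_payoff_matrix",
    "write_census_table",
    "write_sweep",
]


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    if trajectory.records is None:
        raise InvalidParameterError(
            "trajectory was recorded without abundance records"
        )
    with open(path, "w") as fh:
        fh.write("generation\tspecies_id\tabundance\n")
        for gen, sid, ab in trajectory.records:
            fh.write(f"{gen}\t{sid}\t{ab}\n")


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_events(events: list[GenerationEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(asdict(ev)) + "\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=_jsonify) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_payoff_matrix(
    entries: np.ndarray, species_ids: list[int], path: str | Path
) -> None:
    entries = np.asarray(entries)
    with open(path, "w") as fh:
        fh.write("species_id\t" + "\t".join(str(s) for s in species_ids) + "\n")
        for sid, row in zip(species_ids, entries):
            fh.write(str(sid) + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_payoff_matrix(path: str | Path) -> tuple[np.ndarray, list[int]]:
    """Read a dense payoff matrix; returns (entries, species_ids)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "species_id":
        raise InvalidParameterError(
            f"{path}: first column must be 'species_id', got {df.columns[0]!r}"
        )
    ids = [int(s) for s in df["species_id"]]
    entries = df.drop(columns="species_id").to_numpy(dtype=float)
    if entries.shape[0] != entries.shape[1]:
        raise InvalidParameterError(f"{path}: payoff matrix must be square")
    return entries, ids


def write_census_table(rows: list[dict], path: str | Path) -> None:
    """One row per sampled generation: generation, n_pairs, frac_* columns."""
    cols = [
        "generation", "n_pairs", "frac_coexistence", "frac_bistability",
        "frac_dominance", "frac_degenerate",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def write_sweep(result: SweepResult, out_dir: str | Path, name: str) -> None:
    """Tidy TSV of the sweep plus a JSON manifest with its configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.to_dataframe().to_csv(out / f"{name}.tsv", sep="\t", index=False)
    write_manifest(
        {
            "axis_name": result.axis_name,
            "axis_values": result.axis_values,
            "diagnostics": result.diagnostics,
            "config": result.config_echo,
            "replicate_seeds": [list(s) for s in result.replicate_seeds],
        },
        out / f"{name}.manifest.json",
    )
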