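"""Reading and writing datasets, bases and reconstructed profiles.

Everything is plain text: numeric matrices are UTF-8 comma-delimited files
with a single header row of column labels, and metadata travels in a JSON
sidecar next to each matrix (same stem, ``.json`` extension).  Floats are
written with shortest-round-trip precision, so a write/read cycle is
lossless.  Every sidecar carries a SHA-256 hash of the configuration that
produced the file, so outputs can be traced back to an exact run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import BasisSet, FeatureSpace
from .iem import Reconstruction
from .simulate import NeuronPopulation, SimConfig, SimulatedDataset

__all__ = [
    "config_hash",
    "write_dataset",
    "read_dataset",
    "write_basis",
    "read_basis",
    "write_profiles",
]


def config_hash(mapping: dict) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration mapping."""
    blob = json.dumps(mapping, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def _write_matrix(path: Path, matrix: np.ndarray, columns: list[str], index_name: str):
    # repr() of a Python float is shortest-round-trip, so the write is lossless
    lines = [",".join([index_name, *columns])]
    for i, row in enumerate(np.asarray(matrix, dtype=float)):
        lines.append(",".join([f"{index_name}_{i:04d}", *(repr(v) for v in row.tolist())]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_dataset(dataset: SimulatedDataset, outdir, stem: str = "dataset") -> dict:
    """Write activations (CSV, rows = voxels, columns = trials) plus a JSON
    sidecar with labels and the full generative ground truth.

    Returns a dict of the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat_path = outdir / f"{stem}.csv"
    side_path = outdir / f"{stem}.json"
    columns = [f"trial_{t:04d}" for t in range(dataset.n_trials)]
    _write_matrix(mat_path, dataset.activations, columns, "voxel")
    cfg = dataset.config.to_dict()
    sidecar = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "trial_orientation": dataset.trial_orientation.tolist(),
        "trial_condition": dataset.trial_condition.tolist(),
        "trial_split": dataset.trial_split.tolist(),
        "populations": [
            {
                "centers": p.centers.tolist(),
                "bandwidths": p.bandwidths.tolist(),
                "amplitudes": p.amplitudes.tolist(),
            }
            for p in dataset.populations
        ],
        "shape": list(dataset.activations.shape),
        "units": "response units (arbitrary)",
    }
    side_path.write_text(json.dumps(sidecar, indent=1))
    return {"matrix": mat_path, "sidecar": side_path}


def read_dataset(outdir, stem: str = "dataset") -> SimulatedDataset:
    """Inverse of :func:`write_dataset`; restores labels and ground truth."""
    outdir = Path(outdir)
    df = pd.read_csv(outdir / f"{stem}.csv", float_precision="round_trip")
    activations = df.drop(columns=df.columns[0]).to_numpy(dtype=float)
    side = json.loads((outdir / f"{stem}.json").read_text())
    pops = [
        NeuronPopulation(
            centers=np.asarray(p["centers"], dtype=float),
            bandwidths=np.asarray(p["bandwidths"], dtype=float),
            amplitudes=np.asarray(p["amplitudes"], dtype=float),
        )
        for p in side["populations"]
    ]
    return SimulatedDataset(
        activations=activations,
        trial_orientation=np.asarray(side["trial_orientation"], dtype=float),
        trial_condition=np.asarray(side["trial_condition"], dtype=int),
        trial_split=np.asarray(side["trial_split"], dtype=str),
        config=SimConfig.from_dict(side["config"]),
        populations=pops,
    )


def write_basis(basis: BasisSet, outdir, stem: str = "basis") -> dict:
    """Write the channels x grid matrix plus a JSON sidecar (centres,
    exponent, kind, lineage, period)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat_path = outdir / f"{stem}.csv"
    side_path = outdir / f"{stem}.json"
    columns = [repr(float(g)) for g in basis.space.grid]
    _write_matrix(mat_path, basis.values, columns, "channel")
    sidecar = {
        "period": basis.space.period,
        "grid_size": basis.space.grid_size,
        "centers": basis.centers.tolist(),
        "exponent": basis.exponent,
        "kind": basis.kind,
        "origin_kind": basis.origin_kind,
        "lineage": basis.lineage.tolist(),
    }
    side_path.write_text(json.dumps(sidecar, indent=1))
    return {"matrix": mat_path, "sidecar": side_path}


def read_basis(outdir, stem: str = "basis") -> BasisSet:
    outdir = Path(outdir)
    df = pd.read_csv(outdir / f"{stem}.csv", float_precision="round_trip")
    values = df.drop(columns=df.columns[0]).to_numpy(dtype=float)
    side = json.loads((outdir / f"{stem}.json").read_text())
    return BasisSet(
        space=FeatureSpace(period=side["period"], grid_size=side["grid_size"]),
        centers=np.asarray(side["centers"], dtype=float),
        values=values,
        kind=side["kind"],
        exponent=side["exponent"],
        lineage=np.asarray(side["lineage"], dtype=float),
        origin_kind=side["origin_kind"],
    )


def write_profiles(
    rec: Reconstruction,
    outdir,
    stem: str = "profiles",
    *,
    averaged: dict[int, np.ndarray] | None = None,
    run_config: dict | None = None,
) -> dict:
    """Write per-trial reconstructed profiles (rows = trials, columns =
    channels) and, optionally, condition-averaged profiles, with a JSON
    sidecar recording basis lineage, scheme and units.

    Reconstructed channel responses are in arbitrary units and are
    labelled as such in the sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    columns = [f"channel_{i}" for i in range(rec.basis.k)]
    trial_df = pd.DataFrame(rec.values.T, columns=columns)
    trial_df.insert(0, "trial", rec.trial_indices)
    trial_df.insert(1, "orientation_deg", rec.trial_orientation)
    trial_df.insert(2, "condition", rec.trial_condition)
    paths["trials"] = outdir / f"{stem}_trials.csv"
    trial_df.to_csv(paths["trials"], index=False)
    if averaged is not None:
        avg_df = pd.DataFrame(
            [vals for vals in averaged.values()], columns=columns
        )
        avg_df.insert(0, "condition", list(averaged.keys()))
        paths["averaged"] = outdir / f"{stem}_averaged.csv"
        avg_df.to_csv(paths["averaged"], index=False)
    sidecar = {
        "units": "arbitrary units",
        "scheme": rec.scheme,
        "basis_kind": rec.basis.kind,
        "basis_exponent": rec.basis.exponent,
        "basis_centers": rec.basis.centers.tolist(),
        "basis_lineage": rec.basis.lineage.tolist(),
        "details": {
            key: (value.tolist() if isinstance(value, np.ndarray) else value)
            for key, value in rec.details.items()
        },
    }
    if run_config is not None:
        sidecar["run_config"] = run_config
        sidecar["config_hash"] = config_hash(run_config)
    paths["sidecar"] = outdir / f"{stem}.json"
    paths["sidecar"].write_text(json.dumps(sidecar, indent=1))
    return paths
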