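"""Readers and writers for curve tables, trajectories, and result ledgers.

Curve tables are delimited text (comma or tab, autodetected) with a header
row.  Trajectories are exchanged as multi-model PDB or plain XYZ frames so
that no binary format is required; the CA selection and chain/residue maps
come from the PDB records themselves or, for XYZ, from the caller.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .datatypes import (
    ActivityDecaySeries,
    MeltSeries,
    StabilityRecord,
    TemperatureActivitySeries,
    TrajectoryEnsemble,
)
from .errors import FormatError, StructuralError, ValidationError

_REQUIRED_COLUMNS = {
    "decay": ("time", "activity"),
    "melt": ("temperature",),
    "t50-series": ("temperature", "activity"),
}


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse delimited table: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_curve_table(path, kind: str, variant: str | None = None, temperature: float = 60.0):
    """Read a decay, melt, or residual-activity-vs-temperature table.

    Parameters
    ----------
    path : str or Path
        Delimited text file with a header row.
    kind : {"decay", "melt", "t50-series"}
        Which series type to construct.
    variant : str, optional
        Variant label; overrides a ``variant`` column if both are present.
    temperature : float
        Incubation temperature (deg C) attached to decay series.
    """
    if kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown kind {kind!r}")
    df = _read_table(path)
    for col in _REQUIRED_COLUMNS[kind]:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r} (found {list(df.columns)})")
    if variant is None:
        variant = str(df["variant"].iloc[0]) if "variant" in df.columns else "unknown"

    if kind == "decay":
        return ActivityDecaySeries(
            variant=variant,
            temperature=temperature,
            times=df["time"].to_numpy(float),
            activities=df["activity"].to_numpy(float),
        )
    if kind == "t50-series":
        return TemperatureActivitySeries(
            variant=variant,
            temperatures=df["temperature"].to_numpy(float),
            activities=df["activity"].to_numpy(float),
        )
    if "ratio" not in df.columns and "sls" not in df.columns:
        raise FormatError(f"{path}: melt table needs a 'ratio' and/or 'sls' column")
    return MeltSeries(
        variant=variant,
        temperatures=df["temperature"].to_numpy(float),
        ratio=df["ratio"].to_numpy(float) if "ratio" in df.columns else None,
        sls=df["sls"].to_numpy(float) if "sls" in df.columns else None,
    )


def _frames_from_pdb(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        raise StructuralError(f"{path}: inconsistent models ({exc})") from exc
    if not isinstance(stack, struc.AtomArrayStack):
        stack = struc.stack([stack])
    ca = stack[:, stack.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValidationError(f"{path}: no CA atoms found")
    return ca.coord.copy(), ca.res_id[:].copy(), ca.chain_id[:].copy()


def _frames_from_xyz(path) -> np.ndarray:
    """Parse concatenated plain XYZ frames (natoms / comment / atom lines)."""
    frames = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise StructuralError(f"{path}: frame {len(frames)} truncated ({len(block)}/{n} atoms)")
        coords = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    n0 = frames[0].shape[0]
    for k, f in enumerate(frames):
        if f.shape[0] != n0:
            raise StructuralError(f"{path}: frame {k} atom count {f.shape[0]} != {n0}")
    return np.stack(frames)


def read_trajectory(
    paths: Sequence,
    fmt: str = "pdb",
    resids: Iterable[int] | None = None,
    chains: Iterable[str] | None = None,
    chain_pairing: dict[int, int] | None = None,
    frame_interval_ps: float = 10.0,
) -> TrajectoryEnsemble:
    """Load one or more replicate trajectory files into a CA-atom ensemble.

    PDB files supply residue and chain ids directly (one CA per residue);
    XYZ files carry coordinates only, so ``resids``/``chains`` default to
    sequential numbering on a single chain unless given.
    """
    if fmt not in ("pdb", "xyz"):
        raise ValueError(f"unknown trajectory format {fmt!r}")
    reps, ref_resids, ref_chains = [], None, None
    for path in paths:
        if fmt == "pdb":
            coords, rid, cid = _frames_from_pdb(path)
        else:
            coords = _frames_from_xyz(path)
            n = coords.shape[1]
            rid = np.asarray(list(resids) if resids is not None else np.arange(1, n + 1))
            cid = np.asarray(list(chains) if chains is not None else ["A"] * n)
        if ref_resids is None:
            ref_resids, ref_chains = rid, cid
        elif coords.shape[1] != len(ref_resids):
            raise StructuralError(f"{path}: atom count {coords.shape[1]} differs across replicates")
        reps.append(coords)
    if chain_pairing is not None:
        known = set(np.unique(ref_chains))
        if len(known) < 2 and len(chain_pairing) and set(chain_pairing) - set(ref_resids.tolist()):
            raise ValidationError("chain pairing references residues absent from the structure")
    return TrajectoryEnsemble(
        replicates=reps,
        resids=ref_resids,
        chains=ref_chains,
        chain_pairing=chain_pairing,
        frame_interval_ps=frame_interval_ps,
    )


def _jsonable(value):
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    return value


def write_records(records: Iterable[StabilityRecord], path) -> None:
    """Serialize stability records to JSON; NaN fields become null."""
    payload = []
    for rec in records:
        rec.validate()
        d = dataclasses.asdict(rec)
        payload.append({k: _jsonable(v) for k, v in d.items()})
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_records(path) -> list[StabilityRecord]:
    raw = json.loads(Path(path).read_text())
    records = []
    for entry in raw:
        entry = {k: (math.nan if v is None else v) for k, v in entry.items()}
        for key in ("se", "r2"):
            if isinstance(entry.get(key), float) and math.isnan(entry[key]):
                entry[key] = {}
        records.append(StabilityRecord(**entry))
    return records


def write_matrix_tsv(matrix: np.ndarray, labels: Sequence, path) -> None:
    """Write a square matrix as TSV with residue-id headers on both axes."""
    df = pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", index_label="residue")


def read_matrix_tsv(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), [int(c) for c in df.columns]


def write_profile_tsv(resids: Sequence[int], values: np.ndarray, path, column: str = "rmsf") -> None:
    pd.DataFrame({"residue": list(resids), column: np.asarray(values)}).to_csv(
        path, sep="\t", index=False
    )
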