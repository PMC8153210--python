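"""File I/O helpers: SMILES files in, CSV/JSON reports out.

Readers accept ``.smi`` (whitespace-separated ``SMILES [name]`` records) and
CSV files with a ``smiles`` column.  Writers emit deterministic column
orders with floats at 4 decimals and embed a hash of the generating
configuration so a report can be traced back to its run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
from rdkit import Chem

from .pathing import ChemicalPath, MedianCandidate
from .subspace import SubspaceReport

__all__ = ["read_smiles_file", "config_hash", "write_subspace_report",
           "write_chemical_path", "write_median_candidates"]

log = logging.getLogger("stoned")


def read_smiles_file(path: str | Path, on_error: str = "warn",
                     ) -> list[tuple[str, str | None]]:
    """Read (smiles, optional name) records from a .smi or CSV file.

    Malformed SMILES are reported with their line number and either skipped
    (``on_error="warn"``, default) or fatal (``on_error="raise"``).
    """
    if on_error not in ("warn", "raise"):
        raise ValueError("on_error must be 'warn' or 'raise'")
    path = Path(path)
    records: list[tuple[str, str | None, int]] = []
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path)
        if "smiles" not in frame.columns:
            raise ValueError(f"{path}: CSV needs a 'smiles' column")
        names = frame["name"] if "name" in frame.columns else None
        for i, smi in enumerate(frame["smiles"]):
            name = None if names is None or pd.isna(names.iloc[i]) \
                else str(names.iloc[i])
            records.append((str(smi), name, i + 2))  # 1-based + header
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                records.append((parts[0],
                                parts[1] if len(parts) > 1 else None, lineno))
    out: list[tuple[str, str | None]] = []
    for smi, name, lineno in records:
        if Chem.MolFromSmiles(smi) is None:
            msg = f"{path}: line {lineno}: cannot parse SMILES {smi!r}"
            if on_error == "raise":
                raise ValueError(msg)
            log.warning(msg)
            continue
        out.append((smi, name))
    if not out:
        log.warning("%s: no valid SMILES records", path)
    return out


def config_hash(config: dict[str, Any]) -> str:
    """Short stable hash of a run configuration, for report provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(frame: pd.DataFrame, path: Path, config: dict) -> None:
    frame = frame.copy()
    for col in frame.columns:
        if frame[col].dtype.kind == "f":
            frame[col] = frame[col].map(lambda v: f"{v:.4f}")
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash(config)}\n")
        frame.to_csv(fh, index=False)


def write_subspace_report(report: SubspaceReport, path: str | Path,
                          config: dict | None = None) -> None:
    """CSV of unique molecules + JSON sidecar with the threshold table."""
    path = Path(path)
    config = config or {}
    _write_csv(report.to_frame(), path, config)
    sidecar = {
        "seed_smiles": report.seed_smiles,
        "representation": report.representation.value,
        "fingerprint": report.fingerprint_kind,
        "n_orderings": report.n_orderings,
        "n_strings_generated": report.n_strings_generated,
        "n_valid": report.n_valid,
        "n_unique": report.n_unique,
        "validity_percent": round(report.validity_percent, 4),
        "thresholds": report.threshold_table(),
        "scaffold_retention": report.scaffold_retention,
        "config_hash": config_hash(config),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def write_chemical_path(path_obj: ChemicalPath, path: str | Path,
                        config: dict | None = None) -> None:
    """CSV of a chemical path, ordered start → target."""
    data = {"smiles": path_obj.molecules,
            "sim_to_start": path_obj.sims_to_start,
            "sim_to_target": path_obj.sims_to_target}
    for name, values in (path_obj.properties or {}).items():
        data[name] = values
    _write_csv(pd.DataFrame(data), Path(path), config or {})


def write_median_candidates(candidates: list[MedianCandidate],
                            path: str | Path,
                            config: dict | None = None) -> None:
    """CSV of ranked median candidates with per-reference similarities."""
    n_refs = len(candidates[0].sims) if candidates else 0
    data: dict[str, list] = {"smiles": [c.smiles for c in candidates]}
    for i in range(n_refs):
        data[f"sim_ref{i + 1}"] = [c.sims[i] for c in candidates]
    data["joint"] = [c.joint for c in candidates]
    data["no_bridgehead"] = [c.passes_bridgehead_filter for c in candidates]
    _write_csv(pd.DataFrame(data), Path(path), config or {})
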