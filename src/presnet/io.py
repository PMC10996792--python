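"""Readers, writers and configuration for the analysis pipeline.

All tables are comma-delimited text with headers; graphs are written both
as two-column edge lists and as GraphML with typed node attributes. Every
pipeline run writes a manifest (inputs, configuration hash, seed, package
versions) so that a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

__all__ = [
    "ClaimsValidationError",
    "PipelineConfig",
    "read_claims",
    "read_table",
    "write_table",
    "write_graph",
    "read_edgelist",
    "config_hash",
]

_REQUIRED_COLUMNS = {
    "fills": ["patient_id", "prescriber_id", "drug_id", "drug_class", "start_day", "days_supply"],
    "encounters": ["patient_id", "physician_id", "day"],
    "physicians": ["physician_id", "specialty", "region"],
    "patients": ["patient_id", "region"],
}

_VALID_CLASSES = {"O", "B", "S"}


class ClaimsValidationError(ValueError):
    """Malformed claims input, with the offending file and row."""


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str, "physician_id": str, "prescriber_id": str})


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, kind: str, path) -> None:
    missing = [c for c in _REQUIRED_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ClaimsValidationError(f"{path}: missing column(s) {missing}")


def _require_int(df: pd.DataFrame, col: str, path, lo=None, hi=None) -> pd.Series:
    try:
        vals = pd.to_numeric(df[col], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        raise ClaimsValidationError(f"{path}: column {col!r} is not integer: {exc}") from None
    bad = pd.Series(False, index=df.index)
    if lo is not None:
        bad |= vals < lo
    if hi is not None:
        bad |= vals >= hi
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based + header line
        raise ClaimsValidationError(
            f"{path}: column {col!r} out of range at line {row} (value {vals[bad].iloc[0]})"
        )
    return vals


def read_claims(
    fills_path, encounters_path, physicians_path, patients_path, year_days: int = 365
):
    """Read and validate the four claims-like input tables.

    Returns ``(fills, encounters, physicians, patients)``. Malformed rows
    (unknown drug class, out-of-year days, non-positive supply) raise
    :class:`ClaimsValidationError` naming the file and line.
    """
    fills = read_table(fills_path)
    _require_columns(fills, "fills", fills_path)
    bad = ~fills["drug_class"].isin(_VALID_CLASSES)
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise ClaimsValidationError(
            f"{fills_path}: unknown drug_class {fills['drug_class'][bad].iloc[0]!r} at line {row}"
        )
    fills["start_day"] = _require_int(fills, "start_day", fills_path, 0, year_days)
    fills["days_supply"] = _require_int(fills, "days_supply", fills_path, 1, None)

    encounters = read_table(encounters_path)
    _require_columns(encounters, "encounters", encounters_path)
    encounters["day"] = _require_int(encounters, "day", encounters_path, 0, year_days)

    physicians = read_table(physicians_path)
    _require_columns(physicians, "physicians", physicians_path)
    patients = read_table(patients_path)
    _require_columns(patients, "patients", patients_path)
    return fills, encounters, physicians, patients


def write_graph(net: nx.Graph, stem: str | Path) -> None:
    """Write a graph as ``<stem>.edgelist`` and ``<stem>.graphml``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    with open(stem.with_suffix(".edgelist"), "w") as fh:
        for i, j in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{i},{j}\n")
    clean = net.copy()
    for _, data in clean.nodes(data=True):  # GraphML cannot carry None
        for k in [k for k, v in data.items() if v is None]:
            del data[k]
    nx.write_graphml(clean, stem.with_suffix(".graphml"))


def read_edgelist(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                i, j = line.split(",")
                g.add_edge(i, j)
    return g


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults are the study constants.

    Either ``input_dir`` points at existing claims tables or
    ``simulation`` configures the synthetic generator.
    """

    input_dir: str | None = None
    simulation: dict = field(default_factory=dict)
    year_days: int = 365
    merge_buffer_fraction: float = 0.2
    deprescribe_min_length: int = 30
    deprescribe_visit_window: int = 30
    min_region_nodes: int = 100
    ergm_indexes: tuple = ("IeverOBS", "IOBS", "Ipresc2mr", "Idepresc2mr")
    n_perm: int = 30
    seed: int = 0
    output_dir: str = "presnet_run"
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("merge_buffer_fraction", "deprescribe_min_length",
                     "deprescribe_visit_window", "min_region_nodes", "year_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ergm_indexes" in data:
            data["ergm_indexes"] = tuple(data["ergm_indexes"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ergm_indexes"] = list(d["ergm_indexes"])
        return d


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the full configuration (any default change changes it)."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
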