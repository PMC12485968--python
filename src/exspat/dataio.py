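"""On-disk schemas for spot / cell / sample tables, with readers, writers
and a dataset validator.

All tables are UTF-8 TSV with a header row and '.' decimal separator.
The unassigned sentinel is the literal string ``"NA"`` (kept as a string in
memory as well, so round trips are bit-exact). Coordinates are FOV-local
biological micrometres; ``fov_offsets.tsv`` places FOVs in sample space
when cross-FOV geometry is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

UNASSIGNED = "NA"
COMPARTMENTS = ("nuclear", "cytoplasmic", UNASSIGNED)
REGIONS = ("CA1", "CA3", "DG", "SLM", "DG-CA1", "SO", "Hilus")
CONDITIONS = ("5xFAD", "WT")

SPOT_COLUMNS = {
    "spot_id": str,
    "gene": str,
    "x": float,
    "y": float,
    "z": float,
    "fov_id": str,
    "sample_id": str,
    "cell_id": str,
    "compartment": str,
}
CELL_COLUMNS = {
    "cell_id": str,
    "sample_id": str,
    "fov_id": str,
    "cx": float,
    "cy": float,
    "cz": float,
    "radius": float,
    "cell_type": str,
    "region": str,
    "condition": str,
}
SAMPLE_COLUMNS = {
    "sample_id": str,
    "condition": str,
    "mouse_id": str,
    "replicate_role": str,
}
FOV_OFFSET_COLUMNS = {"fov_id": str, "x_offset": float, "y_offset": float, "z_offset": float}


class SchemaError(ValueError):
    """A table does not match its declared schema (e.g. missing column)."""


class PanelError(ValueError):
    """A table references genes outside the declared panel."""


def _read_table(path: str | Path, columns: dict[str, type]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    for col, typ in columns.items():
        if typ is float:
            df[col] = pd.to_numeric(df[col])
    return df


def _write_table(df: pd.DataFrame, path: str | Path, columns: dict[str, type]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {Path(path).name}: missing column(s): {', '.join(missing)}")
    # Required columns first, unknown extras preserved after them.
    extras = [c for c in df.columns if c not in columns]
    df[list(columns) + extras].to_csv(path, sep="\t", index=False)


def read_spots(path: str | Path, panel: Sequence[str] | None = None) -> pd.DataFrame:
    spots = _read_table(path, SPOT_COLUMNS)
    if panel is not None:
        check_panel(spots["gene"], panel)
    return spots


def write_spots(spots: pd.DataFrame, path: str | Path) -> None:
    _write_table(spots, path, SPOT_COLUMNS)


def read_cells(path: str | Path) -> pd.DataFrame:
    return _read_table(path, CELL_COLUMNS)


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    _write_table(cells, path, CELL_COLUMNS)


def read_samples(path: str | Path) -> pd.DataFrame:
    return _read_table(path, SAMPLE_COLUMNS)


def write_samples(sheet: pd.DataFrame, path: str | Path) -> None:
    _write_table(sheet, path, SAMPLE_COLUMNS)


def read_fov_offsets(path: str | Path) -> pd.DataFrame:
    return _read_table(path, FOV_OFFSET_COLUMNS)


def write_fov_offsets(offsets: pd.DataFrame, path: str | Path) -> None:
    _write_table(offsets, path, FOV_OFFSET_COLUMNS)


def read_panel(path: str | Path) -> list[str]:
    """Panel file: one gene symbol per line; defines the closed vocabulary."""
    lines = Path(path).read_text().splitlines()
    panel = [ln.strip() for ln in lines if ln.strip()]
    if len(set(panel)) != len(panel):
        raise PanelError("panel contains duplicate gene symbols")
    return panel


def write_panel(panel: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(panel) + "\n")


def check_panel(genes: pd.Series, panel: Sequence[str]) -> None:
    offenders = sorted(set(genes) - set(panel))
    if offenders:
        raise PanelError(f"genes outside the declared panel: {', '.join(offenders)}")


@dataclass
class Issue:
    kind: str
    message: str


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    def add(self, kind: str, message: str) -> None:
        self.issues.append(Issue(kind, message))

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)

    def summary(self) -> str:
        if self.ok:
            return "dataset consistent (0 issues)"
        return "\n".join(f"[{i.kind}] {i.message}" for i in self.issues)


def validate_dataset(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    sheet: pd.DataFrame,
    panel: Sequence[str] | None = None,
    fov_size: tuple[float, float, float] | None = None,
) -> ValidationReport:
    """Check cross-table consistency; violations become report entries, never
    exceptions."""
    rep = ValidationReport()

    dup = spots["spot_id"][spots["spot_id"].duplicated()]
    for sid in dup.unique():
        rep.add("duplicate_spot_id", f"spot_id {sid} occurs more than once")
    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    for cid in dup.unique():
        rep.add("duplicate_cell_id", f"cell_id {cid} occurs more than once")

    if panel is not None:
        for g in sorted(set(spots["gene"]) - set(panel)):
            rep.add("gene_not_in_panel", f"gene {g} not in declared panel")

    bad_comp = sorted(set(spots["compartment"]) - set(COMPARTMENTS))
    for c in bad_comp:
        rep.add("bad_compartment", f"unknown compartment label {c!r}")
    # cell_id unassigned forces compartment unassigned
    mask = (spots["cell_id"] == UNASSIGNED) & (spots["compartment"] != UNASSIGNED)
    for sid in spots.loc[mask, "spot_id"]:
        rep.add("compartment_without_cell", f"spot {sid} has a compartment but no cell")

    known_cells = set(cells["cell_id"])
    assigned = spots[spots["cell_id"] != UNASSIGNED]
    dangling = sorted(set(assigned["cell_id"]) - known_cells)
    for cid in dangling:
        rep.add("dangling_cell_ref", f"spots reference absent cell_id {cid}")

    known_samples = set(sheet["sample_id"])
    for table, name in ((spots, "spots"), (cells, "cells")):
        for sid in sorted(set(table["sample_id"]) - known_samples):
            rep.add("unknown_sample", f"{name} reference sample_id {sid} absent from sample sheet")
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    for sid in dup.unique():
        rep.add("duplicate_sample", f"sample_id {sid} listed more than once in sample sheet")

    for _, row in cells[cells["radius"] <= 0].iterrows():
        rep.add("nonpositive_radius", f"cell {row['cell_id']} has radius {row['radius']}")
    for r in sorted(set(cells["region"]) - set(REGIONS)):
        rep.add("bad_region", f"unknown region label {r!r}")

    cond = dict(zip(sheet["sample_id"], sheet["condition"]))
    mism = cells[cells.apply(lambda r: cond.get(r["sample_id"], r["condition"]) != r["condition"], axis=1)]
    for _, row in mism.iterrows():
        rep.add(
            "condition_mismatch",
            f"cell {row['cell_id']} condition {row['condition']!r} differs from its sample's",
        )

    if fov_size is not None:
        w, h, d = fov_size
        oob = spots[
            (spots["x"] < 0) | (spots["x"] >= w) | (spots["y"] < 0) | (spots["y"] >= h)
        ]
        for sid in oob["spot_id"]:
            rep.add("spot_out_of_fov", f"spot {sid} lies outside the lateral FOV extent")

    return rep


def dataset_paths(directory: str | Path) -> dict[str, Path]:
    d = Path(directory)
    return {
        "spots": d / "spots.tsv",
        "cells": d / "cells.tsv",
        "samples": d / "samples.tsv",
        "panel": d / "panel.txt",
        "fov_offsets": d / "fov_offsets.tsv",
        "ground_truth": d / "ground_truth.json",
        "config": d / "sim_config.yaml",
    }
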