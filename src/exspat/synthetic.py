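"""Synthetic ExSeq-like point-cloud datasets with planted, independently
tunable effects.

The generator emulates the structure of a super-resolved in situ sequencing
study of mouse hippocampus: a 101-gene panel read out in 100 × 100 μm
(× 30 μm axial) fields of view at ~8,000 molecules per FOV, 3 biological
mice per condition (5xFAD vs WT) with one technical replicate, across seven
hippocampal regions. Cells are modeled as spheres; the nuclear compartment
is the inner sphere at 60% of the cell radius, the cytoplasm the shell
outside it, so compartment labels are purely geometric. A configurable
fraction of molecules (default 10%) is left unassigned to any cell,
mimicking imperfect segmentation.

Planted effect classes, each independently tunable and recorded in a
ground-truth sidecar:

``expression_shift``
    fold change of one gene's per-FOV abundance in one condition;
``spatial_shift``
    reorganization of one gene's positions into tight clusters without any
    change in per-FOV counts (spatial-only by construction);
``velocity_shift``
    multiplication of one gene's nuclear:cytoplasmic odds within one cell
    type, conserving per-cell totals;
``module_shift``
    a multi-gene module whose molecules are redistributed across cells of
    one type along a shared spatial gradient (a co-occurring
    spatially-variable gene set), conserving per-FOV totals;
``proximity_velocity``
    a cell-level nuclear:cytoplasmic odds boost that decays exponentially
    with boundary distance to a target cell type.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import dataio
from ._utils import child_seed
from .dataio import UNASSIGNED

NUCLEAR_INNER_FRACTION = 0.6

EFFECT_KINDS = (
    "expression_shift",
    "spatial_shift",
    "velocity_shift",
    "module_shift",
    "proximity_velocity",
)


class ConfigError(ValueError):
    """A simulation configuration violates an invariant; names the field."""


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    frequency: float
    mean_radius: float  # μm


@dataclass(frozen=True)
class PlantedEffect:
    """One planted effect; ``magnitude`` is kind-specific (fold change,
    cluster concentration, nuclear:cytoplasmic odds multiplier, gradient
    slope, or odds boost at zero distance)."""

    kind: str
    gene: str | tuple[str, ...]
    condition: str
    magnitude: float
    regions: tuple[str, ...] | None = None  # None = all regions
    cell_type: str = "all"
    target_type: str | None = None  # proximity_velocity only
    decay_scale: float = 0.5  # μm, proximity_velocity only

    def genes(self) -> tuple[str, ...]:
        return (self.gene,) if isinstance(self.gene, str) else tuple(self.gene)


DEFAULT_CELL_TYPES = (
    CellTypeSpec("excitatory", 0.45, 6.0),
    CellTypeSpec("inhibitory", 0.15, 6.0),
    CellTypeSpec("microglia", 0.15, 5.0),
    CellTypeSpec("astrocyte", 0.15, 5.0),
    CellTypeSpec("endothelial", 0.10, 4.0),
)


@dataclass
class SimulationConfig:
    seed: int  # mandatory: no silent default entropy
    n_genes: int = 101
    n_samples_per_condition: int = 4
    fovs_per_region_per_sample: int = 6
    fov_size: tuple[float, float, float] = (100.0, 100.0, 30.0)
    mean_molecules_per_fov: float = 8000.0
    cells_per_fov: float = 30.0
    regions: tuple[str, ...] = dataio.REGIONS
    cell_types: tuple[CellTypeSpec, ...] = DEFAULT_CELL_TYPES
    conditions: tuple[str, str] = dataio.CONDITIONS
    unassigned_fraction: float = 0.1
    nuclear_fraction_range: tuple[float, float] = (0.2, 0.5)
    gene_abundance_sd: float = 0.5  # log-normal spread of per-gene abundance
    region_profile_sd: float = 0.35  # log-normal per-(region, gene) modulation
    planted_effects: tuple[PlantedEffect, ...] = ()

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed: a seed is mandatory")
        for name in ("n_genes", "n_samples_per_condition", "fovs_per_region_per_sample"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be >= 1")
        if any(s <= 0 for s in self.fov_size):
            raise ConfigError("fov_size: all extents must be strictly positive")
        if self.mean_molecules_per_fov < 1 or self.cells_per_fov < 1:
            raise ConfigError("mean_molecules_per_fov/cells_per_fov: must be >= 1")
        if not self.regions:
            raise ConfigError("regions: at least one region required")
        unknown = set(self.regions) - set(dataio.REGIONS)
        if unknown:
            raise ConfigError(f"regions: outside the fixed vocabulary: {sorted(unknown)}")
        freq = sum(t.frequency for t in self.cell_types)
        if abs(freq - 1.0) > 1e-6:
            raise ConfigError(f"cell_types: frequencies sum to {freq:.4f}, expected 1")
        if any(t.mean_radius <= 0 for t in self.cell_types):
            raise ConfigError("cell_types: mean_radius must be positive")
        if not 0 <= self.unassigned_fraction < 1:
            raise ConfigError("unassigned_fraction: must be in [0, 1)")
        lo, hi = self.nuclear_fraction_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("nuclear_fraction_range: need 0 < lo <= hi < 1")
        panel = set(self.panel())
        typenames = {t.name for t in self.cell_types}
        for eff in self.planted_effects:
            if eff.kind not in EFFECT_KINDS:
                raise ConfigError(f"planted_effects: unknown kind {eff.kind!r}")
            if eff.magnitude <= 0:
                raise ConfigError("planted_effects: magnitude must be > 0")
            if eff.condition not in self.conditions:
                raise ConfigError(f"planted_effects: unknown condition {eff.condition!r}")
            if eff.regions is not None and set(eff.regions) - set(self.regions):
                raise ConfigError("planted_effects: region outside simulated regions")
            if eff.cell_type != "all" and eff.cell_type not in typenames:
                raise ConfigError(f"planted_effects: unknown cell_type {eff.cell_type!r}")
            if eff.kind == "proximity_velocity":
                if eff.target_type not in typenames:
                    raise ConfigError("planted_effects: proximity_velocity needs a valid target_type")
                if eff.decay_scale <= 0:
                    raise ConfigError("planted_effects: decay_scale must be > 0")
            if eff.gene != "all":
                bad = set(eff.genes()) - panel
                if bad:
                    raise ConfigError(f"planted_effects: gene(s) not in panel: {sorted(bad)}")

    def panel(self) -> list[str]:
        width = max(3, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cell_types"] = [dataclasses.asdict(t) for t in self.cell_types]
        d["planted_effects"] = [dataclasses.asdict(e) for e in self.planted_effects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "cell_types" in d:
            d["cell_types"] = tuple(CellTypeSpec(**t) for t in d["cell_types"])
        if "planted_effects" in d:
            effs = []
            for e in d["planted_effects"]:
                e = dict(e)
                if isinstance(e.get("gene"), list):
                    e["gene"] = tuple(e["gene"])
                if isinstance(e.get("regions"), list):
                    e["regions"] = tuple(e["regions"])
                effs.append(PlantedEffect(**e))
            d["planted_effects"] = tuple(effs)
        for key in ("fov_size", "regions", "conditions", "nuclear_fraction_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted-effect records emitted alongside the dataset."""

    effects: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"effects": self.effects}, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(effects=json.loads(text)["effects"])


@dataclass
class Dataset:
    spots: pd.DataFrame
    cells: pd.DataFrame
    samples: pd.DataFrame
    fov_offsets: pd.DataFrame
    panel: list[str]
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# geometry helpers


def _sample_in_sphere_shell(
    centers: np.ndarray, r_lo: np.ndarray, r_hi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points in the spherical shell r in [r_lo, r_hi) around centers."""
    n = len(centers)
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    u = rng.random(n)
    radii = np.cbrt(r_lo**3 + (r_hi**3 - r_lo**3) * u)
    return centers + direction * radii[:, None]


def _positions_in_cells(
    centroids: np.ndarray,
    radii: np.ndarray,
    nuclear: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    inner = NUCLEAR_INNER_FRACTION * radii
    r_lo = np.where(nuclear, 0.0, inner)
    r_hi = np.where(nuclear, inner, radii)
    return _sample_in_sphere_shell(centroids, r_lo, r_hi, rng)


# ---------------------------------------------------------------------------
# baseline generation


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cond in config.conditions:
        for i in range(1, config.n_samples_per_condition + 1):
            # up to three distinct mice per condition; further samples are
            # technical replicates of the third mouse
            mouse = min(i, 3)
            rows.append(
                {
                    "sample_id": f"{cond}_s{i}",
                    "condition": cond,
                    "mouse_id": f"{cond}_m{mouse}",
                    "replicate_role": "biological" if i <= 3 else "technical",
                }
            )
    return pd.DataFrame(rows)


def _panel_parameters(config: SimulationConfig):
    rng = np.random.default_rng(child_seed(config.seed, "panel"))
    abundance = rng.lognormal(mean=0.0, sigma=config.gene_abundance_sd, size=config.n_genes)
    lo, hi = config.nuclear_fraction_range
    nuclear_fraction = rng.uniform(lo, hi, size=config.n_genes)
    region_mod = rng.lognormal(
        mean=0.0, sigma=config.region_profile_sd, size=(len(config.regions), config.n_genes)
    )
    return abundance, nuclear_fraction, region_mod


def _generate_fov_cells(
    fov_id: str,
    sample_id: str,
    region: str,
    condition: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    w, h, d = config.fov_size
    n = max(1, rng.poisson(config.cells_per_fov))
    freqs = np.array([t.frequency for t in config.cell_types])
    type_idx = rng.choice(len(config.cell_types), size=n, p=freqs / freqs.sum())
    mean_r = np.array([t.mean_radius for t in config.cell_types])[type_idx]
    radius = np.clip(rng.normal(mean_r, 0.12 * mean_r), 0.4 * mean_r, 1.6 * mean_r)
    # keep the sphere inside the FOV so geometric compartments stay in-bounds
    cx = rng.uniform(radius, w - radius)
    cy = rng.uniform(radius, h - radius)
    cz = rng.uniform(radius, d - radius)
    return pd.DataFrame(
        {
            "cell_id": [f"{fov_id}:c{i}" for i in range(n)],
            "sample_id": sample_id,
            "fov_id": fov_id,
            "cx": cx,
            "cy": cy,
            "cz": cz,
            "radius": radius,
            "cell_type": [config.cell_types[i].name for i in type_idx],
            "region": region,
            "condition": condition,
        }
    )


def _generate_fov_spots(
    fov_id: str,
    sample_id: str,
    condition: str,
    region_index: int,
    cells: pd.DataFrame,
    config: SimulationConfig,
    abundance: np.ndarray,
    nuclear_fraction: np.ndarray,
    region_mod: np.ndarray,
    expr_mult: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    w, h, d = config.fov_size
    panel = config.panel()
    weights = abundance * region_mod[region_index]
    # molecule yield tracks cellular content: FOVs with more cells carry
    # proportionally more molecules, keeping per-cell depth homogeneous
    density = len(cells) / config.cells_per_fov
    lam = config.mean_molecules_per_fov * density * weights / weights.sum() * expr_mult
    counts = rng.poisson(lam)
    gene_idx = np.repeat(np.arange(config.n_genes), counts)
    n = len(gene_idx)
    order = rng.permutation(n)  # interleave genes so row order carries no signal
    gene_idx = gene_idx[order]

    unassigned = rng.random(n) < config.unassigned_fraction
    cell_row = rng.integers(0, len(cells), size=n)
    nuclear = rng.random(n) < nuclear_fraction[gene_idx]

    xyz = np.empty((n, 3))
    n_un = int(unassigned.sum())
    xyz[unassigned] = rng.uniform([0, 0, 0], [w, h, d], size=(n_un, 3))
    a = ~unassigned
    centroids = cells[["cx", "cy", "cz"]].to_numpy()[cell_row[a]]
    radii = cells["radius"].to_numpy()[cell_row[a]]
    xyz[a] = _positions_in_cells(centroids, radii, nuclear[a], rng)

    cell_ids = np.where(unassigned, UNASSIGNED, cells["cell_id"].to_numpy()[cell_row])
    compartment = np.where(unassigned, UNASSIGNED, np.where(nuclear, "nuclear", "cytoplasmic"))
    return pd.DataFrame(
        {
            "spot_id": [f"{fov_id}:{i}" for i in range(n)],
            "gene": np.array(panel, dtype=object)[gene_idx],
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "fov_id": fov_id,
            "sample_id": sample_id,
            "cell_id": cell_ids,
            "compartment": compartment,
        }
    )


# ---------------------------------------------------------------------------
# planted effects


def _affected_fovs(
    cells: pd.DataFrame, effect: PlantedEffect
) -> pd.Index:
    mask = cells["condition"] == effect.condition
    if effect.regions is not None:
        mask &= cells["region"].isin(effect.regions)
    return pd.Index(cells.loc[mask, "fov_id"].unique())


def plant_spatial_shift(
    spots: pd.DataFrame,
    gene: str,
    concentration: float,
    rng: np.random.Generator,
    fov_size: tuple[float, float, float],
    fovs: Sequence[str] | None = None,
    n_attractors: int = 3,
    cluster_sd: float = 5.0,
) -> pd.DataFrame:
    """Resample the gene's positions toward a few attractor centers per FOV.

    Each spot is drawn near a random attractor with probability
    c / (c + 1) (c = ``concentration``) and kept uniform otherwise, so the
    c → 0 limit is exactly the uniform baseline while large c yields tight
    clusters. The number of spots per FOV is conserved by construction and
    all non-coordinate columns are untouched.
    """
    if gene not in set(spots["gene"]):
        raise KeyError(f"gene {gene!r} not present in spot table")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    spots = spots.copy()
    w, h, d = fov_size
    bounds = np.array([w, h, d])
    target_fovs = spots["fov_id"].unique() if fovs is None else fovs
    p_cluster = concentration / (concentration + 1.0)
    for fov in target_fovs:
        idx = spots.index[(spots["fov_id"] == fov) & (spots["gene"] == gene)]
        n = len(idx)
        if n == 0:
            continue
        centers = rng.uniform([0, 0, 0], bounds, size=(n_attractors, 3))
        clustered = rng.random(n) < p_cluster
        which = rng.integers(0, n_attractors, size=n)
        pos = rng.uniform([0, 0, 0], bounds, size=(n, 3))
        jitter = rng.normal(scale=cluster_sd, size=(n, 3))
        pos[clustered] = centers[which[clustered]] + jitter[clustered]
        pos = np.clip(pos, 0.0, np.nextafter(bounds, 0.0))
        spots.loc[idx, ["x", "y", "z"]] = pos
    return spots


def _relabel_compartments(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    idx: pd.Index,
    odds_multiplier: np.ndarray,
    rng: np.random.Generator,
    nuclear_fraction: pd.Series | None = None,
) -> pd.DataFrame:
    """Redraw compartment labels for ``idx`` with per-spot odds multipliers,
    repositioning each spot inside its cell consistently. Per-cell totals
    are conserved (labels change, membership does not).

    ``nuclear_fraction`` is the per-gene baseline nuclear fraction; the
    generator passes its true values so a multiplier of 1 is a statistical
    identity. Without it the fraction is estimated from the affected subset,
    whose shared estimation error then acts as a small coherent shift across
    all relabeled cells — acceptable for standalone use on large subsets.
    """
    spots = spots.copy()
    sub = spots.loc[idx]
    if nuclear_fraction is None:
        frac = sub.groupby("gene")["compartment"].apply(lambda s: (s == "nuclear").mean())
        f0 = sub["gene"].map(frac).to_numpy()
    else:
        f0 = sub["gene"].map(nuclear_fraction).to_numpy()
    f0 = np.clip(f0, 0.02, 0.98)  # keep odds finite for degenerate genes
    odds = f0 / (1.0 - f0) * odds_multiplier
    f1 = odds / (1.0 + odds)
    nuclear = rng.random(len(sub)) < f1
    geo = cells.set_index("cell_id")
    centroids = geo.loc[sub["cell_id"], ["cx", "cy", "cz"]].to_numpy()
    radii = geo.loc[sub["cell_id"], "radius"].to_numpy()
    spots.loc[idx, ["x", "y", "z"]] = _positions_in_cells(centroids, radii, nuclear, rng)
    spots.loc[idx, "compartment"] = np.where(nuclear, "nuclear", "cytoplasmic")
    return spots


def plant_velocity_shift(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    gene: str,
    cell_type: str,
    ratio_multiplier: float,
    rng: np.random.Generator,
    fovs: Sequence[str] | None = None,
    nuclear_fraction: pd.Series | None = None,
) -> pd.DataFrame:
    """Multiply the expected nuclear:cytoplasmic odds of one gene within one
    cell type; total per-cell counts of the gene are unchanged."""
    if gene != "all" and gene not in set(spots["gene"]):
        raise KeyError(f"gene {gene!r} not present in spot table")
    if cell_type != "all" and cell_type not in set(cells["cell_type"]):
        raise KeyError(f"cell type {cell_type!r} not present in cell table")
    target_cells = cells if cell_type == "all" else cells[cells["cell_type"] == cell_type]
    if fovs is not None:
        target_cells = target_cells[target_cells["fov_id"].isin(fovs)]
    mask = spots["cell_id"].isin(set(target_cells["cell_id"]))
    if gene != "all":
        mask &= spots["gene"] == gene
    idx = spots.index[mask]
    if len(idx) == 0:
        return spots.copy()
    mult = np.full(len(idx), float(ratio_multiplier))
    return _relabel_compartments(spots, cells, idx, mult, rng,
                                 nuclear_fraction=nuclear_fraction)


def plant_module_shift(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    genes: Sequence[str],
    cell_type: str,
    slope: float,
    rng: np.random.Generator,
    fovs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Redistribute the module genes' molecules across cells of one type
    along a shared lateral gradient (weight ∝ exp(slope · (cx/W − ½))),
    creating a co-occurring spatially-variable gene set. Per-FOV totals of
    each gene are conserved."""
    missing = set(genes) - set(spots["gene"])
    if missing:
        raise KeyError(f"gene(s) not present in spot table: {sorted(missing)}")
    spots = spots.copy()
    target_fovs = spots["fov_id"].unique() if fovs is None else fovs
    for fov in target_fovs:
        fov_cells = cells[(cells["fov_id"] == fov)]
        if cell_type != "all":
            fov_cells = fov_cells[fov_cells["cell_type"] == cell_type]
        if len(fov_cells) < 2:
            continue
        width = float(fov_cells["cx"].max() - fov_cells["cx"].min()) or 1.0
        weights = np.exp(slope * (fov_cells["cx"].to_numpy() - fov_cells["cx"].min()) / width)
        weights /= weights.sum()
        idx = spots.index[
            (spots["fov_id"] == fov)
            & spots["gene"].isin(genes)
            & spots["cell_id"].isin(set(fov_cells["cell_id"]))
        ]
        if len(idx) == 0:
            continue
        pick = rng.choice(len(fov_cells), size=len(idx), p=weights)
        centroids = fov_cells[["cx", "cy", "cz"]].to_numpy()[pick]
        radii = fov_cells["radius"].to_numpy()[pick]
        nuclear = spots.loc[idx, "compartment"].to_numpy() == "nuclear"
        spots.loc[idx, "cell_id"] = fov_cells["cell_id"].to_numpy()[pick]
        spots.loc[idx, ["x", "y", "z"]] = _positions_in_cells(centroids, radii, nuclear, rng)
    return spots


def plant_proximity_velocity(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    source_type: str,
    target_type: str,
    boost: float,
    decay_scale: float,
    rng: np.random.Generator,
    fovs: Sequence[str] | None = None,
    nuclear_fraction: pd.Series | None = None,
) -> pd.DataFrame:
    """Boost the nuclear:cytoplasmic odds of all genes in source-type cells
    by 1 + (boost − 1)·exp(−d/decay_scale), d = boundary distance to the
    nearest target-type cell in the same FOV."""
    from .proximity import boundary_distances  # local import avoids a cycle

    dist = boundary_distances(cells, source_type, target_type, fovs=fovs)
    dist = dist.dropna(subset=["min_boundary_distance"])
    if dist.empty:
        return spots.copy()
    mult_by_cell = 1.0 + (boost - 1.0) * np.exp(
        -dist["min_boundary_distance"].to_numpy() / decay_scale
    )
    cell_mult = dict(zip(dist["cell_id"], mult_by_cell))
    idx = spots.index[spots["cell_id"].isin(cell_mult)]
    if len(idx) == 0:
        return spots.copy()
    mult = spots.loc[idx, "cell_id"].map(cell_mult).to_numpy(dtype=float)
    return _relabel_compartments(spots, cells, idx, mult, rng,
                                 nuclear_fraction=nuclear_fraction)


# ---------------------------------------------------------------------------
# top-level generation


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Generate spots, cells, sample sheet, FOV offsets and ground truth.

    Deterministic given ``config.seed``: per-FOV random streams are derived
    by stable hashing of (seed, sample, region, fov), so changing the number
    of FOVs never perturbs the others.
    """
    config.validate()
    sheet = _sample_sheet(config)
    abundance, nuclear_fraction, region_mod = _panel_parameters(config)
    panel = config.panel()
    gene_pos = {g: i for i, g in enumerate(panel)}

    expr_effects = [e for e in config.planted_effects if e.kind == "expression_shift"]

    w, h, _ = config.fov_size
    pitch_x, pitch_y = w + 20.0, h + 20.0
    spot_frames, cell_frames, offset_rows = [], [], []
    row = 0
    for _, srow in sheet.iterrows():
        sample_id, condition = srow["sample_id"], srow["condition"]
        for ri, region in enumerate(config.regions):
            for k in range(config.fovs_per_region_per_sample):
                fov_id = f"{sample_id}:{region}:{k}"
                rng = np.random.default_rng(child_seed(config.seed, "fov", sample_id, region, k))
                cells = _generate_fov_cells(fov_id, sample_id, region, condition, config, rng)
                expr_mult = np.ones(config.n_genes)
                for eff in expr_effects:
                    if eff.condition == condition and (
                        eff.regions is None or region in eff.regions
                    ):
                        for g in eff.genes():
                            expr_mult[gene_pos[g]] *= eff.magnitude
                spots = _generate_fov_spots(
                    fov_id, sample_id, condition, ri, cells, config,
                    abundance, nuclear_fraction, region_mod, expr_mult, rng,
                )
                spot_frames.append(spots)
                cell_frames.append(cells)
                offset_rows.append(
                    {"fov_id": fov_id, "x_offset": k * pitch_x, "y_offset": row * pitch_y,
                     "z_offset": 0.0}
                )
            row += 1

    spots = pd.concat(spot_frames, ignore_index=True)
    cells = pd.concat(cell_frames, ignore_index=True)
    offsets = pd.DataFrame(offset_rows)
    nf_series = pd.Series(nuclear_fraction, index=panel)

    for ei, eff in enumerate(config.planted_effects):
        if eff.kind == "expression_shift":
            continue  # applied during sampling
        rng = np.random.default_rng(child_seed(config.seed, "effect", ei, eff.kind))
        fovs = _affected_fovs(cells, eff)
        if eff.kind == "spatial_shift":
            spots = plant_spatial_shift(
                spots, eff.gene, eff.magnitude, rng, config.fov_size, fovs=fovs
            )
        elif eff.kind == "velocity_shift":
            spots = plant_velocity_shift(
                spots, cells, eff.gene, eff.cell_type, eff.magnitude, rng, fovs=fovs,
                nuclear_fraction=nf_series,
            )
        elif eff.kind == "module_shift":
            spots = plant_module_shift(
                spots, cells, eff.genes(), eff.cell_type, eff.magnitude, rng, fovs=fovs
            )
        elif eff.kind == "proximity_velocity":
            spots = plant_proximity_velocity(
                spots, cells, eff.cell_type, eff.target_type, eff.magnitude,
                eff.decay_scale, rng, fovs=fovs, nuclear_fraction=nf_series,
            )

    truth = GroundTruth(effects=[_effect_record(e) for e in config.planted_effects])
    return Dataset(spots, cells, sheet, offsets, panel, truth, config)


def _effect_record(eff: PlantedEffect) -> dict:
    rec = dataclasses.asdict(eff)
    rec["gene"] = list(eff.genes()) if not isinstance(eff.gene, str) else eff.gene
    rec["regions"] = list(eff.regions) if eff.regions is not None else None
    return rec


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = dataio.dataset_paths(out)
    dataio.write_spots(dataset.spots, paths["spots"])
    dataio.write_cells(dataset.cells, paths["cells"])
    dataio.write_samples(dataset.samples, paths["samples"])
    dataio.write_fov_offsets(dataset.fov_offsets, paths["fov_offsets"])
    dataio.write_panel(dataset.panel, paths["panel"])
    paths["ground_truth"].write_text(dataset.truth.to_json() + "\n")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    return paths


def read_dataset(directory: str | Path) -> Dataset:
    paths = dataio.dataset_paths(directory)
    panel = dataio.read_panel(paths["panel"])
    with open(paths["config"]) as fh:
        config = SimulationConfig.from_dict(yaml.safe_load(fh))
    return Dataset(
        spots=dataio.read_spots(paths["spots"], panel=panel),
        cells=dataio.read_cells(paths["cells"]),
        samples=dataio.read_samples(paths["samples"]),
        fov_offsets=dataio.read_fov_offsets(paths["fov_offsets"]),
        panel=panel,
        truth=GroundTruth.from_json(paths["ground_truth"].read_text()),
        config=config,
    )
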