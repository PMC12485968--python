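"""Pipeline orchestration: simulate → validate → qc → spatial screen per
region → neighborhood → velocity → proximity, from one YAML config, with
structured JSON-lines logging, derived per-stage seeds and a run manifest.

Stage seeds are derived from the master seed by stable hashing of stage
names, so adding a stage never shifts the other stages' random streams.
Degenerate-data skips inside stages are recorded, not raised; a stage error
halts the pipeline with the stage named.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import dataio, neighborhood, proximity, qc, spatial, synthetic, velocity
from ._utils import child_seed, file_sha256

__version__ = "0.1.0"

STAGES = ("simulate", "validate", "qc", "spatialdiff", "neighborhood", "velocity", "proximity")


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> None:
    """Validate every stage's parameters before any stage runs."""
    if "seed" not in config:
        raise PipelineConfigError("seed: required")
    if "simulate" not in config and "input_dir" not in config:
        raise PipelineConfigError("either a 'simulate' block or an 'input_dir' is required")
    if "simulate" in config:
        sim = dict(config["simulate"])
        sim.setdefault("seed", child_seed(config["seed"], "simulate"))
        synthetic.SimulationConfig.from_dict(sim).validate()
    for stage in ("spatialdiff", "neighborhood", "velocity", "proximity"):
        block = config.get(stage, {})
        alpha = block.get("alpha", 0.05)
        if not 0 < alpha < 1:
            raise PipelineConfigError(f"{stage}.alpha: must lie in (0, 1), got {alpha}")
        n_perm = block.get("n_perm", 499)
        if n_perm < 99:
            raise PipelineConfigError(f"{stage}.n_perm: must be >= 99, got {n_perm}")
    k = config.get("qc", {}).get("k", 2)
    if k < 2:
        raise PipelineConfigError(f"qc.k: must be >= 2, got {k}")
    thr = config.get("proximity", {}).get("threshold", proximity.DEFAULT_THRESHOLD)
    if thr <= 0:
        raise PipelineConfigError(f"proximity.threshold: must be > 0, got {thr}")


def _stage_outputs_exist(paths: list[Path]) -> bool:
    return bool(paths) and all(p.exists() for p in paths)


def run_pipeline(config: dict, out_dir: str | Path, resume: bool = False) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    With ``resume=True`` a stage whose declared outputs already exist is
    skipped and its files reused, so deleting one stage's outputs and
    re-running regenerates only that stage (and any dependents whose outputs
    were also removed).
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    log_path = out / "pipeline.log.jsonl"
    manifest: dict = {
        "version": __version__,
        "config_hash": None,
        "seed": seed,
        "stages": {},
    }
    config_text = yaml.safe_dump(config, sort_keys=True)
    (out / "run_config.yaml").write_text(config_text)
    manifest["config_hash"] = file_sha256(out / "run_config.yaml")

    log_entries = []

    def log(stage: str, **fields):
        entry = {"stage": stage, **fields}
        log_entries.append(entry)

    def finish_stage(stage: str, t0: float, outputs: list[Path], counters: dict, skipped=False):
        manifest["stages"][stage] = {
            "seed": child_seed(seed, stage),
            "wall_clock_s": round(time.monotonic() - t0, 3),
            "outputs": {p.name: file_sha256(p) for p in outputs},
            "counters": counters,
            "reused": skipped,
        }
        log(stage, event="done", counters=counters, reused=skipped)

    state: dict = {}

    def run_stage(stage: str, declared: list[Path], fn):
        t0 = time.monotonic()
        log(stage, event="start")
        if resume and _stage_outputs_exist(declared):
            counters = fn(reuse=True)
            finish_stage(stage, t0, declared, counters, skipped=True)
            return
        try:
            counters = fn(reuse=False)
        except Exception as exc:  # halt with the stage named
            log(stage, event="error", message=str(exc))
            (out / "pipeline.log.jsonl").write_text(
                "\n".join(json.dumps(e, default=str) for e in log_entries) + "\n"
            )
            raise StageError(stage, exc) from exc
        finish_stage(stage, t0, declared, counters)

    # ------------------------------------------------------------- simulate
    data_dir = out / "dataset"
    if "simulate" in config:
        sim_cfg_dict = dict(config["simulate"])
        sim_cfg_dict.setdefault("seed", child_seed(seed, "simulate"))
        sim_cfg = synthetic.SimulationConfig.from_dict(sim_cfg_dict)
        declared = list(dataio.dataset_paths(data_dir).values())

        def _simulate(reuse: bool):
            if reuse:
                state["dataset"] = synthetic.read_dataset(data_dir)
            else:
                state["dataset"] = synthetic.generate_dataset(sim_cfg)
                synthetic.write_dataset(state["dataset"], data_dir)
            ds = state["dataset"]
            return {"n_spots": len(ds.spots), "n_cells": len(ds.cells),
                    "n_fovs": ds.spots["fov_id"].nunique()}

        run_stage("simulate", declared, _simulate)
        ds = state["dataset"]
    else:
        ds = synthetic.read_dataset(config["input_dir"])
        state["dataset"] = ds

    spots, cells, sheet, panel = ds.spots, ds.cells, ds.samples, ds.panel

    # ------------------------------------------------------------- validate
    val_dir = out / "validation"
    val_dir.mkdir(exist_ok=True)

    def _validate(reuse: bool):
        report = dataio.validate_dataset(spots, cells, sheet, panel=panel,
                                         fov_size=ds.config.fov_size)
        (val_dir / "report.txt").write_text(report.summary() + "\n")
        if not report.ok:
            raise ValueError(f"dataset failed validation with {len(report)} issue(s)")
        return {"issues": len(report)}

    run_stage("validate", [val_dir / "report.txt"], _validate)

    # ------------------------------------------------------------------- qc
    qc_dir = out / "qc"
    qc_dir.mkdir(exist_ok=True)
    qc_block = config.get("qc", {})

    def _qc(reuse: bool):
        mat = qc.fov_expression_matrix(spots, panel=panel)
        corr = qc.fov_spearman_matrix(mat)
        corr.to_csv(qc_dir / "fov_correlation.tsv", sep="\t")
        k = min(qc_block.get("k", max(2, len(ds.config.regions))), mat.shape[1])
        labels, coords = qc.fov_pca_kmeans(mat, k=k, seed=child_seed(seed, "qc"))
        clusters = coords.copy()
        clusters.insert(0, "cluster", labels)
        clusters.to_csv(qc_dir / "fov_clusters.tsv", sep="\t", index_label="fov_id")
        return {"n_fovs": mat.shape[1], "k": int(k)}

    run_stage("qc", [qc_dir / "fov_correlation.tsv", qc_dir / "fov_clusters.tsv"], _qc)

    # ----------------------------------------------------------- spatialdiff
    sp_dir = out / "spatialdiff"
    sp_dir.mkdir(exist_ok=True)
    sp_block = config.get("spatialdiff", {})

    def _spatialdiff(reuse: bool):
        frames = []
        for region in ds.config.regions:
            frames.append(
                spatial.region_screen(
                    spots, cells, region, panel=panel,
                    alpha=sp_block.get("alpha", 0.05),
                    n_perm=sp_block.get("n_perm", 499),
                    seed=child_seed(seed, "spatialdiff"),
                    voxel_size=sp_block.get("voxel_size", spatial.DEFAULT_VOXEL_SIZE),
                    fov_size=ds.config.fov_size,
                    min_spots=sp_block.get("min_spots", spatial.DEFAULT_MIN_SPOTS),
                    permute_by=sp_block.get("permute_by", "fov"),
                )
            )
        results = pd.concat(frames, ignore_index=True)
        results.to_csv(sp_dir / "diff_results.tsv", sep="\t", index=False)
        venn = {region: spatial.venn_summary(results[results["region"] == region])
                for region in ds.config.regions}
        (sp_dir / "venn_summary.json").write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
        state["diff_results"] = results
        return {"n_tests": len(results),
                "n_skipped": int(results["skipped"].sum())}

    run_stage("spatialdiff", [sp_dir / "diff_results.tsv", sp_dir / "venn_summary.json"],
              _spatialdiff)

    # ---------------------------------------------------------- neighborhood
    nb_dir = out / "neighborhood"
    nb_dir.mkdir(exist_ok=True)
    nb_block = config.get("neighborhood", {})

    def _neighborhood(reuse: bool):
        res = neighborhood.neighborhood_analysis(
            spots, cells, panel, fov_offsets=ds.fov_offsets,
            alpha=nb_block.get("alpha", 0.05),
            n_perm=nb_block.get("n_perm", 499),
            seed=child_seed(seed, "neighborhood"),
            jaccard_min=nb_block.get("jaccard_min", neighborhood.DEFAULT_JACCARD_MIN),
            min_cells=nb_block.get("min_cells", neighborhood.DEFAULT_MIN_CELLS),
        )
        res["svg_records"].to_csv(nb_dir / "svg_records.tsv", sep="\t", index=False)
        cluster_rows = [
            {"cell_type": ct, "sample_id": s, "cluster_index": i,
             "members": ",".join(sorted(m))}
            for (ct, s), cls in sorted(res["clusters"].items())
            for i, m in enumerate(cls)
        ]
        pd.DataFrame(cluster_rows, columns=["cell_type", "sample_id", "cluster_index", "members"]
                     ).to_csv(nb_dir / "clusters.tsv", sep="\t", index=False)

        def cluster_json(groups):
            return {
                cond: [
                    {"cell_type": c.cell_type, "consensus": sorted(c.consensus),
                     "jaccard_by_sample": c.jaccard_by_sample}
                    for c in sorted(lst, key=lambda c: (c.cell_type, sorted(c.consensus)))
                ]
                for cond, lst in groups.items()
            }

        (nb_dir / "recurrent_clusters.json").write_text(
            json.dumps(cluster_json(res["recurrent"]), indent=2, sort_keys=True) + "\n")
        (nb_dir / "condition_specific.json").write_text(
            json.dumps(cluster_json(res["condition_specific"]), indent=2, sort_keys=True) + "\n")
        return {"n_svg_records": len(res["svg_records"]),
                "n_strata_skipped": len(res["skips"]),
                "n_condition_specific": sum(len(v) for v in res["condition_specific"].values())}

    run_stage(
        "neighborhood",
        [nb_dir / "svg_records.tsv", nb_dir / "clusters.tsv",
         nb_dir / "recurrent_clusters.json", nb_dir / "condition_specific.json"],
        _neighborhood,
    )

    # -------------------------------------------------------------- velocity
    vel_dir = out / "velocity"
    vel_dir.mkdir(exist_ok=True)
    vel_block = config.get("velocity", {})

    def _velocity(reuse: bool):
        counts, gamma, v, future = velocity.velocity_analysis(
            spots, cells, panel, dt=vel_block.get("dt", 1.0),
            min_cells_gamma=vel_block.get("min_cells_gamma", velocity.DEFAULT_MIN_CELLS_GAMMA),
        )
        gamma.to_frame().to_csv(vel_dir / "gamma_fits.tsv", sep="\t", index_label="gene")
        strata, disp, gene_tables = velocity.stratify(
            counts, gamma, v, future,
            n_perm=vel_block.get("n_perm", 499),
            seed=child_seed(seed, "velocity"),
            min_cells=vel_block.get("min_cells", velocity.DEFAULT_MIN_CELLS_STRATUM),
        )
        strata.to_csv(vel_dir / "stratum_tests.tsv", sep="\t", index=False)
        disp.to_csv(vel_dir / "displacements.tsv", sep="\t", index_label="cell_id")
        gt_frames = []
        for (ct, region), table in sorted(gene_tables.items()):
            table = table.copy()
            table.insert(0, "cell_type", ct)
            table.insert(1, "region", region)
            gt_frames.append(table)
        gt = (pd.concat(gt_frames, ignore_index=True) if gt_frames
              else pd.DataFrame(columns=["cell_type", "region", "gene", "statistic", "p",
                                         "skipped", "q"]))
        gt.to_csv(vel_dir / "gene_velocity_tests.tsv", sep="\t", index=False)
        state["velocity"] = (counts, gamma, v, future)
        return {"n_gamma_fit": int(gamma.notna().sum()),
                "n_strata": len(strata),
                "n_strata_skipped": int(strata["skipped"].sum())}

    run_stage(
        "velocity",
        [vel_dir / "gamma_fits.tsv", vel_dir / "stratum_tests.tsv",
         vel_dir / "displacements.tsv", vel_dir / "gene_velocity_tests.tsv"],
        _velocity,
    )

    # ------------------------------------------------------------- proximity
    px_dir = out / "proximity"
    px_dir.mkdir(exist_ok=True)
    px_block = config.get("proximity", {})
    source_type = px_block.get("source_type", "inhibitory")
    target_type = px_block.get("target_type", "excitatory")

    def _proximity(reuse: bool):
        if "velocity" in state:
            counts, gamma, v, future = state["velocity"]
        else:
            counts, gamma, v, future = velocity.velocity_analysis(
                spots, cells, panel, dt=vel_block.get("dt", 1.0))
        records = proximity.proximity_records(
            cells, source_type, target_type,
            threshold=px_block.get("threshold", proximity.DEFAULT_THRESHOLD),
        )
        records.to_csv(px_dir / "proximity.tsv", sep="\t", index=False)
        sel = (counts.meta["cell_type"] == source_type).to_numpy()
        counters = {"n_source_cells": int(sel.sum()),
                    "n_without_target": int(records["min_boundary_distance"].isna().sum())}
        genes = gamma.dropna().index
        if sel.sum() >= 2:
            disp = velocity.pca_displacement(counts.s[genes][sel], future[genes][sel],
                                             counts.meta[sel])
            strata = proximity.proximity_stratified_tests(
                disp, records,
                n_perm=px_block.get("n_perm", 499),
                seed=child_seed(seed, "proximity"),
                min_cells=px_block.get("min_cells", proximity.DEFAULT_MIN_CELLS),
            )
            corr_frames = []
            for cond in sorted(counts.meta.loc[sel, "condition"].dropna().unique()):
                csel = sel & (counts.meta["condition"] == cond).to_numpy()
                table = proximity.gene_velocity_distance_correlation(
                    v[csel], records,
                    n_perm=px_block.get("n_perm", 499),
                    seed=child_seed(seed, "proximity", cond),
                )
                table.insert(0, "condition", cond)
                corr_frames.append(table)
            corr = (pd.concat(corr_frames, ignore_index=True) if corr_frames
                    else pd.DataFrame(columns=["condition", "gene", "r", "p", "skipped", "q"]))
        else:
            strata = pd.DataFrame(
                columns=["stratum", "condition_a", "condition_b", "n_a", "n_b",
                         "magnitude_p", "magnitude_delta", "direction",
                         "phase_delta", "phase_p", "skipped"])
            corr = pd.DataFrame(columns=["condition", "gene", "r", "p", "skipped", "q"])
        strata.to_csv(px_dir / "stratum_tests.tsv", sep="\t", index=False)
        corr.to_csv(px_dir / "gene_distance_correlations.tsv", sep="\t", index=False)
        return counters

    run_stage(
        "proximity",
        [px_dir / "proximity.tsv", px_dir / "stratum_tests.tsv",
         px_dir / "gene_distance_correlations.tsv"],
        _proximity,
    )

    (out / "pipeline.log.jsonl").write_text(
        "\n".join(json.dumps(e, default=str) for e in log_entries) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def result_hashes(manifest: dict) -> dict[str, str]:
    """Stage-output hashes (excludes wall-clock), for determinism checks."""
    return {
        f"{stage}/{name}": digest
        for stage, info in manifest["stages"].items()
        for name, digest in info["outputs"].items()
    }
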