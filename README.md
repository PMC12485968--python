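# exspat

Spatial-differential analysis of super-resolved in situ sequencing point
clouds — for studies that ask not only *which genes change expression*
between two conditions, but *which genes move*: transcripts whose spatial
organization inside a tissue changes while their abundance does not, and
cells whose predicted transcriptional trajectory shifts depending on region
and on which neighbors they touch.

The package targets ExSeq-style data of mouse hippocampus — per-molecule 3D
positions of a ~100-gene panel in 100 × 100 μm fields of view (FOVs), with
segmented cells, region labels (CA1, CA3, DG, SLM, DG-CA1, SO, Hilus) and
two conditions (5xFAD vs WT) — and provides three analysis strategies plus
a fully seeded synthetic generator that plants each effect class so every
stage is verifiable without raw study data:

1. **Grid Moran's I differential screen** (`exspat.spatial`) — molecules are
   voxelized per gene and FOV onto a 10 μm lattice; spatial autocorrelation
   is measured as

       I = (N/W) · Σᵢⱼ wᵢⱼ (xᵢ−x̄)(xⱼ−x̄) / Σᵢ (xᵢ−x̄)²

   with binary 6-neighbor weights; conditions are compared per region by
   permutation tests on per-FOV values (expression and Moran's I as
   separate BH families), and each gene is categorized expression-only /
   **spatial-only** / both / neither. KDE axis profiles with two-sample KS
   tests visualize and test 1D reorganization.
2. **Single-cell neighborhood analysis** (`exspat.neighborhood`) — per cell
   type and sample, spatially variable genes are detected by kNN-graph
   Moran's I with a permutation null; detected genes are clustered by
   shared per-cell expression (1 − Spearman, average linkage), clusters are
   intersected across samples by greedy Jaccard matching, and clusters
   recurrent in one condition but absent in the other are reported.
3. **Spatial RNA velocity with proximity stratification** (`exspat.velocity`,
   `exspat.proximity`) — nuclear counts proxy unspliced, cytoplasmic counts
   spliced; γ is fit per gene by regression through the origin, v = u − γs
   is extrapolated to a future state and projected into a shared 2D PCA
   basis; magnitudes (Mann–Whitney U) and phases (circular-mean permutation
   test) of per-cell displacements are compared by cell type, region, and
   by ≤1 μm boundary proximity to a target cell type, with per-gene
   velocity MWU+BH and velocity–distance Pearson permutation tests.

See `docs/methods.md` for the full model description, assumptions and
defaults.

## Worked example

Generate a dataset with one planted expression fold change (G001, 2×) and
one planted spatial reorganization (G002, concentration 20 — same per-FOV
counts, clustered positions), then screen the DG-CA1 region:

```python
from exspat import spatial, synthetic
from exspat.synthetic import PlantedEffect, SimulationConfig

cfg = SimulationConfig(
    seed=43, n_genes=12, n_samples_per_condition=2,
    fovs_per_region_per_sample=10, mean_molecules_per_fov=1500.0,
    regions=("DG-CA1",),
    planted_effects=(
        PlantedEffect(kind="expression_shift", gene="G001",
                      condition="5xFAD", magnitude=2.0),
        PlantedEffect(kind="spatial_shift", gene="G002",
                      condition="5xFAD", magnitude=20.0),
    ),
)
ds = synthetic.generate_dataset(cfg)
res = spatial.region_screen(ds.spots, ds.cells, "DG-CA1",
                            panel=ds.panel, n_perm=999, seed=0)
print(res[["gene", "de_q", "moran_q", "category"]].head(3).to_string(index=False))
print(spatial.venn_summary(res))
```

prints

```
gene   de_q  moran_q        category
G001 0.0120    0.492 expression_only
G002 0.8100    0.012    spatial_only
G003 0.2220    0.588         neither
{'expression_only': 2, 'spatial_only': 1, 'both': 0, 'neither': 9}
```

G001 is significant in the expression family only (BH q = 0.012) and G002
in the Moran family only (q = 0.012) with unchanged expression
(q = 0.81) — the planted spatial-only signature, recovered. (One null gene
lands in the expression family at q = 0.042 in this draw; at q < 0.05 a
small number of false positives is expected.)

The same analyses are available from the shell:

```
exspat simulate    --config sim.yaml --out data/ --seed 7
exspat qc          --spots data/spots.tsv --cells data/cells.tsv --k 3 --seed 0 --out out/qc
exspat spatialdiff --spots data/spots.tsv --cells data/cells.tsv --region DG-CA1 \
                   --n-perm 10000 --seed 0 --out out/spatial
exspat neighborhood ... ; exspat velocity ... ; exspat proximity ...
exspat pipeline run --config run.yaml --out out/run
```

`pipeline run` executes every stage from one YAML config with derived
per-stage seeds, JSON-lines logging and a manifest of output hashes;
re-running with the same config and seed reproduces byte-identical outputs.

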