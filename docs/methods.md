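# Methods

`exspat` implements a spatial-differential analysis workflow for
super-resolved in situ sequencing (ExSeq-style) point clouds of mouse
hippocampus: per-molecule 3D positions of a ~100-gene panel, read out in
100 × 100 μm (× 30 μm axial) fields of view (FOVs), with segmented cells,
hippocampal region labels and two conditions (5xFAD vs WT). This note
documents the models, the statistical procedures and their assumptions, the
synthetic-data generator used to verify every stage, and the numerical and
design choices that were genuinely open.

## 1. Data model

A dataset is three TSV tables plus sidecars (see `exspat.dataio`): a spot
table (one row per sequenced molecule: gene, FOV-local x/y/z in biological
μm, FOV, sample, cell assignment, nuclear/cytoplasmic compartment), a cell
table (centroid, sphere-radius boundary proxy, cell type, region,
condition) and a sample sheet (mouse, biological/technical replicate role).
The unassigned sentinel is the literal string `NA`; the gene panel is a
closed vocabulary (`panel.txt`); `fov_offsets.tsv` places FOVs in sample
space when a cross-FOV geometry is needed (the neighborhood kNN graph).
Coordinates are biological micrometres — any expansion factor is assumed
divided out upstream, since the raw reports give FOVs as 100 × 100 μm
without stating pre- or post-expansion units.

## 2. Differential spatial autocorrelation (module `spatial`)

Each gene's molecules in each FOV are binned onto a fixed half-open
10 × 10 × 10 μm lattice covering the FOV bounding box (empty voxels
retained). Global Moran's I is computed over all lattice voxels with binary
face-adjacent (6-neighbor) weights:

    I = (N / W) · Σ_ij w_ij (x_i − x̄)(x_j − x̄) / Σ_i (x_i − x̄)²

with N the voxel count and W the directed weight sum. A fixed lattice keeps
the weight graph identical across FOVs, so I is comparable between them;
grids with fewer than `min_spots` molecules (default 10) or zero variance
are flagged invalid (NaN) and dropped pairwise per gene. I ≈ +1 indicates
spatial clustering, 0 randomness, negative values dispersion.

Conditions are compared per region with FOVs as the replicate unit: the
statistic is the difference of group means of per-FOV values (depth-
normalized expression, or Moran's I), and the null is random relabeling of
FOV group labels with the add-one convention
p = (1 + #{|T_perm| ≥ |T_obs|}) / (n_perm + 1). FOVs from the same mouse
are technical replicates, so this design carries pseudoreplication; a
`permute_by="sample"` variant relabels whole samples for a conservative
check. P values are Benjamini–Hochberg adjusted per region, separately for
the expression and the spatial family, and each gene is categorized as
expression-only / spatial-only / both / neither at q < α — the spatial-only
class being the signature of reorganized-but-not-differentially-expressed
transcripts.

**Depth normalization.** Per-FOV expression uses median-of-ratios (DESeq-
style) size factors rather than total-count scaling. Sequencing depth
varies severalfold between samples and must be removed, but scaling by the
FOV total makes every gene's normalized value depend on every other gene's
abundance: a single strong composition change in one condition then drags
the whole panel into apparent differential expression. Median-of-ratios is
robust as long as most genes are unchanged, which is the regime this screen
assumes.

Axis-density comparisons project a gene's coordinates onto a tissue axis
(default: first principal axis of the pooled cloud, deterministically
oriented; a user axis can be supplied), evaluate a Gaussian KDE (Scott's
rule) per condition for display, and test with a two-sample
Kolmogorov–Smirnov statistic on the raw projections so the test is
bandwidth-free.

## 3. Single-cell neighborhood analysis (module `neighborhood`)

Per cell type and sample, genes whose per-cell expression fraction
(count / cell total; cells with < 5 molecules excluded) is spatially
structured are detected by Moran's I over a binary k-nearest-neighbor graph
(k = 6) of cell centroids, with a permutation null (fractions shuffled
across cells; rows permuted jointly so each gene's marginal null is exact
and gene–gene dependence is preserved) and BH adjustment within the
stratum. This detector is a deliberate surrogate with the same input/output
contract as dedicated spatially-variable-gene tools, whose internal models
are outside this package's scope.

Detected genes are clustered by average-linkage hierarchical clustering at
distance 1 − Spearman correlation of per-cell fractions, tree cut at 0.7,
singletons discarded. Clusters are matched across the samples of each
condition by greedy maximal-Jaccard matching (ties: larger cluster, then
lexicographic); a cluster is *recurrent* when every sample of the condition
matches at Jaccard ≥ 0.5, with the consensus being the intersection of
matched member sets, and *condition-specific* when no recurrent cluster of
the other condition matches it at that threshold.

## 4. Compartment-based spatial RNA velocity (module `velocity`)

Nuclear molecules are the unspliced proxy u, cytoplasmic molecules the
spliced proxy s; the nuclear/cytoplasmic distinction is geometric in the
synthetic data (inner sphere at 60% of cell radius) and taken from the spot
table in general. Per gene, the steady-state ratio is fit by least squares
through the origin over the cells in scope, γ = Σus / Σs² (≥ 30 cells with
s > 0 required), velocity is v = u − γs and the predicted future state is
s* = max(s + vΔt, 0) with Δt = 1 in arbitrary units.

Current and future states are depth-normalized per cell (same factor for
both states), log1p-transformed, and projected into a single 2D PCA basis
fitted on pooled current states of both conditions — so displacement
comparisons always share a basis, and the basis cannot encode condition
labels. Component signs are fixed by the first nonzero loading in panel
order. Each cell's displacement vector yields a magnitude (‖·‖₂) and a
phase (atan2, zero by convention for zero displacement). Magnitudes are
compared between conditions by a two-sided tie-corrected Mann–Whitney U;
phases by a permutation test on the angular distance between group circular
means (statistic in [0, π]; zero-magnitude cells excluded; groups with
vanishing resultant length are skipped); an alternative integrated-squared-
difference statistic on circular KDEs is available
(`velocity.phase_kde_distance`). Per-gene velocities are compared by MWU
with BH across genes within the scope. All three tests run per stratum
(cell type × region, and cell type with regions pooled), each stratum with
its own PCA basis — magnitudes are never compared across strata.

Known properties: (i) the magnitude readout lives in a 2-component basis,
so a shift confined to genes that carry little current-state variance can
be invisible — sensitivity depends on the panel's abundance spectrum;
(ii) cell-level MWU inherits any cell–cell dependence within FOVs
(pseudoreplication), which the synthetic generator keeps small by making
molecule yield track cellular content (below).

## 5. Proximity stratification (module `proximity`)

Boundary distance between cells uses the sphere proxy
max(0, ‖c_i − c_j‖ − r_i − r_j), minimized over target-type cells of the
same FOV only (no stitched geometry); cells whose FOV lacks a target are
excluded and counted. With real segmentation masks a precomputed
surface-to-surface distance column can override the proxy. The proximal
stratum is distance ≤ 1 μm (inclusive, configurable). Magnitude and phase
comparisons are re-run within the proximal and non-proximal strata, with
the direction of effect reported. Per-gene velocity–distance association
uses Pearson correlation with a permutation p (distances permuted across
cells) and BH across genes; zero-variance genes are skipped.

## 6. Synthetic data generator (module `synthetic`)

The generator emulates the study design: two conditions with up to three
mice each plus a technical replicate (4 samples/condition by default),
seven hippocampal regions, 6 FOVs per region per sample, ~8,000 molecules
and ~30 spherical cells per 100 × 100 × 30 μm FOV, a 101-gene panel with
log-normal abundance (σ = 0.5) modulated per region (σ = 0.35, identical
across conditions so regions differ but conditions do not), per-gene
nuclear fractions uniform in [0.2, 0.5], and 10% of molecules left
unassigned to model imperfect segmentation. Molecule totals scale with the
FOV's realized cell count, keeping per-cell depth homogeneous across FOVs —
with independent draws, each FOV's cell-count fluctuation becomes a
coherent per-cell depth shift that cell-level rank tests misread as
condition differences. Randomness is a single mandatory seed with child
streams derived by stable hashing per (sample, region, FOV), so outputs are
byte-identical under a fixed seed and adding a FOV never perturbs others.

Planted effects (each recorded in `ground_truth.json`):

- **expression_shift** — multiplies one gene's Poisson intensity in the
  affected condition/regions; other genes' intensities untouched.
- **spatial_shift** — resamples the gene's positions per FOV toward 3
  attractor centers (Gaussian, σ = 5 μm) with mixture weight c/(c+1), so
  concentration c → 0 is exactly the uniform baseline and large c gives
  tight clusters; per-FOV counts, cell assignments and compartments are
  untouched, making the effect spatial-only by construction.
- **velocity_shift** — redraws compartment labels of one gene within one
  cell type so the nuclear:cytoplasmic odds are multiplied, repositioning
  spots consistently; per-cell totals conserved. Inside the generator the
  redraw uses the true per-gene nuclear fractions, so a multiplier of 1 is
  a statistical identity (an empirically estimated baseline would inject a
  small coherent error across all affected cells).
- **module_shift** — redistributes several genes' molecules across one cell
  type's cells along a shared lateral gradient (weight ∝ exp(slope·x̃)),
  creating a co-occurring spatially-variable gene set; per-FOV totals
  conserved.
- **proximity_velocity** — a cell-level odds boost
  1 + (boost − 1)·exp(−d/decay) with d the boundary distance to the nearest
  target-type cell, applied to all genes of affected cells.

What the generator does **not** model: optics and sequencing error, cell-
type-specific expression signatures (cell typing is validated against
explicit reference profiles instead), non-spherical cell shapes, per-gene
abundance spectra of the real panel, and cross-FOV tissue continuity.
Passing recovery tests therefore demonstrate the statistical machinery
recovers planted effects of the stated sizes under this idealization — not
performance on real segmentation or chemistry artifacts.

## 7. Verification studies (module `evaluation`, `scripts/acceptance.py`)

Every stage is verified against an independent oracle or a planted truth;
`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes
all of them from scratch:

- **Moran oracle**: 200 random grids up to 6×6×3 against a brute-force
  O(N²) double loop (agreement < 1e−12), plus closed forms I = 1/3 for a
  half-and-half 1×4 line and I = −1 for a 2×2 checkerboard.
- **Null calibration**: 10 effect-free datasets × 100 genes give 1,000
  replicates each for the expression and Moran permutation tests and the
  per-gene velocity MWU; 1,000 matched von Mises pairs for the phase test.
  All empirical α at 0.05 should lie in [0.03, 0.07].
- **Spatial-only recovery**: concentration-20 spatial shift, 20 FOVs per
  condition, 30-gene panel at 2,400 molecules/FOV (per-gene depth matching
  the full-scale design), 999 permutations.
- **Velocity recovery**: γ within ±10% on steady-state data (500 cells,
  s ~ Poisson(20)); ratio ×3 shift, ~200 cells/side, on a uniform 5-gene
  panel slice at 8,000 molecules/FOV.
- **Proximity recovery**: boost ×2 at distance 0 with 0.3 μm decay (so the
  planted effect is confined to the ≤1 μm stratum), ~300 cells/side;
  distance oracle exact.
- **Neighborhood recovery**: 3-gene module (gradient slope 2.5) in every
  sample of one condition, 3 samples/condition, 160 cells of the type per
  sample, homogeneous panel (abundance σ = 0.2), 1,999 permutations.
- **Determinism**: a 2-condition × 2-sample × 2-region × 5-FOV pipeline run
  twice with one seed; all stage outputs hash-identical.

Recovery studies use reduced panels with molecules scaled so per-gene,
per-cell depth matches the full design; homogeneous abundance isolates the
planted effect from the panel-composition sensitivity noted in §4.

## 8. Pipeline

`exspat pipeline run --config run.yaml --out DIR` executes
simulate → validate → qc → spatial screen per region → neighborhood →
velocity → proximity. All stage parameters are validated before any stage
runs; stage seeds derive from the master seed by stable hashing of stage
names; a JSON-lines log carries per-stage counters (tests run, FOVs or
strata skipped), and `manifest.json` records config hash, per-stage output
hashes, seeds and wall-clock. Degenerate strata produce skip records, never
exceptions; re-running with `--resume` regenerates only stages whose
outputs are missing.

## 9. Defaults

| Parameter | Default | Why |
| --- | --- | --- |
| voxel size | 10 μm | matches the reported grid |
| Moran min_spots | 10 per (gene, FOV) | I is unstable on near-empty lattices |
| α | 0.05 | reported significance level |
| BH families | per region; expression and spatial separately | mirrors per-region gene counts |
| kNN k | 6 | neighborhood detector graph |
| cluster cut | 0.7 (1 − Spearman) | co-expression at ρ ≥ 0.3 |
| Jaccard threshold | 0.5 | recurrence/specificity matching |
| γ fit min cells | 30 | slope stability |
| stratum min cells | 10 per group | rank-test validity |
| Δt | 1 (a.u.) | magnitudes comparable only within a basis |
| proximity threshold | ≤ 1 μm boundary distance | reported stratification |
| cell-typing correlation threshold | 0.2 (Spearman) | "unknown" is safer than forced assignment |
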