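# Methods

This note documents the models, conventions and numerical choices behind
`psmapet`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, and where
the design was genuinely open.

## Coordinate and volume conventions

All volumes are axis-aligned regular grids; the world position of voxel
(i, j, k) is `origin + index·spacing` in millimetres. Oblique orientations
are deliberately unsupported — every in-repo data source (the phantom
generator, the NIfTI writer) produces axis-aligned geometry, and supporting
a single convention keeps the voxel bookkeeping exact. Voxel volume is
`Πspacing / 1000` cm³; at the default PET spacing of 4.07 × 4.07 × 2 mm this
is 0.0331298 cm³.

## SUV conversion

`to_suv_bw` implements the de-facto standard body-weight SUV:
concentration (Bq/mL) × body mass (g) / injected activity decay-corrected to
scan start (Bq), with the ⁶⁸Ga half-life of 67.71 min as default. The
decay-correction convention (correct to scan start over the uptake delay,
default 60 min) and the half-life are both parameters, since vendor consoles
vary in where they anchor the correction. The conversion is linear in
concentration; the package treats 1 g of tissue as 1 mL.

## Resampling

`resample_to_grid` uses cubic B-spline interpolation (order 3, configurable)
for intensity volumes and nearest-neighbour for masks — masks must never be
blended. One numerical subtlety: the spline prefilter is run with
nearest-neighbour boundary extension, and the out-of-extent constant fill
(default: source minimum, ≈ air for CT) is applied explicitly from the
target-to-source coordinate map. Prefiltering against a zero-padded exterior
injects visible ringing from the edge discontinuity several voxels into the
field; boundary-extension prefiltering keeps linear fields exact away from
the border, which the tests assert on a ramp.

## Connected components and detection

Contiguity is configurable as 6/18/26-connectivity with 26 (faces, edges,
corners) as the default — the most inclusive reading of "contiguous voxel
cluster". Labels are assigned in raster order of each cluster's minimum flat
index, so labelling is deterministic and reproducible across runs.

A ground-truth lesion is *detected* when the whole predicted mask covers at
least the fraction τ of the lesion's voxels, inclusive at the boundary
(overlap 0.100 at τ = 0.10 counts). The denominator is the ground-truth
lesion volume, not the union or the predicted volume. One predicted cluster
may detect several lesions; each lesion counts once. A predicted cluster
whose intersection with ground-truth foreground is *empty* is a
false-positive cluster; a cluster that touches ground truth without pushing
any lesion over τ is neither a detection nor a false positive. This
asymmetric rule is what makes the lesion-level PPV bookkeeping
(detected / (detected + FP clusters)) internally consistent.

Scan-level classification is deliberately strict on negatives: a
ground-truth-negative scan is a true negative only when the prediction
contains not a single positive voxel.

Voxel-level metrics (DSC, sensitivity, PPV, specificity) are computed per
scan and only on ground-truth-positive scans — DSC is undefined on an empty
reference, so negative scans are excluded from voxel-level summaries; cohort
summaries report mean ± SD and the median. Percentages are kept at full
precision internally and rounded half-up to one decimal only for display.

## Threshold segmentation

The baseline segmenter keeps voxels with SUV_bw strictly above the global
threshold (default 3.0; "> 3" is read literally and boundary-tested), then
removes clusters below a minimum size (default 1 voxel — no minimum — since
no such minimum is part of the protocol being mirrored), then subtracts an
explicitly supplied physiologic mask. Modelling *which* regions are
physiologic is human expertise; the package takes the mask as a declared
input rather than guessing.

## Phantom generator

The generator's defaults are the study conditions the rest of the package is
validated under:

| parameter | default | why |
| --- | --- | --- |
| grid | 96 × 96 × 256 @ 4.07 × 4.07 × 2 mm | whole-body PET reconstruction geometry |
| background SUV | lognormal, median 0.5, σ = 0.3 | low soft-tissue uptake |
| PET noise | Gaussian, sd 0.1 SUV, clipped at 0 | controllability over realism |
| lesions / positive scan | Poisson(880/209 ≈ 4.21), truncated ≥ 1 | training-cohort lesion burden per positive scan |
| lesion radius | uniform 4–20 mm | spans sub-voxel to bulky disease |
| lesion peak SUV | uniform 3.5–25 | floor just above the 3.0 threshold |
| site mix | 141:191:356:167:25 / 880 | observed five-way lesion site distribution; exact fractions so they sum to 1 |
| negative scans | 53/128 ≈ 41.4 % | evaluation-cohort composition |
| survival horizon | 80 months | follow-up range of the modelled cohort |

Lesions are spheres with a cosine-tapered uptake profile
`peak·(1+cos(πr/R))/2` added to the background; the ground-truth mask is the
set of voxels whose lesion profile reaches the SUV floor (3.0). Defining
ground truth through the same threshold that defines avidity mirrors how
tracer-avid disease is bootstrapped in practice and guarantees that an
uncorrupted threshold segmentation recovers every lesion. Lesion centres
snap to voxel centres so even the smallest lesion owns at least one voxel.
Sites are assigned by axial zones (pelvic → local prostate / regional nodal,
abdominal → distant nodal, thoracic → visceral, spine column → osseous) so
per-site tables are geometrically meaningful; osseous lesions are placed
inside the high-HU spine column of the banded CT (air −1000, soft tissue 40,
bone 700 HU). Physiologic organs are uniform-uptake ellipsoids (bladder,
kidneys, salivary glands, SUV 9–22). Lesion cores are rejected-and-resampled
until disjoint from (and non-adjacent to) organs and other lesions, with a
bounded retry budget; an overcrowded configuration raises a generation
error rather than silently overlapping.

What the phantom does **not** emulate: scanner point-spread, scatter,
partial-volume effects, reconstruction artefacts, anatomically realistic
organ shapes, or inter-lesion uptake correlation. Passing tests therefore
demonstrate the correctness of the *assessment machinery* under known ground
truth — not segmentation performance on real scans.

### Controlled corruption

`corrupt_prediction` derives a synthetic "predicted" mask from ground truth:
each lesion is dropped with probability p (miss-rate model), or eroded /
dilated by a signed voxel radius (boundary-error model), or shrunk to a
contiguous interior region of exactly ⌈f·V⌉ voxels grown breadth-first from
the centroid (partial-overlap model — this probes the τ rule to within one
voxel). False-positive clusters are small spheres placed Poisson(rate) per
scan, rejected until disjoint from and non-adjacent to both ground truth and
the current prediction, so every injected cluster is counted as exactly one
false positive downstream.

### Survival simulation

Event times are exponential with hazard `λ₀·exp(β·log1p(TLV))` — a
proportional-hazards law on log burden, so β = 0 is an exact null.
Observation is truncated by optional independent exponential censoring and
an administrative horizon (default 80 months). All randomness in the
generator flows through one seeded `numpy` Generator per call; identical
(config, seed) gives bit-identical volumes, masks and survival tables.

## Survival statistics

Kaplan–Meier estimation and the unweighted (Mantel–Haenszel) log-rank test
are delegated to lifelines; Wilcoxon signed-rank, Spearman and one-way ANOVA
to scipy.stats. Conventions fixed here because they are genuinely open:

- Median split assigns values **≤** median to the low group. Q1-vs-Q4
  compares values ≤ 25th percentile against values ≥ 75th percentile, with
  linear-interpolation quantiles computed on the analysed subset.
- Only baseline scans enter survival analysis; follow-up timepoints are
  filtered before stratification.
- Two-group log-rank only (1 df); no trend test.
- Wilcoxon drops zero differences, mid-ranks ties, uses the exact null
  distribution for n ≤ 25 without ties and the normal approximation with
  continuity correction otherwise.
- p-values below 0.005 are *displayed* as "< 0.005"; machine-readable
  outputs always carry the exact value.

Measured calibration (recomputed by the acceptance script, not asserted from
memory): the log-rank null rejection rate at α = 0.05 with 36 + 36
exponential subjects sits within [0.035, 0.065], and median-split power
under a strong burden effect (β = 1.5, n = 128) exceeds 0.8.

## Pipeline and problem sizes

`run_pipeline` fans a single master seed out to per-scan generation seeds,
per-scan corruption seeds and a survival seed through
`numpy.random.SeedSequence`, making cohort runs byte-reproducible. The
default cohort is 128 scans (53 negative) at full grid resolution with a
27 % lesion drop rate and 30/128 FP clusters per scan — the composition the
package's acceptance run uses. The test suite runs its cohort-scale loops on
a reduced 48 × 48 × 96 grid (identical spacing, uptake model and site
logic); the full 96 × 96 × 256 grid is exercised in targeted tests and in
the acceptance script. Test assertions on stochastic recoveries use 3
binomial standard errors around the configured rates.

## Known limitations

- TLU units are a bare SUV sum; whether a volume-weighted variant is more
  appropriate depends on the downstream use, so `compute_total_lesion_activity`
  (Σ SUV × voxel volume) is provided under its own name and is never the
  default.
- The phantom's site geometry is a caricature (axial bands + a cylindrical
  spine); per-site sensitivities are meaningful for machinery validation
  only.
- `match_lesions` computes overlap against the whole predicted mask; there
  is no per-component assignment problem (no Hungarian matching), matching
  the one-sided volumetric detection rule.
- Surface-distance metrics (Hausdorff, ASSD), per-lesion SUV statistics and
  radiomics features are out of scope.
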