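# psmapet

Whole-body PSMA PET/CT lesion assessment downstream of *any* segmenter:
SUV quantification, threshold-based candidate segmentation, three-level
evaluation of predicted lesion masks, whole-body tumour-burden biomarkers,
and Kaplan–Meier survival stratification — together with a synthetic
whole-body phantom cohort generator so the entire pipeline can be exercised
and validated end-to-end without clinical data.

## Who this is for

Groups developing or evaluating automated metastatic-lesion segmentation on
whole-body [⁶⁸Ga]Ga-PSMA-11 PET/CT (or similar tracer studies) who need the
*assessment* half of the problem: given a predicted lesion mask and a
reference delineation, how good is the prediction at the patient, lesion and
voxel level, and do the derived burden biomarkers carry prognostic signal?

## The model in brief

**SUV conversion.** PET activity concentration C(v) in Bq/mL is converted to
the body-weight standardised uptake value

    SUV_bw(v) = C(v) · m / A(t),   A(t) = A₀ · 2^(−t/T½),

with body mass m in grams, injected activity A₀ decay-corrected to scan
start over the uptake delay t (T½ = 67.71 min for ⁶⁸Ga).

**Candidate segmentation.** Tracer-avid candidates are voxels with
SUV_bw > 3 (strict inequality); regions of physiologic uptake (bladder,
kidneys, salivary glands, …) are removed with an explicit physiologic mask;
contiguous clusters are extracted under 6/18/26-connectivity (default 26).

**Three-level evaluation.** A ground-truth lesion counts as *detected* when
the predicted mask covers at least a fraction τ of its volume (τ = 0.10 by
default, inclusive). A predicted cluster with no ground-truth overlap is a
false positive; clusters that touch ground truth without triggering a
detection are neither. Scan-level: a positive scan is a true positive iff
≥ 1 lesion is detected; a negative scan is a true negative only if *not a
single voxel* is predicted. Voxel-level: DSC = 2|A∩B|/(|A|+|B|),
sensitivity |A∩B|/|A|, PPV |A∩B|/|B|, specificity.

**Biomarkers.** TLV = Σ voxel volumes over the lesion mask (cm³);
TLU = Σ SUV_bw over the mask (unitless, no volume weighting; the
volume-weighted total lesion activity is available under its own name).

**Survival.** Kaplan–Meier product-limit curves and the unweighted log-rank
test on median splits (low group = values ≤ median) or Q1-vs-Q4 splits of a
biomarker, baseline scans only; supporting statistics include the Wilcoxon
signed-rank test (exact for n ≤ 25), Spearman correlation and one-way ANOVA.

**Phantom cohorts.** Synthetic whole-body scans on a 96 × 96 × 256 grid at
4.07 × 4.07 × 2 mm voxels: lognormal background uptake, ellipsoidal hot
organs, cosine-tapered spherical lesions with a five-way anatomical site mix
placed in axial body zones, CT with air/soft-tissue/bone bands, paired
"predicted" masks with controlled error modes (lesion drops,
erosion/dilation, exact partial overlap, Poisson false-positive clusters),
and exponential proportional-hazards survival times tied to log1p(TLV).

## Worked example

```python
from psmapet import (PhantomConfig, CorruptionConfig, generate_scan,
                     corrupt_prediction, match_lesions, voxel_metrics,
                     compute_tlv, compute_tlu)

scan = generate_scan(PhantomConfig(), positive=True, seed=1)
pred = corrupt_prediction(scan.ground_truth,
                          CorruptionConfig(drop_probability=0.27,
                                           fp_rate=30/128, seed=7))
report = match_lesions(scan.ground_truth, pred, tau=0.10)
print(f"lesions {report.n_lesions}, detected {report.n_detected}, "
      f"FP clusters {report.fp_cluster_count}")
vox = voxel_metrics(scan.ground_truth.foreground(), pred)
print(f"DSC {vox.dsc:.1f}%  TLV {compute_tlv(pred):.3f} cm³  "
      f"TLU {compute_tlu(pred, scan.pet):.1f}")
```

prints

```
lesions 5, detected 4, FP clusters 1
DSC 91.5%  TLV 13.948 cm³  TLU 3500.3
```

Five ground-truth lesions were generated; the corruption model dropped one
(27 % per-lesion miss rate) and injected one false-positive cluster on this
draw, and the remaining prediction overlaps ground truth with DSC 91.5 %.
The whole-body burden of the predicted mask is 13.948 cm³ (TLV) with a total
uptake sum of 3500.3 (TLU).

The same stages are scriptable from the shell:

```bash
psmapet simulate --n-scans 4 --seed 0 --out scans/
psmapet segment --pet scans/P0003_pet_suv.nii.gz \
                --physiologic scans/P0003_physiologic.nii.gz --out mask.nii.gz
psmapet evaluate --gt scans/P0003_gt.nii.gz --pred mask.nii.gz --out report.json
psmapet run-all --n-scans 32 --seed 0 --out run/
psmapet report --run-dir run/
```

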