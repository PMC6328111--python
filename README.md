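# nodulecad

Computer-aided detection (CAD) of pulmonary nodules on thin-slice chest CT.

Radiologists screening for lung cancer must find nodules — roughly spherical
opacities of 3–30 mm — among thousands of CT slices in which the dominant
bright structures are pulmonary vessels. The hardest false positives are
**vessel bifurcations**, whose smoothed intensity profile mimics a blob, and
the hardest true positives are **juxta-vascular** nodules attached to those
same vessels. `nodulecad` implements a classic two-group CAD pipeline for
this problem, fully testable without any clinical data through a synthetic
thorax phantom generator with known ground truth.

## Pipeline

1. **Lung-window normalization** — HU values are mapped to real numbers in
   [0, 1] on the lung window (width 1600 HU, level −600 HU); no 8-bit
   re-quantization, so subtle contrast survives.
2. **Lung segmentation** — Otsu extraction of the air region, airway removal
   by seeded 3D region growing with a leak guard, separation of fused lungs
   along the anterior junction line (gray-integral projection), and boundary
   repair with a 15 mm rolling ball that recovers juxta-pleural indentations.
3. **Grouping** — high-attenuation structures inside each lung
   (multilevel-Otsu upper class, 26-connectivity labeling) are split into the
   *vessel-tree group* (the largest connected component per lung, carrying
   any attached nodule) and the *non-vessel-tree group* (everything else).
4. **Dot enhancement** — a multi-scale Hessian blob filter. With eigenvalues
   sorted |λ₁| ≥ |λ₂| ≥ |λ₃|,

       Z(λ₁, λ₂, λ₃) = |λ₃|² / |λ₁|   if λ₁, λ₂, λ₃ < 0, else 0,

   computed from σ²-normalized Gaussian derivatives and maximized over
   scales σ ∈ {1, 1.5, 2, 4, 6, 10} mm. Spheres respond strongly, tubes and
   sheets are suppressed. Binarization thresholds: 15/256 (vessel-tree
   group) and 10/256 (non-vessel group), followed by constrained region
   growing of up to 5 mm geodesic distance to reclaim the full nodule.
5. **False-positive reduction (non-vessel group)** — volume gates
   (14.14 mm³ – 14.14 cm³, the 3 mm and 30 mm sphere volumes) and three lax
   shape rules: elongation ≤ 6, 2D compactness ≥ 0.3, sphericity ≥ 0.3.
6. **Classification (vessel-tree group)** — 27 gray-level / surface-gradient
   / shell-gradient / inertia-tensor shape features per candidate,
   random-subset feature selection (RSFS), boundary-aware undersampling, and
   a weighted RBF-SVM tuned by nested cross-validation with the geometric
   mean √(sensitivity × specificity) as the imbalance-robust score.
7. **Evaluation** — centroid-within-truth-radius matching, per-group
   sensitivity and FPs/scan, ROC/AUC, and the composite arithmetic that
   combines the prescreening and classification stages.

## Worked example

```python
from nodulecad import generate_phantom, PhantomSpec, NoduleSpec
from nodulecad.pipeline import detect_volume, label_candidates
from nodulecad.evaluation import match_detections, group_metrics

spec = PhantomSpec(seed=42, nodules=[
    NoduleSpec(type="isolated", diameter_mm=8.0),
    NoduleSpec(type="juxta_pleural", diameter_mm=10.0),
    NoduleSpec(type="juxta_vascular_tree", diameter_mm=9.0),
])
vol, truth = generate_phantom(spec)          # normalized volume + ground truth
result = detect_volume(vol)                  # segment, group, enhance, extract
print("stage counts:", result.stage_counts)

labels = label_candidates(result.vessel_candidates, truth.objects)
detections = result.nonvessel_detections + [
    c for c, keep in zip(result.vessel_candidates, labels) if keep]
tp, fp, fn = match_detections(detections, truth.objects)
sens, fps = group_metrics(tp, fp, fn, n_scans=1)
print(f"TP={tp} FP={fp} FN={fn}  sensitivity={sens:.2f}  FPs/scan={fps:.1f}")
```

prints

```
stage counts: {'structures': 5, 'nonvessel_components': 3,
 'nonvessel_after_rules': 1, 'nonvessel_detections': 1, 'vessel_candidates': 39}
TP=3 FP=0 FN=0  sensitivity=1.00  FPs/scan=0.0
```

The isolated and juxta-pleural nodules come out of the non-vessel branch
(the rule filter discarded the tiny peripheral vessels, then the dot filter
kept the nodule); the juxta-vascular nodule is one of 39 vessel-group
candidates — the other 38 are vessel bifurcations, which is exactly the
imbalance the weighted SVM is there to resolve (here the ground-truth labels
stand in for it). `run_phantom_study` runs the same flow over a whole batch
with a leave-one-volume-out classifier.

A command-line interface mirrors the library:

```
nodulecad phantom --seed 3 --output out/           # volume + truth CSV
nodulecad detect --input ct.nii.gz --output out/   # candidates + masks
nodulecad train  --features feats.csv --output out/
nodulecad eval   --detections det.csv --truth truth.csv
```

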