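# vmdseiz

Seizure detection from multichannel scalp EEG. The package implements a
classical machine-learning detection pipeline for 2-s EEG epochs:

1. **Preprocessing** — zero-phase 1–60 Hz band-pass plus a power-line notch,
   then segmentation of annotated recordings into non-overlapping 2-s epochs
   labeled interictal (0) or ictal (1).
2. **Variational mode decomposition (VMD)** — each channel of each epoch is
   split into K = 6 band-limited modes by minimizing the summed analytic
   bandwidth Σ_z ‖∂_t[(δ(t) + j/πt) * p_z(t)] e^{−jω_z t}‖² subject to
   Σ_z p_z = f, solved by ADMM in the frequency domain (Wiener-filter mode
   update, spectral-centroid frequency update, dual ascent).
3. **Features** — per mode, the differential entropy DE = ½ ln(2πe σ²)
   averaged over the five canonical EEG bands (δ, θ, α, β, γ), and the
   Higuchi fractal dimension (HFD) from the log–log slope of delay-decimated
   curve lengths. 2K features per channel per epoch.
4. **Channel selection** — binary grey-wolf optimization (BGWO): candidate
   channel masks evolve under the canonical α/β/δ leader updates, binarized
   through the steep transfer S(x) = 1/(1 + e^{−10(x−0.5)}) against uniform
   draws; fitness is stratified-CV KNN accuracy minus a small cardinality
   penalty. Exactly 5 channels are kept.
5. **Classification** — an RBF-kernel SVM on the selected channels under
   stratified 10-fold cross-validation, reporting accuracy, sensitivity
   TP/(TP+FN), specificity TN/(TN+FP), and the rank-statistic AUC of the
   decision scores.

It is aimed at EEG/biosignal researchers who want a tested, reproducible
reference implementation of this pipeline — including a synthetic-data
module that plants known ground truth (informative channels, DE/HFD class
contrast, known-fractal-dimension series, tone mixtures) so every stage can
be validated without access to clinical data.

## Worked example

```python
from vmdseiz import (
    BGWOConfig, PipelineConfig, SyntheticSpec, run_pipeline,
)

spec = SyntheticSpec()          # 8 channels, 5 informative, 100+100 epochs
cfg = PipelineConfig(selection=BGWOConfig(target_channels=5),
                     n_folds=10, master_seed=1)
report, selection, features = run_pipeline(spec, cfg, out_dir="artifacts")

print("selected channels:", selection.selected_channels)
print(f"accuracy    {report.accuracy:.3f}")
print(f"sensitivity {report.sensitivity:.3f}")
print(f"specificity {report.specificity:.3f}")
print(f"auc         {report.auc:.3f}")
```

Output:

```
selected channels: [0, 1, 2, 3, 6]
accuracy    0.995
sensitivity 0.990
specificity 1.000
auc         1.000
```

Four of the five selected channels (0, 2, 3, 6) are planted informative
channels; the
pooled 10-fold confusion counts give 99.5 % accuracy because the generator
plants a strong ictal signature (suppressed 1/f background, 3 Hz
spike-and-wave, broadband high-frequency noise) on those channels. The
`artifacts/` directory receives the epoch archive, feature CSV, channel
mask, classifier report and a manifest with the configuration hash and all
derived stage seeds; rerunning the same call reproduces every file
byte-for-byte.

The same stages are scriptable from the shell:

```sh
vmdseiz simulate --out data/
vmdseiz features data/epochs.npz --k 6 --out features.csv
vmdseiz select features.csv --target 5 --seed 1 --out mask.json
vmdseiz classify features.csv --mask mask.json --folds 10 --report report.json
vmdseiz run --out artifacts/          # everything in one shot
```

Clinical EDF recordings are supported through the same pipeline:
`run_pipeline([(path.edf, annotations.csv), ...], cfg)`, where the CSV has
`start_s,end_s,label` rows marking interictal/ictal intervals.

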