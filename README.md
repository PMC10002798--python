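# slacspect

Transmission-less attenuation compensation (AC) for myocardial perfusion
SPECT, with task-based evaluation — built and tested entirely on synthetic
digital thorax phantoms.

Conventional AC needs a CT-derived attenuation map, which adds dose, cost
and misregistration risk, and many SPECT systems have no CT at all.  The
method implemented here (SLAC: scatter-window + learning-based AC)
estimates the attenuation map from the emission data alone:

1. reconstruct the Compton **scatter window** (114–126 keV) without AC —
   scatter probability tracks the attenuation distribution, so this
   reconstruction carries tissue contrast;
2. **segment** it (together with the photopeak no-AC reconstruction) into
   six tissue classes — background, lungs, skin/adipose, muscles/organs,
   bones, patient table — with an attention-gated multi-decoder U-Net
   (McEUN) or a classical fallback segmenter;
3. assign **predefined per-class attenuation coefficients** (class means
   fitted on a training cohort), yielding a piecewise-constant μ map;
4. reconstruct the **photopeak window** (126–154 keV) with OSEM using that
   map for attenuation compensation, plus collimator-detector response
   modeling, Butterworth post-filtering (order 5, cutoff 0.44 cm⁻¹) and
   short-axis reorientation.

Evaluation is task-based: a channelized Hotelling observer (CHO) with
rotationally symmetric frequency channels scores 32×32 short-axis ROIs for
myocardial perfusion defects (27-type grid: extent × severity × wall),
leave-one-out; empirical and binormal ROC give the AUC, the figure of
merit, and RMSE/SSIM quantify fidelity against the CT-based AC (CTAC)
reference.  Three arms are compared under identical reconstruction:
**SLAC vs CTAC vs NAC** (no AC).

The intended audience is researchers in SPECT reconstruction and model
observers who want a compact, fully synthetic, reproducible sandbox for
transmission-less AC pipelines.

## Worked example

```python
from slacspect.pipeline import ExperimentConfig, run_full_experiment

report = run_full_experiment(ExperimentConfig(seed=1234))
print(report.summary())
```

With the default desk-scale configuration (10 training patients, 12
defect-present + 12 defect-absent test patients, inferior-wall defects,
30-view anterior arc, 4×10⁶ counts, fallback segmenter) this prints, after
about ten minutes on one CPU:

```
auc_slac            0.6759   (95% CI 0.595-0.749)
auc_ctac            0.6561   (95% CI 0.581-0.728)
auc_nac             0.5936   (95% CI 0.519-0.670)
rmse_slac_vs_ctac   0.0244
ssim_slac_vs_ctac   0.9330
rmse_nac_vs_ctac    0.0263
ssim_nac_vs_ctac    0.9043
```

Reading: detection of inferior-wall defects degrades clearly without
attenuation compensation (NAC), while the transmission-less SLAC arm
performs on par with the CT-based reference — the SLAC-CTAC difference
(0.02) is smaller than the CTAC-NAC gap (0.06) — and SLAC images are
closer to the CTAC reference than NAC's by both RMSE and SSIM.  At this
cohort size the AUC differences are of the same order as the bootstrap
CIs; the ordering is the scientifically expected one, not a powered
clinical claim.

A CLI wraps the main stages:

```bash
slac simulate --seed 3 --out out/pt3          # phantom + noisy 2-window scan
slac segment  --projections out/pt3/projections --out out/pt3/seg.nii.gz
slac recon    --projections out/pt3/projections --out out/pt3/nac.nii.gz
slac train    --n-train 8 --out out/mceun.npz  # train the McEUN segmenter
slac evaluate --seed 1234 --out out/report.json
slac report   --report out/report.json --plot out/roc.png
```

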