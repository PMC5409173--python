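# frocdwi

Quantitative analysis of multi-b-value breast diffusion-weighted MRI:
voxel-wise fitting of the mono-exponential (ADC), fractional-order-
calculus (FROC) and intravoxel-incoherent-motion (IVIM) signal models,
per-lesion summarisation, and the benign-vs-malignant statistical
comparison (Mann–Whitney U, ROC/AUC with DeLong confidence intervals,
paired AUC tests, lesion-size stratification).  A calibrated
Rician-noise phantom generator makes the whole chain runnable and
testable end-to-end without clinical data.

Intended users: MR physicists and imaging scientists evaluating
diffusion biomarkers on few-b-value protocols.

## Models

On the four-point breast protocol (b = 0, 100, 750, 1500 s/mm²,
δ = 14.1 ms, Δ = 35.1 ms):

* ADC: `S(b) = S0 · exp(−b · D_app)`, fitted by log-linear least squares
  on b ≤ 750 s/mm².
* FROC: `S = S0 · exp(−D · μ^{2(β−1)} · (γGδ)^{2β} ·
  (Δ − ((2β−1)/(2β+1)) · δ))`, with fractional order β ∈ (0, 1]
  (heterogeneity-related) and spatial constant μ (μm), fitted by a
  staged ladder: D from the ADC fit, β from 0.5, μ from a 1-D pre-fit,
  then bounded Levenberg–Marquardt over (D, β, μ) on the weighted
  b-values with S0 frozen to the b = 0 signal.
* IVIM: `S = S0 · [f · exp(−b·D*) + (1−f) · exp(−b·D)]`, fitted on all
  b-values with deterministic segmented initialisation (D* flagged
  low-confidence).

A caveat built into the API: with a single gradient timing, the FROC
data determine only β and the product `D · μ^{2(β−1)}` — D and μ are
not separately identifiable, and their split reflects the fit's
starting point.  Diagnostics record every starting point and
`initialization_sensitivity` quantifies the coupling.  See
`docs/methods.md`.

## Worked example

```python
import numpy as np
from frocdwi import AcquisitionScheme, FROCParams, froc_signal, fit_froc

scheme = AcquisitionScheme.breast_protocol()   # b = 0/100/750/1500
truth = FROCParams(S0=1000.0, D=1.03, beta=0.69, mu=8.34)
signal = froc_signal(truth, scheme)
print(np.round(signal, 2))
# [1000.    838.78  493.58  320.11]

params, diag = fit_froc(signal, scheme)
print(f"D={params.D:.4f} beta={params.beta:.4f} mu={params.mu:.4f}")
# D=0.9166 beta=0.6900 mu=6.9092
print(params.D * params.mu ** (2 * (params.beta - 1)))   # 0.27651...
print(truth.D * truth.mu ** (2 * (truth.beta - 1)))      # 0.27651...
```

The fit reproduces β exactly and lands on the D–μ ridge: the
identifiable product matches the truth to machine precision while the
individual D and μ sit where the initialisation put them — the
documented behaviour of this model on single-timing protocols.

Full pipeline from the shell:

```sh
frocdwi pipeline --seed 1 --out results/
# results/results.csv        per-parameter AUC, CI, Mann-Whitney p,
#                            paired AUC-vs-ADC p; repeated for the
#                            <=10 mm and >10 mm size subgroups
# results/lesion_summaries.csv  one row per lesion
# results/results.json, manifest.json
```

`simulate`, `fit` and `analyze` run the stages separately on NIfTI +
FSL-.bval(+JSON timing sidecar) + CSV inputs.

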