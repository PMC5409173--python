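# Methods

## The problem

Multi-b-value diffusion-weighted MRI (DWI) of the breast is read
quantitatively by fitting signal-decay models voxel by voxel inside a
lesion ROI, averaging the fitted parameters over the ROI, and asking
whether the per-lesion summaries separate malignant from benign
lesions.  This package implements three decay models on the four-point
breast protocol (b = 0, 100, 750, 1500 s/mm², gradient pulse width
δ = 14.1 ms, lobe separation Δ = 35.1 ms), the voxel-wise fitting
procedures, the cohort statistics, and a calibrated synthetic phantom so
the full chain is testable without clinical data.

## Signal models and units

Internally: time in ms, length in μm, field in mT, so diffusivities are
μm²/ms and 1000 s/mm² = 1 ms/μm².  γ = 267.513 rad·ms⁻¹·mT⁻¹ (proton).
Public interfaces take b in s/mm² and convert at the boundary.

* **Mono-exponential (ADC)**: S(b) = S₀·exp(−b·D_app).
* **IVIM**: S(b) = S₀·[f·exp(−b·D*) + (1−f)·exp(−b·D)].
* **FROC** (fractional-order calculus):
  S = S₀·exp(−D·μ^{2(β−1)}·(γGδ)^{2β}·(Δ − ((2β−1)/(2β+1))·δ)),
  with fractional order β ∈ (0, 1] and spatial constant μ (μm).

Gradient amplitudes G are a convention inverted from the nominal
b-values through the rectangular-pulse relation b = (γGδ)²(Δ − δ/3)
(the β = 1 limit of the FROC exponent), not measured hardware values.
This makes the β = 1 collapse of FROC onto the mono-exponential exact by
construction.  β > 1 is rejected rather than extrapolated: the timing
factor loses its meaning there and reported tissue values are ≤ 1.

### Identifiability of the FROC fit (important)

With a single (δ, Δ) timing, the exponent can be rewritten as
−[D·μ^{2(β−1)}·T(β)]·(b/(Δ−δ/3))^β: the data determine **β and the
product D·μ^{2(β−1)}** and nothing more.  Two parameter sets with equal
β and product generate bit-identical signals at every b, so no
estimator can split D from μ; the split is inherited from the fit's
starting point.  The implementation therefore records the initial
values in every fit's diagnostics, exposes the product as
`coupling_product` in `initialization_sensitivity`, and the recovery
tests assert the identifiable set (β and the product to 1e-3 relative
on noiseless data; machine precision in practice).  Separating D and μ
would need acquisitions at several (δ, Δ) combinations, which the
four-point protocol does not provide.

## Voxel fitting

All fits are deterministic (no random starts); repeated calls are
bit-identical.

* **ADC**: ordinary least squares of log S on b over b ≤ 750 s/mm²
  (exact on noiseless data; the b = 1500 channel never enters).
* **FROC ladder**: (1) D_init from the b ≤ 750 ADC fit; (2) β_init =
  0.5; (3) μ_init from a bounded 1-D least-squares fit of μ alone with
  (D_init, β_init) frozen, on the diffusion-weighted channels (matching
  stage 4); (4) bounded trust-region Levenberg–Marquardt over
  (D, β, μ) on b = 100/750/1500 with S₀ frozen to the measured b = 0
  signal and an analytic Jacobian.
* **IVIM**: all four b-values, S₀ frozen to S(b = 0), the constraint
  D* ≥ D imposed structurally by fitting the excess D* − D ≥ 0.
  Segmented initialisation: D from the high-b (≥ 750) slope, f from the
  gap between S₀ and the high-b fit extrapolated to b = 0 (clipped to
  [0.01, 0.5]), D* = 10·D.  D* is returned but flagged low-confidence —
  one sub-200 b-value cannot pin a pseudo-diffusion coefficient.

Bounds: D ∈ [10⁻³, 10] μm²/ms, β ∈ [0.01, 1], μ ∈ [0.1, 50] μm,
f ∈ [0, 1], D* ≤ 500 μm²/ms — enclosing all reported breast values with
wide margins.  Convergence tolerances 1e-10 (relative step and cost),
iteration cap 500, chosen so optimizer tolerance is never the accuracy
bottleneck.  Voxels with any non-positive signal are flagged invalid
and skipped, never zero-filled.

## Cohort statistics

Per-lesion summaries are arithmetic means over valid ROI voxels
(lesion-level means, not voxel pooling).  Group comparison uses the
two-sided Mann–Whitney U test: exact when n₁·n₂ ≤ 400 with tie-free
data, otherwise the normal approximation with tie and continuity
corrections (scipy).  Percentiles use linear interpolation.

ROC areas are the midrank concordance (Mann–Whitney) estimator; 95%
CIs use the DeLong variance, and per-parameter AUCs are compared
against the ADC with the paired DeLong test for correlated curves (a
stratified-bootstrap alternative is available for tiny subgroups).
Each score is auto-oriented so AUC ≥ 0.5 — diffusivity-like parameters
score malignancy with *lower* values — and the direction is recorded.
No multiple-testing correction is applied across parameters; p-values
are reported raw, matching common practice for this analysis.  The
whole analysis repeats within lesion-size subgroups (≤ 10 mm and
> 10 mm maximal in-plane diameter by default); a subgroup missing one
class is reported as not computable rather than aborting.

## Synthetic phantom

Per-lesion parameters are drawn from class-conditional two-parameter
laws identified by median plus quartile: log-normal for D and μ,
logit-normal for β and f.  Calibration targets (per-lesion medians and
25–75% quartiles):

| parameter | malignant | benign |
|---|---|---|
| D (μm²/ms) | 0.97 (0.87–1.01) | 1.20 (1.06–1.47) |
| β | 0.69 (0.60–0.77) | 0.75 (0.64–0.78) |
| μ (μm) | 8.34 (7.74–9.05) | 8.91 (7.30–10.30) |

Because the printed quartiles are asymmetric while a two-parameter law
has one spread parameter, a `skew` flag selects the calibrating
quartile (upper, lower, or the averaged implied sigma; default
averaged).  The f law is deliberately weakly informative (population
AUC ≈ 0.54, benign median 0.055); per-class D* laws are unpublished, so
both classes share a broad log-normal (median 30 μm²/ms) — both
documented approximate.  Lesion diameters are truncated normals; the
source statistics disagree between running text and the demographics
table on the class SDs, so both variants are exposed as presets
(`table2`, the default: benign 11.54 ± 4.03 mm in 4.9–21.7, malignant
12.56 ± 5.17 mm in 6.3–21.3; `text` swaps the SDs).

The forward voxel signal is the IVIM mixture whose tissue term is the
FROC decay, scaled to S₀ = 1000, with 5% relative log-normal
within-lesion jitter (so ROI means differ from single voxels), rendered
as world-mm spheres on a 2.5 × 2.5 × 3 mm grid, one cell per lesion,
over a distinct high-diffusivity background (mono-exponential, D = 2.0
μm²/ms, S₀ = 300, emulating fibroglandular tissue after fat
suppression).  Rician noise — the magnitude of a complex Gaussian
perturbation, E[M²] = S² + 2σ² — is added at SNR 50 at b = 0 (typical
for breast EPI-DWI and high enough that noise bias does not dominate
calibration).  Everything is reproducible bit-for-bit from (spec,
seed).

A summary-level path (`simulate_cohort_summaries`) draws the same
per-lesion truth and per-voxel noisy signals but skips spatial
rendering; replicate studies use it with 4–8 fitted voxels per lesion,
a problem-size choice that preserves the per-lesion-mean structure the
statistics consume while keeping hundreds of replicates tractable.

### What the phantom does and does not show

Passing tests demonstrate that the *pipeline* is correct and
deterministic and that the *statistical machinery* behaves as designed
under the calibrated laws.  The phantom does not emulate EPI
distortion, partial-volume fat, real lesion shapes, spatial noise
correlation, or rater variability in ROI placement; conclusions about
real diagnostic performance do not follow from it.  Two model-driven
effects surface in the synthetic cohorts and are worth knowing:

* **IVIM/FROC mismatch**: a β < 1 tissue term has a steep initial decay
  that the IVIM fit absorbs into its perfusion fraction, so fitted f
  exceeds the generating f whenever β < 1 (tested explicitly).
* **ADC contamination**: the fitted D_app is a deterministic transform
  of (D, β, μ, f), so between-lesion variance of the weakly
  discriminative parameters leaks into D_app and compresses its AUC
  relative to the sampled-D population value (0.73 vs 0.78 noise-free).
  Consequently the synthetic cohorts reproduce the *direction* of the
  published comparison (ADC ≥ FROC β/μ, D-like parameters significant,
  β/μ mostly not) but at weaker effect sizes than the published AUCs —
  which are themselves larger than the published quartiles can support
  under any median/quartile-calibrated two-parameter law.

## Numerical notes

* The β = 1 collapse onto the mono-exponential is exact because G is
  derived from b by inverting the β = 1 correspondence; μ^{2(β−1)}
  evaluates to exactly 1.0 in floating point at β = 1.
* Double-precision FROC evaluation agrees with a 50-digit
  arbitrary-precision oracle to better than 1e-12 relative.
* Overflowing model evaluations raise an invalid-parameter error rather
  than propagating NaN.
* Fits on the β bound are flagged (`beta_at_bound`) rather than
  silently projected.
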