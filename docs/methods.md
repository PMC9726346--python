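# Methods

This note documents the models, defaults and numerical choices behind
`dtialps`, and what the validation suite does and does not demonstrate.

## Signal model and phantom

Every voxel carries a single symmetric diffusion tensor D (mm²/s); the
diffusion-weighted signal for b-value b and unit gradient g is the
mono-exponential model S = S0·exp(−b·gᵀDg). The phantom realises the
geometric premise of the ALPS method at the lateral-ventricle-body
level with axis-aligned diagonal tensors:

| region       | eigenvalues (λx, λy, λz)        | principal axis |
|--------------|---------------------------------|----------------|
| projection   | (α·λ⊥, λ⊥, λ∥)                  | z              |
| association  | (α·λ⊥, λ∥, λ⊥)                  | y              |
| subcortical  | (λ⊥, λ∥, λ⊥)                    | y              |
| CSF          | isotropic 3.0 × 10⁻³            | —              |

with λ⊥ = 0.3 × 10⁻³ and λ∥ = 1.4 × 10⁻³ mm²/s, literature-typical
white-matter values (the emulated study publishes no per-tissue
diffusivities). The single free factor α = target ALPS dials the
x-axis diffusivity of both fibre regions, so the analytic index
mean(λx_proj, λx_assoc)/mean(λy_proj, λz_assoc) equals the target
exactly; targets must stay below λ∥/λ⊥ ≈ 4.67 so that x remains a
transverse direction. Oblique fibres, crossing fibres, partial volume
and motion/eddy artifacts are deliberately outside the model: the
phantom isolates the measurement chain, not anatomy.

The default grid is 64×64×16 voxels at 1.875×1.875×2.5 mm — the
in-plane resolution of a 240 mm FOV / 128 matrix acquisition with
2.5 mm slices, cropped in extent for desk-scale runtimes. The affine is
RAS with the world origin at the grid centre, so hemispheres are exact
voxel mirrors about x = 0. Region blocks are placed by fixed fractional
extents, which keeps smaller grids (the 16³ smoke fixture) valid and
mirror-symmetric.

## Acquisition scheme

8 b = 0 volumes followed by 30 directions at b = 600 s/mm². Directions
come from a spherical Fibonacci lattice: deterministic, dependency-free
and near-uniform (minimum pairwise angle 32.7° for n = 30). The vendor
direction table of the emulated protocol is not published; any
well-spread 30-direction set yields a rank-7 design and exact noiseless
recovery, so the choice only perturbs noise propagation marginally.

## Noise

Rician magnitude noise: S ← |(S + ε₁) + i·ε₂| with ε ~ N(0, σ) and
σ = S0_ref/SNR, S0_ref the mean b0 signal over tissue. Default SNR 40,
chosen so measurement noise is small relative to the between-group ALPS
effect while still exercising the estimator. At SNR 40 the per-subject
ALPS estimate is unbiased with SD ≈ 0.03 (measured over 200 seeded
hemisphere measurements: mean signed error 0.001, SD 0.032); roughly
85–90% of hemisphere estimates fall within 0.05 of truth and all within
0.12. That dispersion is set by the physics of the protocol — b = 600,
30 directions, ~8-voxel 5-mm ROIs — not by the implementation: the
log-linear WLS fit agrees with an independent nonlinear least-squares
fit to ≈ 10⁻⁶ mm²/s per voxel.

## Cohort generator

Each subject draws age ~ N(μ_age, σ_age) (per group), then, per
hemisphere, ALPS conditionally on the standardised age so that the
marginal is N(μ_ALPS, σ_ALPS) with corr(age, ALPS) = ρ. Gestational age
and sex are independent. ALPS values are redrawn (residual only) until
above 0.5; with the default group parameters the bound is ≈ 3 SD below
every group mean, so truncation is effectively inactive. Defaults are
the published two-group study: ASD n = 30 (left 1.02 ± 0.12, right
1.03 ± 0.12), control n = 25 (left 1.27 ± 0.25, right 1.32 ± 0.20),
ages 47.83 ± 15.56 vs 44.80 ± 15.01 months, ρ = +√R² from the printed
age–ALPS R² (ASD 0.4658/0.441, control 0.3028/0.3709). The source
study's Results and abstract report a *positive* age association while
one Discussion sentence says "inversely correlated"; the generator
follows the Results and this contradiction is only noted, not resolved.
Randomness is organised as spawned substreams of one top-level seed
(demographics and scanner noise separately per subject), so cohorts are
pure functions of (config, seed) regardless of iteration order.

## Tensor fit

Per masked voxel: ordinary least squares on log S against the 7-column
design [−b·gx², −b·gy², −b·gz², −2b·gxgy, −2b·gxgz, −2b·gygz, 1],
followed by one weighted pass with weights equal to the predicted
squared signal (the first-order variance correction for log-transformed
magnitude data). Signals are floored at 10⁻⁸·S0_ref before the log;
negative eigenvalues are clamped to zero; either event flags the voxel
and flagged voxels are excluded from ROI means rather than imputed.
Multiple b0 volumes enter as ordinary rows. The default mask is
"mean b0 > 0"; the pipeline passes the phantom label volume as mask
(the phantom's brain-mask analogue), which changes no ROI statistic —
every ROI voxel is labelled — and avoids fitting empty background.

## ROI placement and the ALPS index

The study placed 5-mm spherical ROIs manually on colour-FA maps; manual
placement is not reproducible in software, so ROIs are centred
automatically at the world-space centroid of each labelled fibre
region. Sphere membership is by voxel-centre distance (≤ diameter/2, no
partial-volume weighting); on this grid a 5-mm sphere centred on a
voxel centre contains 7 voxels (centre + 6 face neighbours, the 2.5-mm
z-neighbours included by the boundary-inclusive rule) and one centred
at a region centroid of the default layout contains the 2×2×2 block
around it. The subcortical ROI is measured and reported but excluded
from the index, whose denominator is fixed as mean(Dyproj, Dzassoc):
the source prints a typographically garbled formula line, and the prose
symbols Dyproj/Dzassoc are the consistent reading. The index is scale
invariant and strictly monotone in its four components; both are
tested, as is the end-to-end noiseless identity (simulate → fit →
extract reproduces the analytic ALPS to 10⁻⁶).

## Statistics

Group comparisons use the two-sided Mann–Whitney U test: exact
enumeration when n₁·n₂ ≤ 400 and the pooled sample is tie-free,
otherwise the normal approximation with midranks, tie correction and
continuity correction (either mode can be forced). The exact mode is
verified against a brute-force enumeration over rank assignments. The
normal approximation is loose at very small n: exhaustively over all
tie-free configurations with n₁, n₂ ≤ 6 the worst exact-vs-asymptotic
gap is 0.129 (n = 1, 3) and still 0.031 for n₁, n₂ ∈ 4..6 — at the
study's sizes (30 vs 25) the approximation is excellent and its null
rejection rate calibrates to 4–5% at nominal 5%. Sex uses Fisher's
exact test by default (a Mann–Whitney on 0/1 coding is available behind
a flag). Age–ALPS association uses Pearson r with p from the
t-distribution (n − 2 df) and R² = r². The Bonferroni family defaults
to {left ALPS, right ALPS, age}, giving the threshold 0.05/3 ≈ .017
stated by the study (which does not list its three comparisons; the
family is configurable). P-values render in clinical-table style
(".520", "<.001" below 0.0005).

## Validation design and what it shows

With no deposited MRI, the printed results act as recovery targets on
synthetic cohorts generated at the printed parameters:

- **Group means** — one full-imaging run of the 55-subject cohort at
  SNR 40; cohort means must land within 3·SD/√n of the printed means.
- **Group separation** — the full-imaging run separates groups at
  p < .001; at ground-truth level, note that the *replicate-rate* power
  of the left-index comparison is intrinsically ≈ 82% for p < .001
  (AUC = Φ(0.25/√(0.12² + 0.25²)) = 0.816 at n = 30 vs 25), so a
  published p < .001 on the left index is a realisation, not a
  near-certain outcome, at these parameters; the right index
  (AUC 0.893) reaches ≈ 99%.
- **Age correlation** — mean sample R² over 200 replicate cohorts per
  stratum matches each printed R² within 0.05; the small-sample
  inflation E[r²] ≈ ρ² + (1 − ρ²)²/n (≈ 0.01–0.02 here) is part of
  what "matches" means.
- **Null calibration** — identically generated ages reject at 5% ± 1.5%
  over 2000 replicates.

Passing these shows the measurement chain is unbiased and correctly
calibrated **under the phantom's assumptions**. It does not show the
ALPS index measures glymphatic function in real brains, nor that manual
ROI placement on real colour-FA maps would behave like centroid
placement on labelled phantoms — real data add anatomy, motion, eddy
currents, CSF contamination at b = 600, and reader variability that the
phantom deliberately omits.

## Problem sizes and determinism

Default validation sizes — one 55-subject imaging cohort, 100
ground-truth replicate cohorts for the group test, 200 per correlation
stratum, 2000 for null calibration — are the package's chosen balance
of statistical resolution against desk-scale runtime (the full suite
runs in a few minutes; the acceptance script in under a minute). All
randomness flows from explicit seeds; reruns are byte-identical on CSV
and JSON outputs (NIfTI files compare equal after decompression; the
gzip container embeds no timestamp under nibabel's writer, but byte
guarantees are only claimed for CSV/JSON).
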