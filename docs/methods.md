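# Methods

`tbikit` implements, on fully synthetic data, the analysis chain used to
evaluate quantitative diffusion-MRI markers of traumatic axonal injury in
a two-group rodent study (n = 5 sham, n = 5 injured): phantom simulation →
diffusion tensor estimation → scalar metric maps → voxelwise group
difference maps → per-region statistics with step-down multiple-comparison
correction → immunohistochemistry quantification → random-forest injury
classification. This note records the models, the defaults and their
rationale, and the places where a design choice was genuinely open.

## Signal model and acquisition scheme

Diffusion-weighted amplitudes follow the single-tensor Stejskal–Tanner
equation, S_i = S0·exp(−b_i·ĝ_iᵀ D ĝ_i), with D a symmetric 3×3 tensor in
mm²/s. The default protocol mirrors a high-field ex vivo acquisition: two
low-b shells (b = 250 and 500 s/mm²) with 6 directions each, two high-b
shells with 32 directions each, and one b = 0 volume (77 volumes). The
high shells are acquired in practice over ranges (≈1500–1700 and
≈3000–3800 s/mm²); we fix single representative values of 1500 and
3000 s/mm² — shell b-values are configurable, and nothing downstream
depends on the in-range variation. Direction sets are spherical Fibonacci
lattices: deterministic, quasi-uniform, and reproducible without a seed.
The b-matrix uses pure b·ĝĝᵀ terms; imaging-gradient cross terms require
pulse-timing information that a simulation has no reason to invent.

Magnitude noise is Rician, S̃ = √((S+ε₁)² + ε₂²) with ε ~ N(0, σ²) and
σ = S0/snr — the standard magnitude-MRI model. The default snr of 40
(referenced to S0) is a plausible value for high-field ex vivo imaging,
not an estimate of any particular scanner's output; it is a configurable
study condition, and all synthesized signals are non-negative by
construction.

## Phantom

The phantom stands in for a registered, distortion-corrected cohort:
19 labeled regions (bilateral brachium of the superior colliculus,
cingulum bundle, external/internal capsule, optic tract, cortex,
hippocampus, thalamus, plus anterior commissure and anterior/posterior
corpus callosum) laid out as rectangular blocks spanning five slices
(500 µm at 100 µm isotropic voxels). Geometry is deliberately schematic:
every downstream statistic consumes only label membership and tensor
values, never anatomy, so simplified topology changes nothing that is
tested. Registration and EPI-distortion correction are consequently out
of scope — phantoms share a grid by construction.

Baseline tensors are tissue-class constants. Fixed (ex vivo) tissue
diffuses more slowly than in vivo tissue, so both classes default to a
trace of ≈1.0×10⁻³ mm²/s: white matter is prolate with eigenvalues
(0.70, 0.15, 0.15)×10⁻³ (FA ≈ 0.75, principal axis along x), grey matter
near-isotropic at (0.36, 0.33, 0.31)×10⁻³ (FA ≈ 0.06). Injury is a map
(region, eigenvalue index) → multiplicative factor applied before tensor
reassembly; the default injury lowers λ1 by 20% and raises λ2, λ3 by 25%
in the optic tract and brachium bilaterally, reproducing the
reduced-FA/reduced-AD signature of axonal damage with gliosis.

## Tensor estimation

Fitting is two-stage and vectorised over voxels:

1. **Log-linear WLS** — ordinary least squares on log S against the
   design matrix [1, −b ĝĝᵀ…] with weights proportional to S (the
   delta-method standard deviation of log S), giving log S0 and the six
   tensor components in closed form.
2. **Nonlinear refinement** — unweighted least squares on the signal
   amplitudes, Gauss–Newton in (log S0, D) with step halving, converged
   when the relative cost change drops below 1e-10 (or the cost reaches
   numerical zero relative to the signal energy) within 200 iterations.
   Non-convergent voxels are flagged, never raised.

The nonlinear stage is unconstrained; negative eigenvalues are clamped to
1e-12 afterwards with a per-voxel flag, matching common practice and
keeping the estimator simple. Unweighted amplitude least squares was
chosen because the upstream tooling this emulates does not document its
weighting; this is recorded as the package's fixed choice. Background is
masked where the mean b=0 signal falls below 5% of its maximum
(configurable) — appropriate for phantoms whose background is exactly
zero.

## Scalar metrics

From sorted eigenvalues λ1 ≥ λ2 ≥ λ3: trace T = λ1+λ2+λ3, AD = λ1,
RD = (λ2+λ3)/2, and FA in its usual normalised-dispersion form. For the
Westin shape measures two normalisations circulate in the literature; both
are implemented and selectable:

* **trace convention (default):** WL = (λ1−λ2)/T, WP = 2(λ2−λ3)/T, which
  satisfies WL + WP + WS = 1 with WS = 3λ3/T — an identity the test suite
  checks to 1e-12;
* **lambda1 convention:** WL = (λ1−λ2)/λ1, WP = (λ2−λ3)/λ1.

The conventions agree on the prolate/oblate limits and differ on
intermediate shapes (e.g. eigenvalues (2,1,0): WL = 1/3 vs 1/2). The
trace-normalised form is the default because its sums-to-one identity
makes it testable and it matches the tensor-toolkit lineage this package
follows. Degenerate all-zero eigensystems yield zero metrics plus a flag.

## Group difference maps

Group comparison follows the FA-of-mean rule: tensors are averaged
component-wise (Euclidean mean) within each group, FA is computed on each
group's mean tensor, and the sham map is subtracted from the injured map.
FA-of-mean and mean-of-FA differ whenever groups are heterogeneous — a
regression test constructs orthogonal prolate tensors where the orderings
diverge sharply. Euclidean (not log-Euclidean) averaging is the default
to match the stated procedure literally; overlays render signed
differences with warm colours positive on a grayscale background, zero
transparent.

## Region statistics

Per-region means feed pooled-variance two-sample Student t tests
(df = n₁+n₂−2 = 8 for the reference cohort; pooled rather than Welch
because the reference tables print df = 8 throughout). Within each metric
or marker family (m = 19 regions), p-values receive the Holm-Šidák
step-down adjustment: with ordered p(1) ≤ … ≤ p(m), the i-th adjusted
value is max over j ≤ i of 1 − (1−p(j))^(m−j+1), clipped to 1. The
family-per-metric definition is confirmed by the worked reproduction:
feeding the published |t| values through this chain reproduces the
published adjusted p's (see below). Tests are two-sided; raw significance
is marked `#`, adjusted `*`, both at α = 0.05.

**Reproduction tolerance.** The published t statistics are printed
rounded to two decimals, so a correctly recomputed adjusted p can differ
from the printed one by a full unit in the last place (the worked example
includes one such case, where t = 4.42 adjusts to 0.0350 against a
printed 0.03). The reproduction checks therefore require agreement within
0.01 — one unit in the last printed digit — and require "<0.01" entries
to adjust below 0.01. The published MBP adjusted column is internally
inconsistent (a larger |t| receives a larger adjusted p within the same
family), most plausibly a typesetting error; MBP and the
never-significant APP column are excluded from reproduction checks.

## Immunohistochemistry quantification

Measurements follow bright-field DAB conventions (stained = dark) on
8-bit grayscale sections: percent area is the fraction of ROI pixels
below a per-marker intensity threshold (default 128 — "predetermined"
thresholds are not published, so the midpoint is used); optical density is
the ImageJ-style calibrated mean of log10(255/I) with I floored at 1, and
no background correction is applied. IBA-1, GFAP and APP use percent
area, MBP uses optical density; two serial sections are measured per
region and averaged, emulating a 500-µm imaging slab sampled at 300-µm
section spacing. The synthetic section generator places an exact count of
stained pixels (round(f·N)) in smoothed-noise blobs, so the
generate→measure round trip is exact by construction.

## Cohorts and effect-size calibration

Feature cohorts are Gaussian within group — matching the assumptions of
the downstream t tests — with one column per (region, metric) pair.
Effect sizes are calibrated from the published two-sample t statistics
via Cohen's d = t·√(1/n₁+1/n₂) = t·√0.4, giving d up to ≈3.1 for the
strongest white-matter effects. Note that the mean *observed* t over
repeated cohorts exceeds d/√0.4 by ≈11% at df = 8 (the noncentral-t mean
factor), which the calibration tests account for. "Strongly affected"
regions are defined as those whose calibrated d reaches 2.0 in any
metric: the bilateral brachium, optic tract and hippocampus — exactly the
regions the reference analysis flags.

What the generator does **not** emulate: spatial correlation between
neighbouring regions, metric-metric correlation within a sample,
non-Gaussian tails, partial-volume effects, or registration error.
Passing tests therefore demonstrate the correctness and calibration of
the analysis chain, not the biological validity of any particular effect
size on real tissue.

## Random-forest classification

A Breiman-style forest: each of 2000 trees (raised from the common
default of 500 so every feature of a 114-column table is considered many
times) grows unpruned on a bootstrap of n rows with replacement, with
Gini splits over m_try = floor(√F) randomly chosen features. Out-of-bag
(OOB) votes give per-sample predictions; classification error is
incorrect/total per class and overall. Feature importance is the mean
decrease in accuracy (MDA): per tree, the drop in OOB accuracy when one
feature's values are permuted among that tree's OOB rows, averaged over
trees, reported both raw and sd-normalised (mean divided by its standard
error across trees). Error bars come from n_repeats = 10 independent
forests. Region ranking scores each region by its best sd-normalised MDA
and lists as "associated metrics" the region's features within a
configurable fraction (default 0.5) of that maximum; ties break by region
name order.

**A caution on OOB at n = 10.** With five samples per class, OOB voting
is systematically pessimistic on uninformative data: the sample left out
of a bootstrap contributed no copies to it, so the opposite class is on
average over-represented and the vote skews against the sample's own
class. On pure-noise cohorts the mean OOB accuracy is therefore ≈0.2 —
not 0.5 — and the reference R implementation reproduces the same value
under identical conditions. This is a property of the estimator at small
n, not an implementation artifact; the test suite pins it, and OOB error
should be read comparatively (signal vs null), not as an absolute
accuracy estimate.

**Ranking reliability.** With ten samples and a hundred-odd features,
top-1 region identification from MDA is itself a noisy statistic: on
cohorts calibrated from the full published effect tables, the forest's
top-ranked region falls inside the strongly affected set (calibrated
d ≥ 2) in roughly 75–95% of repeated studies depending on the seed set,
and the reference R implementation behaves identically on the same
cohorts. Top-k lists should be read as candidates, not verdicts, at this
sample size.

The single-feature threshold classifier evaluates midpoints between
adjacent sorted values under both label orientations and returns the
minimising threshold (ties → smallest) with its misclassification count.

## Pipeline and reproducibility

One JSON config (unknown keys rejected) drives the six stages; a single
global seed deterministically derives per-stage 31-bit seeds through
`numpy.random.SeedSequence.spawn`, so one integer reproduces a study.
Every run writes a manifest with stage status, wall time, per-stage seeds
and SHA-256 hashes of all artifacts. Volumes are NIfTI-1 with
RAS-positive affines (voxel size in mm); tables are UTF-8 CSV; schemes
are a b-value/direction text pair plus combined JSON.

## Package shape

The pipeline stages are plain functions grouped by module; the one stage
with natural model/results semantics — tensor estimation — is also
exposed as `TensorModel.fit() → TensorFitResult` with a `summary()`, in
the style of statistical modelling packages. Simulation sizes used by the
test suite and the acceptance script (e.g. 1000-tensor recovery checks,
500-seed null calibration, 50-seed forest trials, 20-run ranking trials)
were chosen to give stable Monte-Carlo estimates at interactive runtimes.

## Known limitations

* Single-tensor model only: no crossing fibres, no non-Gaussian
  diffusion, no tractography.
* OOB error at n = 10 is biased (see above); the published classification
  error tables from the original animal cohort are data-bound and are not
  reproduction targets.
* The synthetic histology generator controls percent area exactly but
  models optical density only loosely (uniform intensity bands).
* Default diffusivities and snr are plausible ex vivo placeholders, not
  estimates fitted to any dataset.
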