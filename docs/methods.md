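# Methods

This note records the models implemented in `soycanopy`, the numerical
choices behind them, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Canopy-coverage model (`soycanopy.cc`)

Plot-level canopy coverage (fraction of ground covered in nadir view)
over days after emergence (DAE) is fitted per plot with the logistic
CC(t) = L/(1+e^(−k(t−t₀))) by bounded least squares (scipy `curve_fit`,
trust-region reflective). Bounds: L ∈ (0, 1.05] (a small allowance above
1 so an asymptote at full cover is not pinned to the boundary),
k ∈ (0, 2] per day, t₀ within the observed day range ± 30 d. The start
value for t₀ is the day where the observed series crosses half its
maximum. A series needs at least four distinct days and one coverage
value ≥ 0.2; flatter series carry no growth signal and raise a
degenerate-input error rather than returning a misleading fit.
Non-convergence returns a flagged fit, never silent NaNs. Coverage
inputs outside [0, 1] are clipped at ingest with a logged warning.

Derived quantities are computed on the fitted curve:

* **ACC** — time-average over a window, by the closed-form
  antiderivative (L/k)·ln(1+e^(k(t−t₀))). The default window is first
  to last measurement day; it is a parameter (`--window-start/-end`)
  because the choice of season window is a protocol decision, not a
  property of the fit.
* **CC50** = t₀ identically; **CCR2** = CC(t_R2) with the plot's R2
  date from the phenology table.
* **MCC_d** = 100·L·k/4 %/day (logistic derivative maximum, at t₀).
* **MCC_w** — maximum of 100·[CC(t+7) − CC(t)] over window start times
  on a 0.1 d grid, computed on the fitted curve (not raw data). For a
  logistic the maximizer is t₀ − 3.5, giving the closed form
  100·L·[σ(3.5k) − σ(−3.5k)] used as the test oracle.
* **rate profile** — raw between-date finite differences, %/day, used
  to localize rate changes relative to reproductive stages.

## Light-interception model (`soycanopy.li`)

Transmittance tPAR = TPAR/iPAR is clipped to [0, 1] (sensor readings
above incident light occur in sunflecks). Heights above the plot's
plant height are discarded, remaining heights are normalized by plant
height, and the profile is fitted with
T(h) = σ(k_li(h−h₀))/σ(k_li(1−h₀)). The denominator enforces full
transmittance at the canopy top exactly — the "zero absorbance at the
top" constraint is implemented as normalization rather than a penalty,
which removes a parameter and makes T(1) = 1 hold by construction.
Because absorbance is 1 − tPAR, fitting transmittance or absorbance is
the same least-squares problem under this normalization, so the
ambiguity between the two conventions is immaterial here.

A fit needs ≥ 4 points spanning ≥ 0.5 of normalized height. A profile
with no measurable attenuation (all tPAR > 0.98) short-circuits to the
k_li → 0 limit and is flagged "transparent canopy" (PARG = PAR50H = 1,
H50PAR undefined). Derived parameters: PARG = T(0), PAR50H = T(0.5),
and H50PAR from the closed-form inversion
h₀ + logit(0.5·σ(k_li(1−h₀)))/k_li, reported as NA when PARG > 0.5
(the canopy never blocks light down to 50%). Replicate profiles are
fitted individually; accession-level summaries come from the BLUP layer.

## Outline-shape model (`soycanopy.shape`)

Half-widths at nine relative heights (0 = ground, 1 = apex; the
measurement grid is uniform eighths of plant height) are fitted with the
mode-normalized beta pdf w(x) = Sh_W·f(x;α,β)/f(m;α,β),
m = (α−1)/(α+β−2), by bounded nonlinear least squares over
(Sh_W, α, β), α, β ∈ (1, 60]. The mode-normalized convention makes
Sh_W literally the maximum half-width in metres; the alternative
raw-amplitude convention (amplitude multiplying the unnormalized pdf)
equals Sh_A = Sh_W/f(m;α,β) and is exposed for conversion. α, β > 1 is
required: it guarantees zero width at ground and apex with one interior
widest point, which is the geometry being modelled.

Initialization is method-of-moments, treating the profile as a discrete
density; three fixed extra starts (symmetric, top-heavy, bottom-heavy)
guard against local minima, with ties broken by lowest residual RMS then
lowest α. The beta pdf is evaluated in log space (`xlogy`/`xlog1py` and
`betaln`), which is endpoint-safe and several times faster than the
generic distribution machinery over thousands of plant fits. Full-width
inputs are halved at ingest via a dedicated constructor. Scale
equivariance (widths × c ⇒ Sh_W, Sh_A × c with α, β, Sh_H unchanged)
and reflection symmetry (x → 1−x swaps α ↔ β) are enforced by property
tests.

## Assimilation simulation (`soycanopy.assim`)

A metre of row is idealized as a prism whose cross-section is the
outline, illuminated from straight overhead at midday. Only the outline
segment above the widest point faces upward; its horizontal projection
between heights x and x+dx is −dw, on each of the two row faces.
Within-canopy PAR at relative height x is I₀·T(x) with each accession's
own transmittance fit; leaf response is the non-rectangular hyperbola
A(I) = [φI+A_max − √((φI+A_max)² − 4θφI·A_max)]/(2θ) − R_d.

A_row(I₀) = 2·∫_{Sh_H}^{1} A(I₀T(x))·(−dw/dx) dx is evaluated as a
Riemann–Stieltjes sum in w over ≥ 400 height panels (default 800), with
the light response at panel midpoints. Summing against the exact width
increments telescopes, so a transparent canopy reproduces the closed
form 2·Sh_W·A(I₀) to machine precision regardless of panel count, and
the β < 2 endpoint (where dw/dx is unbounded but integrable) needs no
special handling. All geometric assumptions live in one function
(`row_assimilation`) so a different reading of the illuminated surface
can be swapped in.

Default light-response parameters (φ = 0.05 mol mol⁻¹, A_max = 25,
θ = 0.7, R_d = 1 µmol m⁻² s⁻¹) are implementation defaults in the
typical range for field soybean leaves, configurable via
`--lrc-config`; the panel statistics of interest (deviations from the
panel mean, their PAR slopes, and correlations with Sh_W/Sh_H at
PAR = 250, 450, 900, 1800) are insensitive to the absolute curve level
by construction (deviation from the mean removes any common shift).
Curves are evaluated on a 0–1800 µmol m⁻² s⁻¹ grid at step 10; slopes
are central finite differences on that grid (one-sided and flagged at
the boundary).

## Architecture traits (`soycanopy.traits`)

Nodes are indexed from the top (node 1 = uppermost). PS4/IS4 are OLS
slopes of the top-four petiole/internode lengths on node index; CH is
the sum of the top six internode lengths; leaf traits are leaflet means;
BZ is the insertion height of the highest branch ("most distal along the
stem" is the reading adopted for "last branch initiated"); BD = BN/BZ;
BR = BZ/PH, guaranteed in [0, 1] because branch insertions above the
plant height are rejected at ingest. A branchless plant gets BZ = 0,
BR = 0 and BD = NA, flagged. Branch orientation (BO) has no geometric
definition beyond an angle; it is carried as a passthrough numeric
trait. Plot values are per-trait means over plants, excluding plants
missing that trait (counts logged).

## Mixed-model layer (`soycanopy.genostats`)

The all-random model y = µ + G + Y + B(Y) + G×Y + ε is estimated by
REML on the observed cells (missing plots simply drop out of the
restricted likelihood). The implementation is direct: the covariance
V = Σ σ²_c Z_c Z_cᵀ + σ²_ε I is assembled dense (a two-year, 40 × 6-plot
trial is 240 × 240), profiled over the intercept, and the REML deviance
is minimized by L-BFGS-B over the component *standard deviations*, which
enforces non-negativity by construction (objective tolerance 1e-12,
responses standardized internally for conditioning). BLUPs are
û_G = σ̂²_G Z_Gᵀ V̂⁻¹(y − Xβ̂). Terms that are structurally confounded
are detected and pinned to zero with a flag: year and G×Y in a
single-year table, block-in-year when there is one block per year. A
`components` argument restricts the model (e.g. genotype-only for the
balanced one-way case, where REML is verified against the
method-of-moments ANOVA closed form to 1e-4 relative).

Reliability i²_ACC = σ²_G/(σ²_G + σ²_ε/r) is reported per year with
r = that year's replicate count, and pooled as the mean of the per-year
values, since single per-trait values are often quoted even though the
definition is per-year.

Correlation matrices (Pearson with t-distribution p-values, Spearman)
use pairwise-complete observations; Benjamini–Hochberg adjustment (the
standard choice where only "FDR adjusted" is specified) runs over the
upper-triangle tests via statsmodels. The heatmap matrix tests each
trait against the anchor (ACC by default), BH-adjusts that family,
keeps traits with adjusted p < α, Z-scores the retained columns
(ddof = 1, matching R's `scale`), orders columns by |r| with the anchor
(anchor first) and rows by anchor BLUP descending.

## Synthetic trial generator (`soycanopy.synthetic`)

The generator emulates the study conditions: 40 accessions, years 2018
(4 blocks) and 2019 (2 blocks), twelve coverage flights (DAE 10–76,
every 6 days), 0.1 m PAR transects, width profiles at the nine relative
heights, six plants per plot, and phenology stages R1–R5 around
(36, 44, 51, 59, 67) DAE with accession-level shifts (SD 2 d) and plot
noise (SD 1 d). Every latent trait — the logistic CC triple, the
transmittance pair, the outline parameters (α, β via log(α−1), so
α, β > 1 always), and each architecture trait — receives its own
additive decomposition genotype + year + block(year) + G×Y + plot
residual, with default component magnitudes chosen to give genotypic
coefficients of variation near 10% and reliabilities in the 0.6–0.95
range typical of replicated agronomic trials. Observation noise is
layer-specific: Gaussian SD 0.02 on coverage fractions (clipped to
[0, 1]), Gaussian SD 0.02 on transmittance (clipped), 5% multiplicative
on outline widths (floored at 0), and 3% within-plot variation on plant
measurements. Structural traits are generated consistently rather than
independently: internode/petiole lengths follow the plot's
length-at-node-4 and slope latents (so refitting recovers PS4/IS4
exactly), CH = 6·IL4 − 3·IS4 follows from that linearity, the highest
branch sits exactly at the branching-zone latent, and BD/BR are derived.

All randomness flows from one seed through spawned child streams, so a
seed reproduces the dataset byte-for-byte; truth (accession values,
variance components, noise levels) is emitted alongside the data
(`truth.json`). What the generator does **not** emulate: spatial field
trend, weather, lodging, phenology–growth feedback, image-segmentation
error, or any non-Gaussian measurement pathology. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated stochastic model, not robustness to field artifacts.

## Problem sizes and verification budget

The test suite verifies closed forms exactly; noisy recovery uses 100
seeds per setting (median |t̂₀ − t₀| ≤ 1 d at coverage noise 0.02 over
12 flights; median |Ŝh_H − Sh_H| ≤ 0.05 at 5% width noise); REML
recovery uses 200 simulated trials at the full design, with means of the
well-replicated components (genotype, G×Y, residual) required within 5%
of truth, and the 1-df year and 4-df block components — whose single-
trial estimates are dominated by sampling variance — checked against
truth within three Monte-Carlo standard errors of the simulation mean.
BH false-positive control under the global null uses 1000 replicate
panels. The acceptance script repeats these computations from scratch
plus one full 40-accession pipeline run; end to end it takes roughly
one to two minutes on a single CPU.

## Known limitations

* The assimilation model ignores leaf nitrogen and temperature
  responses, diffuse light, solar angle (midday, straight-down light is
  assumed), and canopy energy balance; it ranks architectures under a
  fixed physiological curve rather than predicting absolute carbon gain.
* ACC depends on the averaging window; comparisons across datasets must
  hold the window fixed.
* The LI fit assumes a monotone transmittance profile; inversion layers
  (brighter mid-canopy than top) are fitted poorly and show up as low
  adjusted R².
* REML standard errors of the 1-df year component are enormous by
  design; per-year reliabilities inherit uncertainty from σ²_G and σ²_ε
  and should be read as descriptive, not inferential.
* The generator's Gaussian noise models are convenient fictions; real
  coverage fractions near 0 or 1 have asymmetric error, and branch
  counts are small integers, not rounded Gaussians.
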