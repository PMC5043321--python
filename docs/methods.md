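# Methods

This note documents the models implemented in `rnlcolour`, the choices made
where the design was genuinely open, and what the synthetic experiment does
and does not establish.

## The receptor-noise-limited (RNL) model

Colour discrimination in a tetrachromatic eye is modelled as limited only by
noise in the four single-cone channels (UVS, SWS, MWS, LWS). The chain from
a stimulus spectrum to a colour distance is:

1. **Cone sensitivity.** R_i(λ) = r_i(λ)·p_i(λ)·o(λ): pigment absorbance ×
   oil-droplet transmittance × ocular-media transmittance. Self-screening of
   the pigment is neglected, so the sensitivity is exactly this product.
   Pigment absorbance uses the Govardovskii A1 template (α-band rational
   exponential plus Gaussian β-band), peak-normalised. Oil droplets use a
   Gompertz-type exponential cut-off T(λ) = exp(−exp(−s(λ−λ_cut))); UVS
   droplets are transparent (identity filter). Tabulated sensitivities can
   be supplied instead of either model form, so template risk is bypassable.
2. **Quantum catch.** Q_i = k_i ∫₃₀₀⁷⁰⁰ R_i(λ)L(λ)dλ, with L in quantum
   units (photon flux). All integrals in the package are trapezoid sums;
   the canonical grid is 300–700 nm at 1 nm, and cross-spectrum operations
   resample both operands to the coarser common grid first.
3. **von Kries adaptation.** k_i = 1/∫R_i(λ)L_b(λ)dλ for the adapting
   background L_b, so the background itself has unit catch in every
   channel. Adaptation makes chromatic outputs invariant to any
   per-receptor scaling of R_i — which is why peak- vs area-normalisation
   of sensitivities is immaterial (verified by test).
4. **Receptor contrast.** Δf_i = ln(Q_{i,1}/Q_{i,2}) between two adapted
   stimuli.
5. **Channel noise.** ω_i = v/√η_i, where v is the single-cone
   noise-to-signal ratio and η_i the relative cone abundance
   (default ratio UVS:SWS:MWS:LWS = 1:1.5:2:3). v is anchored by the
   stated LWS Weber fraction (default ω_LWS = 0.1), giving
   ω = (0.173, 0.141, 0.122, 0.100). The √η pooling is the convention of
   the RNL literature; a `linear` switch (ω_i = v/η_i) is provided because
   the pooling law is typeset ambiguously in parts of the literature.
6. **Colour distance.** ΔS is the tetrachromatic closed form over the six
   receptor pairs; it is algebraically identical to
   min_c Σ_i (Δf_i − c)²/ω_i² — the best-fitting uniform (intensity) shift
   is discounted and the residual chromatic difference is weighted by
   channel reliability. ΔS is in JND units: 1 JND is the model's
   discrimination threshold. Pure intensity changes give ΔS = 0 exactly;
   achromatic contrast is handled separately as the double-cone Michelson
   contrast (Q_max−Q_min)/(Q_max+Q_min).

Degenerate inputs raise rather than being silently floored: a background
with zero catch in any receptor (adaptation undefined) and zero catches in
a log contrast are errors. Near-zero UVS catches — typical for RGB-monitor
stimuli — are allowed as long as strictly positive.

## Psychometric model and threshold criterion

Two-alternative choice data are modelled per stimulus level x as binomial
with success probability

ψ(x) = γ + (1 − γ − λ)/(1 + exp((a − x)/b)),

γ = 0.5 (chance for two alternatives, fixed), lapse rate λ ∈ [0, 0.25],
position a and steepness b > 0 free. Note the exponent is (a − x)/b — the
form is sometimes typeset without the parenthesis, but a as position and b
as steepness requires this reading. (a, b, λ) are estimated by maximising
the binomial log-likelihood with L-BFGS-B from a 5×5 multi-start grid
(a across the level range, b over a decade around the level spacing,
λ started at 0.02). Multi-start guards against the flat-likelihood
plateaus produced by near-chance data. A fit is reported `converged` only
if it also beats the best flat (constant-probability) model; chance-level
data therefore yield `converged=false` rather than an arbitrary threshold.
If only the single highest level is above chance the fit carries a
`ceiling` flag and the pipeline reports the highest tested level as the
threshold, flagged as such.

The threshold is the criterion crossing
x* = a − b·ln((1−γ−λ)/(c−γ) − 1). The criterion c is, by default, derived
from the design: the smallest correct-choice proportion significantly above
chance in a one-tailed binomial test (α = 0.05) at the session's
trials-per-level — 20/30 = 66.7% for 30 trials. Fits can extrapolate x*
below the lowest tested level (or below zero contrast); downstream analyses
floor such estimates at zero.

Group comparisons use the two-sided Wilcoxon rank-sum test, computed by
exact enumeration of all rank assignments (midranks for ties) for combined
n ≤ 12 and by the tie-corrected normal approximation above that.

## Threshold vs background contrast

Each condition's background contrast is the ΔS between the rewarded
stimulus and the background, adapted to that background. Over modest to
strong background contrasts, discrimination thresholds follow

threshold = intercept + slope · background_contrast,

fitted by ordinary least squares with the two-sided Pearson correlation
test as the significance diagnostic. Detection conditions (stimulus
appearing at the background chromaticity) sit at zero background contrast
by convention and are excluded from the line: at small pedestal contrasts
thresholds dip below the detection threshold (the "dipper"), a regime the
line does not describe. `predict_threshold` therefore clamps predictions
at the 1-JND floor of the RNL model instead of modelling the dip, and
`dipper_summary` reports the detection/discrimination comparison
descriptively (ratio and dip presence).

## The synthetic experiment

The generator replaces the live-animal experiment while preserving its
design quantitatively:

- **Monitor.** Stimuli are sums of three Gaussian primaries (peaks
  450/550/610 nm, σ 30–35 nm — an arbitrary but plausible RGB gamut;
  real display spectra can be substituted as CSVs).
- **Stimuli.** A grey→red saturation series is solved (bracketed root
  finding on the convex mixing weight) so the six discs sit at 0.1, 0.6,
  2.1, 3.7, 5.2 and 6.9 JND from the rewarded red disc under grey-background
  adaptation; all discs are rescaled to equal double-cone catch, so
  achromatic cues are absent (pairwise Michelson ≈ 0, well under a 4%
  balance criterion). A separate detection ladder spans 1.0–6.8 JND from
  the grey background.
- **Conditions.** Five backgrounds — medium red, yellow, grey, bright grey
  (same chromaticity as grey, higher intensity) and green — whose contrasts
  against the rewarded disc are ordered medium red < yellow < grey < green
  (1.7, 3.6, 7.2, 8.3 JND with the shipped visual system), plus one
  detection condition at zero background contrast.
- **Observers.** Simulated observers have true thresholds generated by a
  clamped line with slope 0.26 and intercept 0.6 JND over background
  contrast, and a detection threshold of 2.8 JND (inside the 2.5–3.2 JND
  band typical of chromatic detection under adaptation). Psychometric
  curves use b = 0.8, λ = 0.05, γ = 0.5, positioned so the 66.7% crossing
  equals the intended threshold; choices are binomial draws, 30 per level.
- **Schedules.** Rewarded-side sequences are balanced random deals with no
  more than four consecutive same-side rewards (dead ends restart the
  deal) — behaviourally equivalent to constrained pseudo-random series
  used in choice experiments.

Everything is seed-deterministic; regenerating with the same seed
byte-reproduces the fixture set.

What the synthetic study does **not** emulate: learning and motivation
dynamics, sequential dependencies between trials (each choice is an
independent Bernoulli draw), inter-subject variability in visual systems,
stray light and display artefacts, and any achromatic residue of real
stimulus rendering. Passing tests therefore demonstrate that the analysis
machinery recovers known generating parameters under the stated design —
not that any particular animal behaves this way.

## Problem sizes and numerics

The packaged analyses use 5 replicate subjects × 6 conditions × 6 levels ×
30 trials, 200 simulated observers for threshold-recovery calibration, and
10⁴ random draws for the closed-form/minimisation identity check; these
sizes give stable medians while keeping any run to tens of seconds.
Root finding for the stimulus ladder uses Brent's method to 1e-10 on the
mixing weight; the ΔS identity holds to ~1e-13; OLS and rank statistics
come from scipy. Ties in the exact rank-sum are handled with midranks,
which makes identical groups return p = 1 exactly.

## Known limitations

- The linear background-contrast correction is an empirical description
  over the measured range; extrapolating far beyond ~13 JND of background
  contrast is unvalidated.
- The dip region (0 < background contrast < 1-JND crossing) is clamped,
  not modelled; mechanistic dipper models (gain control) are out of scope.
- The example visual-system config ships representative passerine
  parameter values for out-of-the-box runs; quantitative work on real
  spectra should substitute measured sensitivities via `table:` entries.
- Thresholds are fitted per condition independently; no mixed-effects
  pooling across subjects is attempted.
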