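# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data machinery does and does not
establish.

## Encoding

Surface slant lives on [−90°, 90°]. Each cue (binocular disparity δ,
texture χ) is encoded by *n* = 37 units whose preferences tile that range
evenly; *n* is odd so that 0° (frontoparallel) is a preference. Tuning is
von Mises on the doubled angle,

    f(θ) = A · rate_scale · exp(k [cos 2(θ − θ_pref) − 1]),

peak-normalized so the best-matched unit fires at `A·rate_scale` spikes per
interval. Doubling maps the slant range onto one full cycle, which makes
the tuning periodic — ±90° are identified, as they are for a slanted plane
— and matches the cos 4j period of the readout. Mean rates scale exactly
linearly with cue intensity *A*; an absent cue is *A* = 0.

**k (default 11.5).** The concentration sets the tuning bandwidth;
the default gives a half-width at half-height of ~10°. Bandwidth is
mechanism-relevant: it decides at what conflict the two cues' activity
ridges begin to interact through the readout's suppressive lobes. Much
broader tuning (k ≈ 2) merges the ridges so thoroughly that suppression
can only subtract signal, and the robustness phenomenology degrades.

**rate_scale (default 30).** One calibration constant, fixed so that
single-cue intensities A = 1 vs 8 produce a ~1:3 sensitivity ratio (the
structural ceiling is √8 ≈ 2.83) and A = 4 produces ~1:2 with no refit.
Both ratios follow from Fisher scaling — estimator variance inversely
proportional to the Poisson gain — so the calibration mainly ensures the
noise regime is neither saturated nor degenerate.

**n_trials (default 100).** Poisson repetitions per condition; ~100
repeats mirrors the scale of one behavioural session.

## Combination and readout

Combination units pool every (δ-preference, χ-preference) pair:
E = sqrt(f_δ + f_χ), a monotone, sublinear summation. Diagonal cells are
congruent units; the majority are incongruent "what not" units that respond
best when the cues disagree.

The output layer sums the grid along anti-diagonals with weights
cos(4j) − c over offsets |j| ≤ π/4 in grid steps (period 90°: the weight is
positive for cue separations below 45°, negative beyond). c = 0.05 is the
tonic-inhibition offset. Indices wrap circularly, consistent with the
periodic tuning; without wrap-around, truncating the suppressive lobes at
the range ends produces spurious near-edge output peaks as tall as the true
peak. Three multiplicative factors act on the weights: β ∈ [0, 1] on the
negative part (the suppressive gain — the GABA analogue), and
`pos_scale`/`neg_scale` on the positive/negative parts (the tDCS handles).

## Decoding and sensitivity

Per trial: unimodal Poisson draws → combination → readout → rectify at
zero. Two position readings are exposed:

* `slant_hat` — the argmax of the rectified profile (the peak, with its
  height as the reliability proxy);
* `slant_centroid` — the profile's centre of mass, used for bias, cue
  weight and trial-to-trial sensitivity, because the argmax on a 5° grid
  quantizes bias into grid steps while the centroid varies smoothly.

**Sensitivity** is the inverse standard deviation of the centroid estimate
across Poisson trials — the quantity 2IFC discrimination measures, via
s = σ⁻¹/√2. Reliability ratios between conditions use mean peak heights
(e.g., the √2 congruent-fusion benefit is exact in that metric by the
sublinearity of E). Bias is the signed offset of the mean estimate from
the more reliable cue's slant (positive toward the less reliable cue), and
the reliable-cue weight is w = 1 − |bias|/|S_rel − S_unrel|, clipped to
[0, 1]. Bimodality is flagged when the rectified profile has two
disconnected regions above 70% of the peak; decoded peaks in the outer two
grid points carry an edge flag. A noise-free path (exact rates, no Poisson)
exists for symmetry and oracle tests.

Known behaviour of these choices: the centroid is not an efficient
estimator, so sensitivity ratios can deviate a few percent from ideal-
observer predictions; the quadratic-sum ceiling for congruent cues holds to
~1% at the default noise level. At cue separations beyond the ±45° readout
window the ridges no longer interact, so reversion weakens again at extreme
conflicts (> ~55°); standard sweeps stay within 0–50°.

## Suppression sweep

Per simulated individual: β ~ N(0.75, 0.1) clipped to [0, 1], intensities
jittered N(A, 0.1) clipped at 0, conditions single-disparity (A = 1, 20°),
single-texture (A = 1, 50°), congruent (1, 1 at 40°) and incongruent
(1, 4 at 20°/50°). Reported sensitivities are normalized to the sweep-mean
disparity-single sensitivity (Pearson correlations are invariant to that
constant; per-individual normalization by a noisy single-cue measurement
would only inject the reference's noise into every ratio). Correlation
p-values come from the t distribution on n − 2 df.

In this implementation the β → reliable-cue-weight relation is positive
(more suppression pins the conflicted estimate to the reliable cue) but
the β → incongruent-sensitivity relation is weak: suppression removes
total signal along with the implausible interpretations, and at the
behavioural 30° conflict the net effect on estimator dispersion is nearly
flat. The examples print both honestly. Stronger positive couplings were
not achievable without breaking the intensity calibration or the
quadratic-sum ceiling, and this trade-off is a genuine property of the
architecture as specified here.

## Latent cue and the tDCS protocol

Measured congruent sensitivity can exceed the quadratic sum of measured
singles when "single-cue" stimuli carry residual information in the other
modality. The latent cue is modelled as a frontoparallel (0°) cue of
intensity a added to the nominally absent modality: being *conflicting*, it
degrades single-cue sensitivity, which is the direction required (a
congruent latent would improve it). a is fitted by bounded 1-D search so
the model's congruent:single sensitivity ratios match the observed ones.

tDCS is simulated in two stages: (1) with the latent cue frozen,
(p_pos, p_neg) ∈ [0, 1]² are fitted by least squares on
sensitivity-relative-to-sham over the single- and congruent-cue conditions
(41×41 grid then Nelder–Mead, common random numbers throughout, plus a
10⁻⁶ pull toward (1, 1) that resolves exact ridges deterministically);
(2) the frozen factors predict the held-out incongruent condition. Under
uniform scaling the centroid decode is exactly gain-invariant, so only the
positive/negative *balance* carries the fit; the model expresses the
observed pattern (combined-cue conditions lose sensitivity, singles stay
near sham) only partially, since balance shifts also touch the
latent-loaded singles.

## Rivalry dynamics

Output units obey

    τ dX_i/dt = F_i − (1 + A_i) X_i + W(0, σ) − γ Σ_j S[X_j] K_ij
    τ_A dA_i/dt = −A_i + α S[X_i]

with τ = 1, τ_A = 125, γ = α = 7, σ = 0.005, Euler–Maruyama integration at
dt = 0.05 τ (halving dt leaves dominance statistics unchanged). The lateral
kernel is K_ij = [−cos 2(θ_j − θ_i)]₊: rectified, zero between similar
slants, maximal between maximally different ones. S is a Naka–Rushton
sigmoid with exponent 2 and half-saturation at 50% of the drive peak. The
drive F is the rectified noise-free readout normalized to a peak of
`drive_gain` = 8 activity units: this one constant sets the drive :
inhibition balance, and is calibrated so that the default γ, α, τ_A produce
sustained alternation for equally reliable conflicting cues (the stated
calibration criterion); the sigmoid constants and the activity scale are
not independently identified by anything else.

Dominance is assigned when one percept's peak activity exceeds the other's
by a factor 1.5, with episodes shorter than 1 τ debounced. The bistability
index is the angular separation of the two percepts' slants — zero under
fusion (unimodal drive) and growing with conflict once the readout goes
bimodal; for conflict sweeps a static variant reads it directly off the
drive profile.

## Psychophysics and statistics

Psychometric family: cumulative Gaussian with lapse bounded at 0.1, 2IFC
chose-test parameterization P = λ/2 + (1 − λ)Φ((x − PSE)/σ); maximum
likelihood via L-BFGS-B with multiple slope initializations. The j.n.d. is
the 50→84% level difference (one σ); sensitivity is its reciprocal. Fits
whose slope exceeds five times the tested level span are rejected as
degenerate; slopes at the floor are flagged, not rejected. The 2IFC
simulator draws Bernoulli responses with P = Φ((test − ref)/(σ_int √2)),
so the √2 of the sensitivity conversion emerges from the task structure
rather than being inserted.

The JZS Bayes factor is computed by direct quadrature of the Zellner–Siow
integrand (prior scale 0.707). The robust correlation rejects bivariate
outliers by the boxplot rule — outside the 1.5·IQR fences on either
variable's projection — then reports Pearson r, its t-based p and a seeded
bootstrap percentile CI; the exact multivariate variant used by published
toolboxes differs in detail, and no result here depends on the choice.
The log-space 3-SD screen and the quadratic-sum cap are single-pass
operations; both are idempotent on the data patterns they are meant for.
The tissue correction C/(f_GM + f_WM) is included as a small utility.

## Synthetic cohort

Each synthetic observer has β ~ N(0.75, 0.1) clipped to [0, 1] and a
"measured" trait 1 + 2β + N(0, 0.05) (slope and intercept arbitrary:
correlations are scale-free). The observer's true per-condition sensitivity
is characterized precisely (≥ 500 Poisson repeats — measurement noise
belongs to the 2IFC stage, not to the latent trait), mapped to a
behavioural scale on which congruent sensitivity is 0.35 deg⁻¹, and used as
the internal SD of the standard 2IFC observer over the constant-stimulus
level grids. What passing recovery tests show: the pipeline (simulation →
psychometric fitting → robust correlation) recovers the generative
trait–incongruent link and finds no positive congruent link. What they do
not show: anything about real observers — the cohort inherits every
idealization of the model, including Gaussian internal noise, stationary
lapse-free behaviour and the weak β → sensitivity coupling noted above,
which caps the recovered correlations well below 1.

## Limitations

* Slant only; no tilt dimension, no stimulus rendering.
* The β → incongruent-sensitivity coupling is weak and non-monotone in
  this reading of the architecture (see the suppression-sweep section);
  conclusions that depend on its magnitude should be drawn cautiously.
* The normalization comparator is deliberately minimal — congruent-only
  pooling with divisive normalization — and is used only to illustrate the
  absence of reversion, never for quantitative claims.
* Rivalry parameters beyond (τ, τ_A, γ, α, σ) are calibrated, not fitted;
  dominance-duration distributions are not matched to human data.
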