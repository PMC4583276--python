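# Methods

## The model

The multi-component information accumulation (McIA) model describes
two-alternative perceptual categorization — here, deciding which of two
family patriarchs ("A"/"B", displayed as Jones/Smith) a morphed test face
resembles — as a biased random walk between two absorbing response
thresholds at ±θ, starting midway. On each step one evidence source is
sampled:

- the **top half face** alone, with probability (1 − α)/2,
- the **bottom half face** alone, with probability (1 − α)/2,
- the **automatically integrated whole face**, with probability α.

A sampled source moves the walk one step toward the correct threshold with
its step probability δ, else one step away. Half-face sources carry
δ_weak, δ_medium, or δ_strong according to the calibrated evidence strength
of that half; the whole-face source combines the two half probabilities
optimally by multiplying their odds:

    odds(δ_whole) = odds(δ_top) · odds(δ_bottom),   odds(p) = p / (1 − p).

The odds product dominates either source alone whenever both exceed chance,
whereas sampling halves in alternation averages them, pulling performance
below the stronger half. The model therefore produces additive integration
when whole-face sampling is available and dilution when it is not; the
attention parameter α is the single lever that moves it between those
regimes.

Because the evidence source is redrawn independently on every step, the
walk is a simple random walk at the marginal step probability
p = α·δ_whole + (1 − α)/2·(δ_top + δ_bottom), and the classical
gambler's-ruin closed forms apply exactly: with r = (1 − p)/p,

    P(correct) = 1 / (1 + r^θ),
    E[N]       = (θ − 2θ·P(correct)) / (1 − 2p),   E[N] = θ² at p = ½.

Decision steps translate to milliseconds as RT = τ + k·N for whole faces
and RT = τ + h·k·N for half faces (comparing a lone half against
whole-face targets carries a per-step surcharge h).

For **opposite (wom) faces** — a medium half of one family paired with a
weak half of the other — the correct response is defined by the stronger
(medium) evidence, and the opposing weak half contributes 1 − δ_weak toward
the correct response, by the symmetry of binary evidence. This convention
is an interpretation (the construction of the opposite-face evidence is
genuinely open); it makes opposite-face accuracy land above chance but
below the medium half face, as the manipulation check requires.

## Parameters

| parameter | units | default | meaning |
| --- | --- | --- | --- |
| θ | steps | 6.76 | response threshold; distance from start to either boundary |
| α | — | 0.30 | probability of sampling the whole-face source (together faces) |
| δ_weak | — | 0.54 | step probability toward correct, weak evidence |
| δ_medium | — | 0.56 | as above, medium evidence |
| δ_strong | — | 0.64 | as above, strong evidence |
| τ | ms | 359 | non-decision time |
| k | ms | 20 | time per step |
| h | — | 1.24 | half-face multiplier on step time |

The defaults are a reference configuration typical of the face-dilution
task and are also the generating values for the synthetic experiment.
Non-integer θ is evaluated directly in the closed forms with real-valued
exponents, as is standard for random-walk decision models; Monte-Carlo
equivalence is exact only at integer θ because the ±1 walk absorbs at
integer positions (a walk launched with θ = 6.76 behaves as θ = 7).

## Model variants

- **full** — α free for together faces, fixed at 0 for split faces
  (splitting is assumed to abolish automatic integration).
- **alpha_one** — α = 1 everywhere: always integrate optimally.
- **alpha_zero** — α = 0 everywhere: always alternate between halves.
- **alpha_split_free** — separate free α for together and split faces.
- **rate_attenuation** — α = 1 everywhere, but the split-face δs are
  multiplied by a free attenuation γ ∈ (0, 1].

Sign structure: under alpha_one every same-family whole-face deviation
score is non-negative (the odds product dominates the max); under
alpha_zero every deviation is non-positive (an average never beats the
max). The wom cells are the exception under alpha_one: the opposing half's
effective contribution 1 − δ_weak lies below ½, so the odds product falls
below δ_medium and the predicted wom deviation is necessarily negative.
The non-negativity claim is therefore asserted over the 12 same-family
cells only.

## Stimulus design and calibration

Morph levels are percent of the own-family target in the pixelwise linear
morph w·A + (1 − w)·B, kept as floats in [50, 100]. Each participant's
medium level per (half × family) comes from an 18-trial 2-up-1-down
staircase (step 5.6 points, bounds 50/100, start 94); weak and strong are
interpolated as weak = (medium + 50)/2 and
strong = medium + ⅔(100 − medium). The staircase's consecutive-correct
counter resets after every decrement and after any error (the standard
transformed-staircase convention), and decrements are clamped after
subtraction. The equilibrium of the 2-up-1-down rule is the level where
P(correct)² = ½, i.e. ≈ 70.7% correct; `converged_accuracy` estimates it by
averaging the level over the post-burn-in half of a 20 000-trial run (long
enough to hold the seed-to-seed spread of the estimate near 0.4 points) and
evaluating the observer there.

The synthetic observer is a logistic in morph percent rescaled so that
P(50) = 0.5 exactly (chance at the fully ambiguous morph) and
P(midpoint) = 0.75, with a lapse parameter capping asymptotic accuracy.
The four staircases per participant are run independently; the whole-face
filler trials interleaved in the real procedure do not influence the
staircases and are not simulated.

One block enumerates 56 test faces — 12 half (3 strengths × 2 locations ×
2 families), 36 whole (3 × 3 strengths × 2 families × together/split) and
8 opposite (medium-vs-weak across families, 2 top strengths × 2 top
families × formats) — plus a second appearance of each equal-strength
whole face (12 more), giving 68 trials, shuffled per block with a seed
derived from (experiment seed, participant, block). Screen positions are
drawn from the 3 × 3 offset grid {−100, 0, +100}² and carried through the
I/O schema but play no role in the model.

## Synthetic experiment

`simulate_experiment` runs, per participant: calibration → level
derivation → four shuffled blocks → walk-generated choices and RTs.
Defaults are 19 participants × 4 blocks (5168 trials). Contaminant trials
are planted at rates 4.0% fast guesses (RT uniform below 150 ms), 6.4%
slow outliers (RT uniform in 5–8 s) and 2.6% guess-confidence ratings
(confidence set to 50), ≈13% in total, chosen so the confidence-50 share
sits near the ~2.5% typical of this paradigm; ground truth records every
planted trial. The filters (confidence = 50, RT < 150 ms, RT > 5 s; both
RT bounds strict) recover the planted fraction plus a small (~0.3%)
natural tail of walk RTs that legitimately exceed 5 s.

Demo datasets add small between-participant parameter jitter (lognormal
on θ and k, logit-normal on α and the δs) so between-subject SEMs are
realistic. Confidence ratings are a placeholder drawn from a noisy map
decreasing in the number of steps — the walk model does not define
confidence — and exist only to exercise the confidence filter and the
schema.

What the generator does *not* emulate: real face images and their
rendering, presentation/masking timing, sequential effects, confidence as
a cognitive quantity, and upside-down blocks. Passing tests therefore
certify the pipeline and the model's internal consistency, not the
behavior of human observers.

## Behavioral pipeline

Accuracy is coded against the face's correct family (the stronger half's
family for opposite faces). The deviation score of a whole-face trial is
its 0/1 accuracy minus the participant's mean accuracy on the stronger of
its two halves alone, where "stronger" is the half whose matching
half-face cell (location × strength, collapsed over family, computed after
filtering) has the higher empirical mean; exact ties fall back to the
strength label (s > m > w), then to top. For opposite faces the stronger
half is the medium half by definition. Condition summaries average within
participant first; error bars are between-subject SEMs (SD of participant
means / √n), flagged NaN below two participants. The median split
classifies each whole-face trial against the participant's own median RT,
with ties counted as slow.

A property of this empirical scoring rule worth knowing: the subtrahend is
the **max of two noisy means** (~8 trials per half cell in this design), so
it is upward-biased by roughly σ/√π ≈ 0.05–0.09 where the competing halves
are close, and observed deviation scores sit systematically below the
model's predicted deviations (which subtract the true stronger-half
accuracy). Consequences: empirical deviations from an α = 1 process can
average slightly negative even though the process is purely additive, and
a fitted α absorbs part of the offset (biased low by ≈0.05–0.10 in the
recovery study). Comparative statements — together vs split, α = 1 data vs
α = 0 data — are unaffected, and the tests assert those.

## Fitting

The objective is the weighted SSE: (observed − predicted)/SEM, squared and
summed over the 17 accuracy cells, 17 RT cells and 14 deviation cells.
Minimization is Nelder-Mead on transformed coordinates — logit for α (and
variant extras), logit of (δ − .5)/(.999 − .5) for each δ (a δ below ½
would mean calibrated evidence favoring the wrong response, which the
design excludes), log for θ, k, h, identity with a floor at 0 for τ —
with tolerances 10⁻⁶, a generic fixed start, and seeded jittered restarts
(default 25; the scripts and tests use 4–8, which reach the same optima on
these summaries). No ordering constraint is imposed on the δs; ordering is
reported, not enforced. Zero or missing SEMs (ceiling cells where every
participant is perfect, common in synthetic ss cells) would make the
objective undefined; `fit_variant` floors them at the smallest positive
SEM of the same measure, while the standalone `wsse_objective` keeps the
strict contract and rejects them.

**Identifiability.** Accuracy and mean RT are nearly invariant along the
diffusion ridge θ → λθ, logit δ → logit δ/λ, k → k/λ²: condition means
constrain the products θ·logit δ and k·θ² far more tightly than the
factors. Fitted θ therefore wanders over orders of magnitude between
equivalent-prediction solutions and is not recoverable pointwise from this
design; α (which controls the together/split contrast) and the ordering of
the δs are recovered reliably. The recovery study
(`analysis/05_parameter_recovery.py`, 20 replications of the full 19 × 4
design at the reference parameters with no between-participant jitter)
reports the full fitted-parameter distribution.

## Problem sizes

Simulated experiments use the full 19 × 4 × 68 design (~5k trials,
well under a second each). The Monte-Carlo validation of the closed forms
uses 10⁵ walks per cell over p ∈ {.52, .55, .6, .7, .8, .9} ×
θ ∈ {1, …, 8} with a 3-standard-error band. Staircase convergence uses
20 000-trial runs. The recovery study runs 20 replications with 5
restarts each.

## Known limitations

- Only condition means are modelled (no RT distributions, no conditional
  correct/error RTs; for a symmetric-boundary walk the two are identical
  anyway).
- The wom evidence convention (1 − δ) is one defensible choice among
  several.
- The walk's step scale is weakly identified (above); interpret fitted θ,
  δ magnitudes and k only jointly.
- The deviation-score subtrahend is selection-biased (above); absolute
  deviation levels should be read with that offset in mind.
- Confidence generation is schematic; nothing downstream consumes it
  except the 50% filter.
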