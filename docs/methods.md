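# Methods

`semgkit` implements a lower-limb movement recognition pipeline for
8-channel surface electromyography (sEMG): onset detection and
segmentation by frame energy, four features per channel, energy-based
channel weighting (the *weighted feature method*, WFM), and an RBF-SVM
whose hyperparameters are tuned by a genetic algorithm with tiered
championship selection (IGA-SVM). This note records the model, its
assumptions, the parameter choices that matter, and the design
decisions taken where the procedure was genuinely underdetermined.

## Signal model and protocol

A trial is an amplitude matrix of `n = 8` channels x `N` samples at
`fs = 2000` Hz (defaults; 10 s trials give `8 x 20,000` samples). The
montage covers right and left rectus femoris, biceps femoris,
tibialis anterior and gastrocnemius. Six action classes `y1..y6` are
recognised: raise/lower right leg, raise/lower left leg, sitting to
standing, standing to sitting. Amplitudes are treated as volts; no
unit conversion is performed. User-facing sample and frame indices
are 1-based (matching the segmentation formulas below); internal
numpy storage is 0-based.

## Denoising

Raw sEMG carries baseline drift, power-line interference and
broadband noise. The filter chain is a 4th-order Butterworth
high-pass at 10 Hz, an IIR notch at 50 Hz (Q = 30), and per-channel
soft wavelet thresholding (db4, level 4, universal threshold with the
noise scale estimated from the median absolute finest-level detail
coefficient), all applied zero-phase. Reflection padding of 1 s is
used for both IIR stages: the notch transient decays over
~`Q/(pi*f0)` ≈ 0.2 s, far longer than the default pad, and the
residual of a pure 50 Hz tone drops from ~5% to ~1.5% RMS with the
longer pad. This chain is a straightforward composition of standard
filters chosen to remove the three stated artefact classes; it makes
no claim beyond that.

## Segmentation by frame energy

The signal is framed with length `L = 64` and increment `I = 32`
samples; for `N` samples the frame count is
`M = floor((N - L)/I) + 1` (trailing samples are dropped), so
`(M-1)*I + L <= N < M*I + L`. Frame energy is the sum of squared
amplitudes; per-trial energy is the channel sum, giving one onset per
trial (a per-channel option exists). The onset is the first frame of
a run of 4 consecutive frames with energy strictly above the adaptive
threshold `th`; `onset_run_length=3` selects the laxer
three-in-a-row variant. Given onset frame `FS`, the onset sample is
`SN = (FS-1)*I + 1`, and the *main feature segment* is the 2 s window
`MSN = SN + round(0.5*fs)` to `MEN = MSN + 2*fs` (samples
`MSN..MEN-1`, exactly `2*fs` of them) — the action's high-energy core,
skipping the 0.5 s initiation transient.

**Threshold choice.** `th` defaults to the mean frame energy over
*all* frames of the trial. An alternative sometimes suggested — the
mean energy of a designated resting prefix — is statistically
unstable as a detection threshold: the mean of the resting energies
sits at the centre of the resting distribution, so roughly half of
all rest frames exceed it and a 4-frame run occurs in rest almost
surely (observed: spurious onsets hundreds of samples early).
Because resting frames dominate the frame count while action frames
carry orders of magnitude more energy, the whole-trial mean lands
between the two levels and separates them cleanly; on the synthetic
generator it recovers onsets within +1..2 frames. The resting-prefix
variant remains available via `rest_seconds=`. The whole-trial mean
assumes one action burst per trial occupying a minority-to-moderate
fraction of it, which is the acquisition protocol here; it is not
suitable for trials that are almost entirely activity.

## Features

Each channel of the main feature segment is cut into sliding windows
(`n_win = 64`, `inc_win = 32`, the same geometry as framing, since no
separate window size is prescribed) and four scalars are averaged
over windows:

- **MAV** `= (1/(n-1)) * sum |x|` per window. The `n-1` denominator
  is deliberate (it follows the reference formulation);
  `mav_denominator="n"` restores the conventional mean.
- **RMS** `= sqrt(sum x^2 / (n-1))` per window (the root applied per
  window, paralleling MAV's per-window structure).
- **WA** (Willison amplitude): the count of consecutive-sample jumps
  `|x_i - x_{i+1}| >= th_WA`. The default `th_WA = 1e-5` (10 uV) is an
  amplitude threshold and is independent of the segmentation energy
  threshold — the two operate in different units and the reuse of the
  symbol `th` in the source formulations is treated as a collision,
  not an identity.
- **EC1**: `log10(mean_j |S_j|^2)` where `|S_j|^2` is the squared
  norm of window `j`'s full wavelet-packet decomposition at depth 3
  (db4), i.e. the coefficient energy summed over all `2^3` leaf
  bands; the mean is clamped below at `log_floor = 1e-12` so silent
  segments give `log10(1e-12) = -12` rather than `-inf`. The packet
  transform is computed level-by-level with batched single-level DWTs
  (7 filter calls for arbitrarily many windows and channels); tests
  verify exact agreement with a per-window, per-leaf reference
  decomposition. EC1 is exactly equivariant under amplitude scaling:
  `EC1(c*x) - EC1(x) = 2*log10(c)`.

Feature matrices are affinely rescaled per feature to (-1, 1) on the
training set; the same map is applied to test data (which may fall
outside the interval). A constant training feature maps to 0 and
emits a warning.

## Weighted feature method

Per recording, the weight of channel `i` is

    C_i = n * sumabs(X'_i) / sumabs(X'),

where `sumabs(X'_i)` is the sum of absolute denoised amplitudes of
channel `i` over the main feature segment and the denominator is the
total over channels. Weights are non-negative, scale-invariant and
sum to `n`. Scaling each channel's feature vector by `C_i` encodes
the muscle-action contribution structure into the features:
channels quiet in the current movement are attenuated, active ones
amplified.

Two design points were open:

- **Weights are computed per recording from its own energies**, not
  per class. Class-conditional weights would require the label at
  prediction time; the per-recording form is label-free and its
  average over recordings of one class reproduces the class's
  muscle-contribution profile.
- **Fusion is concatenation by default** (`n*a = 32` dimensions):
  per-channel structure is what the classifier discriminates on. The
  literal weighted *sum* over channels (`a = 4` dimensions) is
  available as `mode="sum"`; it collapses channel identity and is
  kept for completeness.

The packaged reference tables (six actions x eight channels of
segment energies, and the correlation coefficients they induce) serve
as fixtures: applying the weight formula to each energy row
reproduces all 48 correlation cells within their printed 4-decimal
rounding (worst deviation ~5e-5).

## IGA-SVM

The classifier is a multiclass (one-vs-one) RBF-SVM,
`k(x_i, x_j) = exp(-g * ||x_i - x_j||^2)`, with penalty `c`. The
solver is scikit-learn's `SVC`; the contribution here is the search
wrapper. Fitness of a candidate `(c, g)` is its stratified k-fold
(default 5) cross-validated accuracy on the training set. The fold
split is fixed across all individuals of a run — fitness comparisons
are then exact, and fitness values are memoised per `(c, g)`.

Chromosomes are real-valued `(log2 c, log2 g)` with
`log2 c in [-5, 15]`, `log2 g in [-15, 3]` (the conventional RBF-SVM
search box). Per generation: evaluate; sort ascending by fitness
(ties broken by `(c, g,` insertion index) for determinism); split
into four tiers — *bad, medium, well, good* — of `floor(C/4)` each
with the remainder to *good*; retain `floor(size * p)` members of
each tier drawn uniformly without replacement, with tier
probabilities `P, P+sigma, P+2*sigma, P+3*sigma` (defaults 0.4 / 0.6
/ 0.8 / 1.0); refill the `C - Cnew` vacancies from the good tier, or
the whole good tier plus random well-tier members when vacancies
exceed it (duplicates permitted — this is the elitist step); then
arithmetic-blend crossover (probability 0.7, blend coefficient
uniform per gene, clipped to range) on shuffled pairs and per-gene
Gaussian mutation (probability 0.1, scale 10% of each range,
clipped). Defaults: population 2000, 50 generations, stopping early
if an optional target fitness is reached. Runs are bit-reproducible
under a fixed seed, and the best-so-far fitness is non-decreasing by
construction. A plain tournament-selection GA (size-2 tournament,
identical operators) is included as the comparison baseline.

**A negative result, documented deliberately.** With the default tier
probabilities the tiered scheme is almost exactly intensity-matched
to the size-2 tournament: the expected average rank of the selected
population is 40.25/60 versus 40.5/60. The ~0.4-percentile deficit
comes from deterministically retaining 40% of the worst quartile —
the diversity the scheme buys. That diversity pays only on rugged,
multimodal fitness landscapes; cross-validated RBF-SVM accuracy over
`(log2 c, log2 g)` is broad-plateaued and effectively unimodal in
every problem family we probed (smooth clusters, badly scaled
features, noisy small-fold fitness, non-linearly structured classes),
so both selection schemes converge within 20 generations and their
final mean fitness differs by well under one percentage point, with
the tournament baseline slightly ahead more often than not. The
package therefore does not claim a mean-fitness advantage for the
tiered scheme on this task; its value is the guaranteed retention of
all elites (best-so-far can never regress through selection) at a
bounded diversity cost.

## Synthetic data generator

No public dataset covers this protocol, so the generator emulates it:
sEMG is modelled as amplitude-modulated band-limited (10-500 Hz)
Gaussian noise — the standard surrogate for the interference pattern
of many asynchronous motor-unit action potentials. A trial is

    x_i(t) = sd_rest * n1_i(t) + gain_i * sd_burst * env(t) * n2_i(t)

with independent unit-variance band-passed noises `n1, n2`, a
raised-cosine envelope (50 ms ramps) over the burst window, and
per-channel gains giving each class its muscle-activation signature.
Defaults: `sd_rest = 0.1 mV`, `sd_burst = 3 mV`, burst at 2.0 s for
4.0 s in a 10 s trial; gains are the six reference correlation rows
rescaled to unit mean, so the synthetic ground truth mirrors the
published muscle-action structure, and the 3 mV scale puts
main-segment absolute-amplitude sums in the 2-31 range of the
reference energy table. Per-trial seeds derive deterministically
from a master seed.

What the generator does *not* model: motor-unit dynamics, muscle
fatigue, electrode shift, inter-channel crosstalk, inter-subject
variability, or non-Gaussian amplitude statistics. Classes are
separated exactly by their energy profiles, which is the structure
the WFM exploits; passing end-to-end tests therefore demonstrates
the pipeline's internal consistency and its sensitivity to
energy-profile structure, not field performance on real recordings.
On these well-separated defaults the classifier saturates near 100%,
with or without channel weighting; the weighting's published
accuracy gains on real data are not reproducible from synthetic
surrogates and are not claimed.

## Problem sizes in the test suite

The verification suite scales stochastic checks to desk size as its
own experimental design: onset recovery uses 200 seeded 10 s trials
(hit criterion: ±3 frames = ±48 ms); the selection-scheme comparison
uses population 60, 20 generations, 20 replicate seeds on a fixed
6-class Gaussian problem; the end-to-end comparison uses 6 x 120
trials of 4 s (the main feature segment is always 2 s, so shorter
trials change only the discarded rest and ending segments) with a
half/half split, a population-20 / 6-generation / 3-fold GA, over 20
replicate seeds; determinism is checked byte-for-byte on serialised
reports.

## Numerical and degenerate-input conventions

Frames/windows that do not fit are dropped, never padded. A trial
with no qualifying threshold run raises a distinct no-onset signal;
one ending before `MEN` raises a too-short error; batch builders log
and exclude such records rather than aborting. Zero total channel
energy makes weights undefined (degenerate-input error). Constant
features normalise to 0 with a warning. `EC1` of silence is the log
of the floor. All randomness flows from explicit
`numpy.random.Generator` seeds; derived seeds stay below 2^31.

## Model persistence

A trained model serialises to JSON as `(best_c, best_g)`, the class
list, the feature scaler, and the (scaled) training matrix; loading
refits the SVM, which is deterministic, so the file fully reproduces
the model without serialising solver internals.
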