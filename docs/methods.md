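# Methods

`srtkit` implements the construction and validation machinery of an
adaptive, sentence-based speech-in-noise test, together with a virtual
testing layer that lets every stage run — and be checked — without audio
or human listeners.

## Psychometric model

Sentence intelligibility in stationary noise is modelled as a logistic
function of the signal-to-noise ratio (SNR):

    p(x) = 1 / (1 + exp(-4 (s/100) (x - m)))

with midpoint `m` (dB SNR at 50% correct) and slope `s`, the derivative
at the midpoint in percentage points per dB. The factor 4 makes `s` the
slope directly, so the two reported parameters of a fitted curve are the
model's own parameters. No guess or lapse rate is modelled: the material
is open-set (chance performance is essentially zero), and trained
listeners at favourable SNRs approach 100%; a plain logistic is the
convention for this material.

Fitting minimizes the squared error between the per-presentation percent
correct (100·k/3 keywords) and the curve, using `scipy.optimize.least_squares`
(trust-region reflective, a damped iterative least-squares method)
multi-started over candidate midpoints spanning the observed SNR range
and three slope scales. Multi-start matters because per-track samples
are small (≤ 20 points) and the loss has flat shoulders. The reported
MSE is the mean squared residual on the percent scale (units %²).
Response sets that are all-correct or all-wrong carry no midpoint
information and return a result flagged `converged=False` instead of
arbitrary numbers; fewer than three distinct SNR levels is an error.

Level normalization: each sentence's offset is `m_i − m̄`, the gap
between its midpoint and the corpus reference mean. Played with a level
gain of that many dB, the sentence's effective midpoint moves onto the
reference, equalizing intelligibility across sentences. Offsets are
translation-equivariant and sum to zero against their own mean.

## Corpus filtering

A sentence survives when it passes, in this documented attribution
order: playback quality (audio and audio-visual), discomfort fraction
< 0.25 (strict), mean naturalness ≥ 4.5 (inclusive), midpoint inside
(−9.2, −0.5) dB (strict), slope inside (0, 33.5) %/dB (strict), and fit
MSE below 897 %². The psychometric cutoffs are 1.5-IQR outlier fences
(quartiles by linear interpolation); they are configuration defaults of
`FilterCriteria`, not quantities the package recomputes. The MSE
comparison direction is exposed because upper-outlier removal (retain
below the cutoff) is the behaviour consistent with the IQR procedure;
the alternative direction is available in configuration.

The offset trim then removes sentences whose midpoint lies more than
3 dB from the mean of the filtered set, which caps every normalization
offset at 3 dB. The trim is single-pass and the pre-trim mean is the
normalization reference; removing a few extreme sentences barely moves
the mean, so iterating is unnecessary (an iterate-until-stable mode with
a 0.05 dB tolerance exists but is off by default).

## List optimization

Lists hold 20 sentences, two per each of the 10 syntactic templates, so
the scarcest template limits the list count to `floor(min_count / 2)`.
Each optimizer iteration:

1. per template, uniformly subsamples 2·L sentences (seeded) — the
   subsample is redrawn every iteration so the optimizer explores the
   sentence selection as well as the arrangement;
2. sorts them by offset and pairs middle-out: the innermost pair holds
   the two most central offsets, the outermost the extreme negative and
   positive ones, so each pair's mean offset is near zero;
3. recomputes the reference mean midpoint over the selected 20·L
   sentences and the offsets against it (the exported reference is
   therefore specific to the winning arrangement);
4. scatters each template's pairs over the L lists with a seeded
   permutation (pair members stay together);
5. scores the arrangement with
   `cost = 1.0·SD(list mean slopes) + 1.0·SD(list mean offsets)`,
   sample SDs (n−1). The equal raw weights mix %/dB with dB by design;
   both weights and the SD denominator are configurable.

The best of `n_iter` iterations (default 1000) wins; ties go to the
earliest iteration, and the full cost log is retained. The whole
procedure is bit-for-bit reproducible under a fixed seed. This is a
random search, deliberately: the arrangement space is astronomically
large, the cost landscape has no useful structure for local moves at
this granularity, and equivalence — not global optimality — is the goal.

## Adaptive staircase

A track consumes one 20-sentence list at a fixed 70 dB(A) noise level.
The first sentence plays at 0 dB SNR and must be repeated completely
correctly (all three keywords); otherwise it is replayed 5 dB louder
until it is. Replays do not consume list sentences and are excluded
from phase counting, reversal detection and the SRT. Afterwards the SNR
moves down on a correct and up on an incorrect response (majority
scoring by default, ≥ 2 of 3 keywords; an all-keywords mode is provided
because the decision rule materially changes SRTs between test
families). Step sizes by phase: 5 dB until at least 4 sentences and the
first reversal; 2 dB until at least 4 more sentences and the standard
error of the phase-2 presented levels (sample SD/√n) drops below 1 dB;
1 dB thereafter. Each adjustment uses the step size of the phase the
just-scored sentence belonged to; a phase transition affects the labels
and steps of subsequent presentations. The track ends when the list is
exhausted, whether or not phase 3 was reached.

SRT = mean nominal (pre-offset) SNR of phase-2/3 presentations; SE =
their sample SD/√n. Nominal levels are used because the sentence
offsets are a property of the material, not of the listener's
threshold. A track that never leaves phase 1 has no SRT and raises a
diagnostic; the companion restart conditions (suspected perseveration,
first four sentences all correct) surface as warnings rather than
automatic restarts, since they are tester judgement calls.

## Virtual listeners and study simulation

A virtual listener shifts every sentence's effective midpoint by a
personal `srt_shift_db` and scales slopes by `slope_scale`; the three
keywords of a presentation are independent Bernoulli draws from the
sentence's (normalized, shifted) logistic curve. Listener shifts
default to Normal(0, 0.5 dB), echoing between-subject SDs typical of
normal-hearing cohorts; within-sentence keyword correlation is not
modelled — real keywords within a sentence are correlated, which
inflates response variance relative to this idealization, so simulated
SRT spreads are best-case.

Sessions mirror the counterbalanced normative design: participants come
in pairs, a seeded permutation of the 44 lists is halved between the
two, each participant first trains on 2 lists drawn from the half they
will not be tested on, then completes 22 test lists; with 20
participants each list collects exactly 10 test scores. Per-track RNG
streams derive from a `SeedSequence` keyed on (master seed, participant,
order), so reordering or dropping sessions never perturbs other tracks.
An optional linear drift of the effective midpoint with presentation
order injects a known practice effect for power checks.

Under these defaults, 500 simulated tracks at sentence slope
18.5 %/dB recover the listener's effective midpoint to well within
0.5 dB with an SRT SD near 0.8 dB — inside the 0.5–1.2 dB band that
brackets human test–retest variability, though the idealized listener
makes such agreement a plausibility check, not a validation against
humans.

## Validation statistics

List equivalence reports per-list means and SDs of test SRTs across
participants, deviations from the grand average (the unweighted mean of
list means), and the largest pairwise list difference. Within-subject
variability is the SD of each participant's 22 test SRTs, averaged
unweighted over participants; training rows are excluded by contract.

The training effect is a linear mixed-effects model
`SRT ~ 1 + order + (1 | participant)` fitted by REML
(`statsmodels.MixedLM`), with a marginal F-test of the order term using
1 and n−2 (residual) denominator degrees of freedom and a matching
t-based 95% CI — the simple residual-df convention, exposed here
because fancier corrections (Satterthwaite, Kenward–Roger) are out of
scope. The model is fitted both with training rows (orders 1–24) and
without (orders kept as 3–24; the slope is invariant to linear
recoding, only the intercept's meaning changes). When the true random
variance is zero the REML optimizer can degenerate; the fit retries a
sequence of optimizers and, failing all, falls back to OLS flagged
`converged=False`. On balanced data the fixed-effect estimates equal
OLS regardless of the variance estimate, which the tests exploit as a
degenerate-limit oracle.

Post hoc slopes refit the logistic to each track's own trial log.  A
caveat measured with the simulator: per-track slope estimates from
~16-point staircase logs are noisy (SD ≈ 12 %/dB) and upward-biased
(mean ≈ 25 %/dB when the generating slope is 18.5), because adaptive
tracks concentrate presentations near the midpoint and small-sample
slope estimates have a heavy right tail. Pooling all tracks' trials
into one fit is consistent and recovers the generating slope closely;
the per-track grand average should therefore be read as a descriptive
statistic comparable only across identically designed tracks.
Non-convergent per-track fits are excluded and counted, never imputed.

## Synthetic corpus generator

The generator emulates the metadata table of a psychoacoustically
characterized corpus: 10 templates × `n_per_template` (default 120)
rows; midpoints Normal(−4.8, 1.6) dB — the SD chosen so the normal
1.5-IQR fences (≈ mean ± 2.7 SD) land near the −9.2/−0.5 dB retention
bounds; slopes Normal(13, 6) %/dB, sentence-level curves being much
shallower than pooled track-level ones; and survey/quality/MSE fields
drawn as compliant bulks plus small violating fractions (2–3% each) so
every filter has work to do. At the default scale the filtered corpus
retains ≥ 88 sentences per template — enough for 44 lists — in well
over 95% of seeds; the residual seeds simply reflect binomial sampling
noise. What the generator does not emulate: real psychometric-parameter
correlations (e.g. between midpoint and slope), template-specific
differences, and any linguistic structure — so passing tests demonstrate
the machinery's correctness under the stated model, not properties of
any real speech material.

## Problem sizes and numerical choices

Defaults follow the reference study design throughout: 1200-sentence
corpus, 44 × 20 lists, 1000 optimizer iterations, 20 participants ×
(2 + 22) lists, 10 scores per list. The test suite and examples scale
only the replication counts (e.g. tens to hundreds of replicate studies
for recovery checks, 200 optimizer iterations in examples), never the
study geometry. Quartiles use linear interpolation; SDs are sample SDs
(n−1) unless noted; optimizer ties break to the earliest iteration;
list CSV offsets serialize at one decimal (full precision in memory);
every randomized entry point takes an integer seed and is exactly
reproducible under it.
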