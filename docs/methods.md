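# Methods

This note records the models, parameter choices and numerical decisions
behind `adrofit`, and what the simulated studies do and do not show.

## Signal path

All audio is mono float64 at 16 kHz; other rates are polyphase-resampled on
ingest and stereo is channel-averaged.  Digital level is tied to sound
pressure level by a fixed affine calibration — RMS 1.0 ≡ 100 dB SPL by
default — so every SPL-valued quantity in the pipeline is well defined and
testable.  Nothing in the method depends on the absolute anchor; changing it
shifts every level and target together.

### Filterbank

Band decomposition is an STFT with 8 ms periodic-Hann frames at 50 %
overlap (128 samples, hop 64).  That window/hop pair satisfies the
constant-overlap-add identity exactly, so analysis → overlap-add synthesis at
unity gain reproduces the input to float rounding (measured ≳ 300 dB
reconstruction SNR; the contract in the tests is ≥ 50 dB).  Each FFT bin
belongs to exactly one band — half-open intervals on bin center frequency,
with the Nyquist bin joining the last band — so per-frame band powers
partition the frame power exactly.  The ten amplifier bands are
0–250–500–750–1000–1500–2000–3000–4000–6000–8000 Hz (the nominal list begins
at 125 Hz and leaves the last band open; we widen the first band to 0 Hz and
close the last at Nyquist so the partition covers the spectrum).  The five
training bands pair them: 0–500–1000–2000–4000–8000 Hz.  Band power is
normalized so a sine concentrated in one band reports its mean-square
amplitude; for broadband signals this sinusoid-referenced convention reads
about 1.8 dB below a noise-bandwidth convention, a constant offset absorbed
by the calibration.

An 8 ms frame gives 125 Hz resolution, so band edges have a finite
transition skirt.  Consequences: a pure tone's measured in-band power is
≥ 99 %, not 100 %; and when adjacent bands carry very different output
levels (possible under arbitrary random maps where neighboring MPOs differ
by ~25 dB), a re-analysis of the time-domain output can attribute 1–2 dB of
a loud band's skirt to its quiet neighbor.  The MPO guarantee is therefore
stated on the synthesis channels (the power the engine puts into each band's
own bins), where it is exact; re-analysis respects the cap to 0.5 dB for
realistic smoothly-varying maps such as the published subject profiles.

### Level tracking

Per-band SPL percentiles (98th / 70th / 30th by default) are tracked with
constant-step stochastic-approximation quantile estimation: for target
quantile p, the estimate moves up by `step·p` on a level above it and down
by `step·(1−p)` otherwise, so the up/down drift balances exactly at the p-th
quantile.  The tracker is streaming and O(1) per band.  Step 0.2 dB per 4 ms
frame: small enough that the equilibrium limit cycle stays well under 1 dB,
large enough to burn in within a second.  Estimates initialize at the
listener's CT; silence floors at 0 dB SPL.  The tracker's *converged*
estimate is read as a trailing mean — any single sample sits somewhere in an
O(step) limit cycle.  On stationary 10⁴-frame streams the converged
estimates match the exact interpolated order statistic within 1 dB for all
three quantiles (uniform, Gaussian and exponential test streams).

### Gain rules

One rule fires per band per frame, precedence 1 > 2 > 3 (safety first; the
ordering under simultaneous conditions is our choice — the rationale is that
discomfort must win over audibility):

1. high percentile > LDL → gain −slew·dt;
2. else mid percentile < CT → gain +slew·dt, blocked once gain = MG or the
   high percentile reaches LDL (the block holds the gain rather than falling
   through to rule 3);
3. else low percentile > AT → gain −slew·dt.

Rule 3 is implemented exactly as stated — the low percentile rising above
the audibility target *reduces* gain — although the classic ADRO literature
frames audibility as a gain-increasing rule; a config flag is deliberately
not provided because the as-stated direction is what the rest of the system
(equilibria, oracles, tests) is built around, and under it rules 2 and 3
form a stable bang-bang controller whose equilibrium is "output mid
percentile = CT".  Slew rate 3 dB/s ⇒ 0.012 dB per 4 ms hop.  Gains clamp to
[−MG, +MG], MG 30 dB by default.  Percentiles track the *amplified*
(pre-MPO) level, which is what makes rule 2's equilibrium the controlled
quantity.

MPO (default = LDL) is applied at synthesis as an instantaneous extra
attenuation wherever the amplified band level overshoots; the overshoot is
taken over a 3-frame neighborhood because 50 %-overlap synthesis smears each
frame into its neighbors.

The steady-state oracle (`steady_state_gain`) replays the *complete*
dynamics — trackers plus rules, identical steps — over a stationary sample
stream pass after pass until the per-pass mean gain settles, and returns the
limit-cycle mean.  A 30 s single-pass run agrees with it to ≤ 0.4 dB
(2 × the tracker step, the equilibrium noise scale); its gain is likewise
read as a trailing 5 s mean.

### Map defaults

Only audiograms and comfort targets are published for the ten bundled
subjects.  The remaining map parameters default to: AT flat 20 dB SPL (below
every CT the scaled space can produce, so range clamping never distorts the
action space), LDL = standard CT + 25 dB, MPO = LDL, MG = 30 dB.  All are
configurable.

## Stimuli

Training stimuli emulate short noisy sentences: a sawtooth-like glottal
source with a drifting fundamental in 90–220 Hz, three random formant
resonances (300–800, 900–2200, 2300–3200 Hz), 3–5 Hz syllabic amplitude
modulation and one or two 100–200 ms silent gaps; utterances are 2.5 s,
RMS-normalized to 0.1 full scale (≈ 80 dB SPL overall under the default
calibration, placing band levels in the 60–75 dB range typical of
conversational speech, below the bundled subjects' CTs).  Babble is the sum
of eight independent utterance streams; the mixer rescales it for an exact
long-term SNR (5 dB in the protocol).  The generator is deterministic in its
seed.  What it does *not* reproduce: phonetic structure, talker variety,
intelligibility — so no word-recognition outcome is attempted or implied,
and passing tests say nothing about speech understanding with real speech.

## Personalization

The candidate space scales each training band's standard CT by a factor from
{0.5, 0.75, 1.0} (the set is configurable; these values are where the
published personalized/standard ratios cluster), enumerated factorially:
3⁵ = 243 profiles, entries rounded to 1 dB (half up) and clamped into
[AT, LDL].  Each training band's scale applies to both of its amplifier
bands on expansion.  The published per-subject tables are not always
consistent with uniform within-pair scaling (some rows scale the two bands
of a pair differently); we implement uniform scaling and keep the published
vectors only as reference data.

The reward is linear in a one-hot encoding of the *action's* per-band scale
(n = 5 bands × 3 scales = 15 features).  This is exactly expressive enough
to encode a preferred scale per band — which is what the protocol can
identify — and makes the reward maximizer decomposable per band.  The policy
is Boltzmann with temperature 1.

The demonstration likelihood is Π π_W(s, a)·ℋ(s, a) over feedback records.
ℋ — the smoothed preference model,
(n_pos + 0.5·n_neutral + 1)/(n_total + 2) per (s, a) — carries no
W-dependence, so the weights are identified by the policy factor alone.  For
that factor to reflect the listener rather than the proposal mechanism, the
records entering it are the listener's *demonstrated selections*: a positive
record contributes the probability of picking the action out of the
presented pair {state, action}, a negative record the probability of keeping
the state, and neutral records shape only ℋ.  This is a Luce-choice
(conditional-logit / Bradley–Terry) likelihood with the linear reward as
score; its log is concave, so gradient ascent with backtracking line search
(start W = 0, Armijo condition, tol 1e-6, cap 500 iterations) is globally
convergent and monotone by construction.  With a deterministic listener the
data can be separable — the cap then bounds ‖W‖ and the recovered *ranking*,
which is all the personalization uses, is unaffected.

Sessions: every trajectory restarts at the standard profile; each step draws
16 candidate profiles and proposes one ε-greedily (ε = 0.5; exploitation
uses weights refit after each completed trajectory, so the first trajectory
is pure random proposal).  Positive feedback moves the state to the action.
After all trajectories the weights are refit on the complete demonstration
and the personalized profile is the reward maximizer, ties broken toward
the standard profile (least intervention); an all-neutral session therefore
returns the standard fit.

### Why paired-comparison renders are warm-started

At 3 dB/s a 2.5 s render moves gains at most 4.5 dB from any starting
point, and the bang-bang rules move at the *same rate* for every CT on the
same side of the signal level — so two renders under different CTs, both
started cold, are nearly identical and carry almost no preference
information for any listener, human or simulated.  In the wearing situation
the comparison emulates, each fitting has been adapting for minutes, not
seconds.  Session renders are therefore initialized at the closed-form rule
equilibrium for that profile on that stimulus — gain =
clip(CT − q70_in, −MG, MG), further capped so the 98th output percentile
stays at or below LDL, with percentile estimates started at the
corresponding output percentiles — and the 2.5 s adaptive trajectory runs
from there.  Stand-alone `process()` keeps the cold start (gains 0 dB,
estimates at CT, rules held for a 1 s burn-in).

## Simulated listeners

Ground truth is a preferred comfort-target vector (per-band scales applied
to the listener's own standard CTs).  A rendering is scored on the engine's
diagnostics: −Σ_bands |final mid percentile − preferred CT| − 20 × (fraction
of frame/band cells whose pre-MPO level exceeds LDL).  Scoring the quantity
ADRO actually controls makes parameter recovery well-posed; it deliberately
ignores distortion, band weighting and anything else a real subject might
attend to.  Choices follow a logistic rule on the score difference with
temperature 0.25 and a "same" band of 1 score unit: the least-discriminable
non-"same" pair is chosen consistently with probability sigmoid(1/0.25)
≈ 0.982, so repeated presentations agree ≥ 96 % of the time — above the 95 %
self-consistency the protocol calls for (the acceptance script verifies this
by measurement and aborts if calibration fails).  Temperature 0 gives the
deterministic listener used in recovery tests.

## Evaluation

The held-out test renders fresh utterance+babble mixtures under the standard
and personalized maps (warm-started, as in training), randomizes
presentation order per pair, and tallies the listener's choices.  The cohort
statistic is a classical two-group one-way ANOVA on per-listener preference
counts — the only two-group layout that yields 1 and 18 degrees of freedom
with ten subjects — with an explicit +∞ sentinel when the within-group
variance is zero; "same" responses stay in the tally but not in the ratio,
and the cohort ratio's denominator is floored at one preference so it stays
finite when no listener ever picks the standard fit.

## Problem sizes and runtime

The full simulated cohort study (10 listeners × (7×31 training + 30 test)
pairs, two renders each, 2.5 s at 16 kHz) runs in a few minutes on one CPU;
the per-frame adaptation loop is JIT-compiled via numba when available, with
an identical pure-Python fallback.  Equilibrium studies use 30 s of
stationary noise (7500 frames); tracker-accuracy studies use 10⁴-frame
streams.

## Known limitations

- The rule-3 direction follows the stated specification, not classic ADRO
  usage; with audibility-increasing semantics the equilibrium analysis would
  change.
- The linear, band-separable listener score and the scale-set prior make
  recovery easier than for real subjects, whose preferences need not factor
  over bands or lie in the candidate space.
- The dBFS→SPL calibration is an assumed constant; absolute SPL claims
  depend on it.
- Gains reset between utterances (sessions re-warm-start each render);
  cross-utterance gain persistence on a device is not modeled.
- No intelligibility surrogate: preference outcomes do not speak to word
  recognition.
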