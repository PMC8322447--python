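# Methods

## Model

The package treats speech-listening EEG as the output of a linear
time-invariant system driven by discrete linguistic events. For channel
`ch`,

    R_ch(t) = Σᵢ Σ_τ wᵢ(τ) · Sᵢ(t − τ) + ε_ch(t),

where `Sᵢ` is a binary impulse train (1 at event onsets of feature `i`, 0
elsewhere) and `wᵢ` is the temporal response function (TRF) of that feature
over lags −200…1500 ms at 200 Hz (341 weights). The assumptions are those
of any mTRF analysis: linear superposition of overlapping responses,
time-invariance within a session, and additive noise uncorrelated with the
stimulus. Features sharing a scheme are estimated jointly, which is what
disentangles temporally adjacent events (e.g. a word onset and its first
phoneme).

Estimation unrolls the convolution into a lagged design matrix (sparse,
feature-major, lags ascending) and solves ridge normal equations
`(XᵀX + λI)w = Xᵀy` with an unpenalised intercept, one fit per trial; the
participant TRF is the equal-weight average of single-trial fits, for both
cross-validation and the final estimate. λ is selected by rotating trials:
for each held-out trial the averaged training-trial TRFs predict the
held-out response, and the grid value (1…10⁴, decades) minimising MSE over
rotations, channels and participants wins; ties go to the smaller λ.
Downstream feature extraction uses one shared λ (default 10²).

## Component features

Amplitudes are arithmetic means over inclusive latency windows: N1 90–140,
P2 190–250, late component 300–600 ms (open-class/N400-like) or 500–800 ms
(closed-class slow negativity). Latency extraction is two-stage: the
cohort grand-average waveform yields the component peak (polarity-matching
extremum in the window, earliest on ties; a wrong-signed extremum means "no
peak" and the feature becomes missing), and dynamic time warping transfers
that peak to each participant.

The DTW step deserves detail because naive transfer is fragile. Both
series are restricted to non-negative lags, smoothed with a Gaussian kernel
(SD 50 ms — symmetric smoothing moves no peak centre), and z-normalised so
amplitude scale cannot dominate the alignment; the warping path (local cost
|a−b|, steps (1,0),(0,1),(1,1), no band constraint) is then read out not at
the single grand-peak column but over the component's support: every path
pair within the component window's half-width of the peak contributes a
shift-corrected individual index, and the lower median of those indices is
the individual latency. Rationale: near a broad, flat extremum the
per-column match is noise-dominated, while the warp aggregated over the
bump's support — anchored globally by the sharper N1/P2 flanks — is stable.
In simulation (planted ±50 ms shifts, white series noise at one tenth of
the signal variance) the pooled rule recovers ~97% of shifts within one
sample, against ~25% for the single-column rule; all noiseless properties
(identity, pure shift, amplitude-scaling invariance) are exact either way.

Word-position and speech-rate TRFs used for late-component features are
estimated from open-class-restricted impulse matrices, since the late
negativity of interest is the open-class N400; matrix construction itself
defaults to pooling both classes and both modes are exposed
(`word_filter=` in `build_stimulus_matrix`).

### The 117-feature manifest

The default manifest enumerates 39 feature × measure combinations at the
three midline electrodes (Fz, Cz, Pz), 117 columns total: word class 12
(open/closed × N1/P2/late × amplitude/latency), speech rate 4 (fast/slow
late × both measures), word position 6 (three pairwise contrasts
beginning−middle, beginning−end, middle−end × both measures; per-position
values are intermediates only), parts of speech 17 (five open classes ×
both measures; amplitude for article/determiner, pronoun, BE verb,
auxiliary verb, preposition; latency additionally for article/determiner
and preposition only — pronouns, BE and auxiliary verbs show no clear
grand-average peak, and numbers, interrogative words, relative pronouns and
conjunctions show no clear slow negativity and are excluded entirely).
This is one documented reading of an under-specified count; the
composition is configurable via `ManifestEntry` lists.

Missing latencies (no-peak grand averages, or a missing side of a position
contrast) are imputed with the cohort median before prediction; columns
missing everywhere are zero-filled and reported.

## Prediction

Pearson screening keeps features with |r| ≥ 0.2 against the score
(inclusive), choosing among passing electrodes of one feature the one with
the highest |r| (a literal signed-r variant is available). Selected
columns are z-scored over the full sample — this mirrors the published
procedure and leaks test-set means; a train-only mode exists for honest
evaluation and, on average, cannot beat full-sample scaling. The LASSO
minimises `1/(2N)Σ(yᵢ−β₀−xᵢᵀβ)² + λΣ|βⱼ|` by cyclic coordinate descent on
the Gram form with soft-thresholding (convergence when the largest
coefficient step < 10⁻⁷); λ = 0 is solved exactly as OLS via least squares.
The outer loop is leave-one-participant-out; each training split tunes λ
over 500 evenly spaced values in [0, 5] by 10-fold CV on RMSE (warm-started
descending path; ties take the smaller λ; fold assignment is a
deterministic shuffle derived from the run seed). Reported metrics:
Pearson r with Fisher-z 95% CI, mean absolute difference ± SD, RMSE.
Feature contributions are across-fold mean coefficients, absolute-valued,
normalised to a maximum of 1.

## Synthetic cohort

The generator emulates the study conditions end to end. Scores are drawn
from a normal distribution (mean 539.1, SD 67.4) truncated to [328, 687].
Word onsets follow a lognormal renewal process (mean rate 2.5 words/s,
shape σ = 0.55) grouped into sentences of geometric length (mean 7 words);
each word carries a part-of-speech class from a fixed frequency table
weighted toward nouns/verbs/determiners/prepositions, and 1–3 syllables
rendered as vowel-nucleus phonemes with flanking consonants. Events are
kept ≥ 0.25 s after trial start and ≥ 1.55 s before trial end so that every
impulse's full lag span lies inside the trial — without this margin the
edge lags are unidentifiable per trial and exact noiseless recovery is
impossible in principle.

Each participant's kernels are sums of Gaussian bumps whose centre is
`base_latency + slope · z(score) + jitter`. Defaults (per word class):

| class  | component | base (ms) | slope (ms/SD) | amplitude | width (ms) |
|--------|-----------|-----------|---------------|-----------|------------|
| open   | N1        | 120       | −2            | −1.0      | 15         |
| open   | P2        | 215       | −12           | +1.1      | 25         |
| open   | late      | 455       | −45           | −0.9      | 70         |
| closed | N1        | 110       | −2            | −0.9      | 15         |
| closed | P2        | 210       | −5            | +1.0      | 25         |
| closed | late      | 700       | 0             | −0.8      | 90         |

Amplitude slopes are negative (−0.12…−0.15 per SD) for open P2 and both
late components, zero elsewhere, so that exactly the measures reported to
track proficiency do so in simulation. The same lag profile is scaled per
channel by a fixed topography (Cz 1.0, Pz 0.9, Fz 0.8, FC5/FC6 0.4).
Recordings are the exact forward model plus noise scaled per channel to a
target clean-to-noise variance ratio over the whole trial (default 10 dB);
the default noise is an equal-power 1/f + white mixture. Phoneme and
sentence-boundary rows receive small proficiency-independent kernels and
are optional in the generating scheme (off by default).

What the generator does **not** emulate: ocular/movement artifacts (the
preprocessing contract — earlobe re-reference, 0.5–50 Hz FIR order 3300,
resample to 200 Hz, 7 Hz FIR order 1320, zero-phase by default — is
implemented and tested on constructed signals, but synthetic recordings
are rendered band-limited at the analysis rate and skip it), nonlinear or
adaptation effects, non-stationarity across trials, and any real
phonology/syntax. Passing recovery tests therefore demonstrates estimator
correctness under the model's own assumptions, not robustness to real EEG
artifact structure.

## Numerical choices

- Onsets discretise by round-half-away-from-zero; two events of one
  feature landing on one sample clip to a single binary impulse.
- Ridge uses a Cholesky solve shared across channels (multi-RHS); a
  rank-deficient design at λ = 0 raises; λ > 0 falls back to least squares
  if factorisation fails.
- Position tertiles split word ordinals at ceil(n/3), ceil(2n/3); words of
  a trial-final interrogative sentence are excluded first.
- Syllables are counted as vowel-nucleus phonemes (short/long vowel,
  diphthong) within the sentence interval; the fast/slow boundary
  (230 SPM) is inclusive on the fast side.
- DTW backtracking breaks ties diagonal-first; matched-index median takes
  the lower (earlier) element.
- The bandpass design (Hamming windowed-sinc, order 3300 at 500 Hz) has a
  ~0.5 Hz transition, so DC rejection is ~59 dB, not infinite.
- Inner-CV fold seeds derive from one `SeedSequence`, keeping all results
  bit-reproducible for a fixed seed.

## Problem sizes

Simulation studies in the test suite and acceptance script use: 33 trials
× 30 s for noisy kernel recovery (the study's trial count); 3 trials for
exact noiseless closure (exactness does not depend on trial count); 6
trials × 20 s with phoneme rows for ridge-weight selection (phoneme/word
collinearity is what makes regularisation matter at 0 dB); 200 simulated
waveforms for DTW latency recovery; 100 participants for planted-feature
screening/prediction; 24 participants × 6 trials for the small full
pipeline run. These sizes are the package's own defaults for desk-scale
verification.

## Known limitations

- With the 9 phoneme rows included, the first phoneme of each word nearly
  coincides with the word onset; this collinearity caps word-kernel
  recovery around r ≈ 0.95 at 10 dB regardless of λ. It reflects a real
  property of jointly modelling words and phonemes, not an estimator bug.
- Full-sample z-scoring before prediction leaks test statistics; it is
  kept as the default to mirror the published procedure and flagged here.
- The DTW latency transfer assumes a single dominant component per window;
  multimodal individual waveforms can map ambiguously.
- TextGrid input is not supported; annotations are ingested as TSV.
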