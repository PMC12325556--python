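# Methods

This note documents the models, conventions and defaults behind
`emgchrono`, the choices made where the design was genuinely open, and what
the synthetic-data generator does and does not establish.

## Generative model for trial-level outcomes

For participant *i*, item *j*, bias block *b* ∈ {neutral, word-bias,
pseudoword-bias} and lexicality *l* ∈ {word, pseudoword}:

- PMT_ijbl = Xβ_PMT + u_i + w_j + ε, ε ~ N(0, σ_PMT)
- MT_ijbl  = Xβ_MT + u'_i + w'_j + ε', ε' ~ N(0, σ_MT)
- RT = PMT + MT (exact identity, not a separate draw)
- accuracy, partial error ~ Bernoulli(logit⁻¹(Xβ + u + w))

X is the treatment-coded bias × lexicality design (references: neutral,
word). The fixed-effect defaults are the published estimates for each
measure; because RT is a sum, its implied coefficients are the sums of the
PMT and MT coefficients (e.g., neutral intercept 518.14 + 134.40 = 652.54
ms against a directly reported 652.76 — the ~0.2 ms discrepancy reflects
separate model fits in the source analysis, not an inconsistency here).

Random-effect and residual SDs are **documented placeholders** (the
published random-effect variances are in supplementary material not
reproduced here): participant/item/residual SDs of 80/30/100 ms for PMT,
15/5/25 ms for MT, and 0.8/0.3 logits for the binary measures — magnitudes
typical of lexical-decision data. In this balanced design, fixed-effect
recovery is unbiased regardless of these values; they control precision
only. PMT and MT residuals are independent by default (the central
empirical claim is their dissociation); a correlation parameter exists and
defaults to 0. PMT is floored at 50 ms and MT at 25 ms (physiological
minima); with the default cell means the floors bind on < 0.1% of trials.
Trials with RT beyond the 1500 ms deadline are flagged timeout and removed
downstream (they are essentially absent at the default parameters,
matching the reported 0.01%). Covert correct-hand activation on error
trials ("partial correct") is drawn at a constant 0.3% and reported but
not modeled.

### Design counterbalancing proxies

Block order after the initial neutral block alternates with participant
parity; the three stimulus sets rotate over blocks with participant index;
the initial stimulus–response mapping alternates every second participant;
the mapping reverses exactly once, halfway through each block, with every
stratum (lexicality × filler status) split evenly across halves. These are
proxies for the original Latin-square-style counterbalancing: they
preserve the marginal balance that matters for the models without
reproducing the exact assignment lists.

## Raw-EMG rendering

Epochs span −500…2100 ms at 1000 Hz (2601 samples). Both channels carry
gaussian baseline noise (SD 1.0 in arbitrary units) and, optionally, a
50 Hz sinusoid. The response burst runs from PMT to the press: a random
sign × U(0.5, 1.5) carrier under a trapezoidal envelope that steps to half
amplitude at the onset sample, ramps to full amplitude over 5 ms, and
decays over the final 5 ms. The half-amplitude onset step is deliberate:
it bounds the onset sample away from zero so that noise-free onset
detection is sample-exact for every burst amplitude — a pure 0→1 ramp
under a noise carrier can make the first burst samples smaller than the
integrated profile's average slope, displacing the detected onset by 1–3
samples. Default plateau amplitude is 5.0, i.e., a burst-to-noise RMS
ratio of 5; partial bursts use amplitude 2.5 and 100 ms duration, starting
at a uniform 40–70% of the trial's PMT (covert incorrect activation
precedes the correct response). Simulated bursts are stationary in
frequency content; real EMG has band-limited spectra, motion artifacts and
amplitude drifts that this generator does not emulate — green detection
tests establish correctness of the bookkeeping and robustness to white
noise, not performance on pathological recordings.

## Preprocessing conventions

Filters are zero-phase (forward–backward `filtfilt`), chosen because the
analysis quantity is an onset latency and causal filtering would shift it;
the effective order therefore doubles (the high-pass behaves as order 4).
The notch is a second-order IIR at Q = 35 (≈ 1.4 Hz bandwidth) — the notch
design was not specified in the source pipeline and this is an explicit
substitute. Per-epoch filtering uses ≥ 1 s of reflection padding.
Rectification is plain absolute value, no envelope smoothing. Baseline
statistics (rectified mean and SD, ddof = 1) use −500…0 ms only. All times
are ms relative to stimulus onset; intervals are closed at the start, open
at the end.

## Onset detection and validation

The integrated-profile convention is fixed as: over the search window
(stimulus onset to button press), IP(t) = Σ rectified samples; reference
line from (first sample, 0) to (last sample, total area); onset = the
sample after the earliest global minimum of IP − line. Restricting the
window at the press excludes post-press artifacts and gives the deviation
curve a sharp minimum at burst onset. Variants of this method differ in
window and tie handling; this convention is validated by the noise-free
exactness property (detected onset = true onset within 1 sample at any
amplitude).

Burst windows: samples strictly above mean + 3.5 SD of the rectified
baseline; gaps measured edge-to-edge with strict `< 25 ms` merging; strict
`< 50 ms` duration removal; response-channel windows starting after the
press removed. An all-zero baseline degenerates to threshold 0 (any
nonzero sample starts a run) — documented, not an error.

Last-window validation is the deterministic stand-in for visual
inspection: an epoch is valid when the onset lies within the last
response-channel window, extended by one merge gap (25 ms) before the
window start. The extension is needed because the integrated profile is
deliberately more sensitive than the 3.5-SD threshold, so the true onset
systematically precedes the threshold crossing by a few milliseconds;
without it, about half of clean synthetic epochs would be rejected,
against observed rejection rates of ~2%. Rejected epochs can be exported
as review plots (`--review-dir`).

Partial responses re-use the same window rules on the non-response channel
(no press rule; pre-stimulus windows ignored) and require an
integrated-profile onset, searched from 100 ms before the window to its
end, to land inside the window — the quantitative proxy for "a visually
clear burst", which had no stated operational definition.

## Chronometry and exclusions

PMT = onset, MT = press − onset, so RT = PMT + MT holds exactly for every
fractionated trial; onsets at/after the press or before the stimulus mark
the trial rejected. Chronometric analyses use pure-correct experimental
trials; accuracy analyses all responded experimental trials; partial-error
analyses correct responded experimental trials. No RT trimming is applied
by default (a range hook exists). Participant exclusion (accuracy below
mean − 2.5 SD, or rejected rate > 25%) computes the statistics on the full
candidate sample in a single pass; whether the original rule iterated was
unstated, and single-pass is the conservative reading.

## CAFs

Quantile binning is within participant × block × lexicality cells (the
binning scope was unstated; within-cell is the field convention and
matches per-participant random intercepts), five bins with sizes differing
by at most one, ties broken by row order, cells below five trials falling
back to one bin with a warning. Quantile covariates are orthonormal
linear/quadratic polynomial scores over bin index 1..5.

## Mixed models

Numerics delegate to lme4 through an Rscript subprocess; the package owns
the model specification, the simplification algorithm, contrasts and model
comparison. Gaussian models default to REML; binomial models use Laplace
ML with the bobyqa optimizer and a raised iteration cap. Treatment coding
with neutral/word references reproduces the published parameterization.
Significance is |t| or |z| > 2; LME contrast p-values use the normal
approximation (consistent with the reported z statistics; the exact df
method was unstated).

Random-structure simplification starts from the maximal structure
(by-participant intercept + bias and lexicality slopes; by-item intercept
+ bias slope — items never get lexicality slopes, since lexicality is a
between-item property) and iterates: drop zero-variance terms on converged
fits; on non-convergence, or on boundary-singular fits whose degeneracy
sits in ±1 correlations, drop correlations first, then the
smallest-variance slope; intercepts go last; the first clean converged fit
wins and the removal trail is returned. Uncorrelated structures expand
factor slopes into numeric indicator columns before reaching R, because
lme4's double-bar syntax does not diagonalize factor terms. Simulation
defaults (and the recovery harness) use intercepts-only random structures:
balanced-design fixed-effect recovery does not require slopes and
intercepts keep runtimes at desk scale; the maximal path is exercised on
reduced data in the tests.

Estimated-marginal lexicality contrasts are reported as word − pseudoword
within each bias level (matching the published sign convention: negative =
words faster/lower); with treatment coding these are exact linear
combinations of coefficients. Pairwise bias contrasts offer a Tukey
adjustment via the large-sample studentized-range distribution (flagged
approximate). Bayes factors use BF = exp(−(BIC_with − BIC_without)/2) and
refuse REML fits and mismatched data.

## Numerical and degenerate-input choices

- Onset ties at the deviation minimum: earliest minimum wins.
- Windows are half-open in time; a one-sample run has duration 1 ms at
  1000 Hz.
- Zero-variance detection in simplification uses a relative SD tolerance
  of 1e-4 against the largest random-effect SD.
- Binary measures refuse nonzero residual SDs; all SDs must be ≥ 0; the
  burst amplitude must exceed the baseline noise SD.
- Config loading rejects unknown keys at every level.

## Known limitations

- EDF input is not supported (no EDF reader in the supported dependency
  set); continuous recordings travel as CSV/NPY sample matrices with an
  events TSV.
- The waveform generator does not model spectral shape, electrode
  artifacts, tonic activity or amplitude drift.
- Random-effect defaults are placeholders (see above); recovered fixed
  effects are calibrated, recovered variances are not meant to match the
  original study.
- The Tukey adjustment is asymptotic, not the exact multivariate-t
  computation.
- Partial-correct responses are counted but not modeled, mirroring their
  sparseness in the source data.
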