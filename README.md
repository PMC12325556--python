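# emgchrono

Single-trial EMG response-time fractionation for two-alternative
button-press experiments.

In mental chronometry, a response time (RT) measured from stimulus onset to
a button press mixes decision-related processing with motor-response
execution. When surface EMG is recorded from the muscle producing the press
(e.g., *flexor pollicis brevis* on each thumb), each RT can be split at the
onset of the response-related EMG burst into a **premotor time**
(PMT, stimulus → EMG onset) and a **motor time** (MT, EMG onset → press),
with RT = PMT + MT exactly. The non-response hand's channel additionally
reveals **partial errors**: sub-threshold bursts of the incorrect response
on otherwise correct trials, an index of online response control.

`emgchrono` implements this analysis end to end for a biased visual
lexical-decision design (three blocks: neutral 50/50 word/pseudoword,
word-bias 75/25, pseudoword-bias 25/75; 240 experimental trials analyzed
per block), for psycholinguists and decision-making researchers who want a
reproducible, scriptable version of the pipeline:

- **Preprocessing** — 10 Hz order-2 Butterworth high-pass and 50 Hz notch
  (both zero-phase), epoching from −500 to 2100 ms around stimulus onset,
  baseline statistics on the rectified pre-stimulus signal.
- **Detection** — EMG onset by the integrated-profile method (the sample
  after the global minimum of the cumulative rectified signal's deviation
  from its straight reference line); supra-threshold burst windows at
  3.5 SD above the rectified baseline mean, merged across gaps < 25 ms,
  discarded below 50 ms or when starting after the press; deterministic
  last-window validation replacing visual inspection; partial-response
  tracking on the non-response channel.
- **Chronometry** — RT fractionation, trial classes (pure-correct,
  partial-error-correct, ...), analysis filters, and participant exclusion
  (accuracy < mean − 2.5 SD, or > 25% rejected epochs).
- **Conditional accuracy functions** — 5 RT quantile bins per
  participant × block × lexicality cell, accuracy per bin, orthonormal
  polynomial quantile scores.
- **Inference** — linear (chronometric) and logistic (accuracy, partial
  error) mixed-effects models with crossed participant/item random effects
  fit via lme4, treatment-coded `lexicality (word ref.) × bias (neutral
  ref.)` fixed effects, |t|,|z| > 2 significance, maximal-to-simplified
  random-structure reduction, estimated-marginal lexicality contrasts
  (with optional Tukey correction), and BIC-approximate Bayes factors
  BF = exp(−ΔBIC/2) for nested comparisons.
- **Synthetic data** — a first-class generator producing the design
  tables, trial-level outcomes from a crossed random-effects model whose
  fixed-effect defaults are the published estimates, and raw 1000 Hz
  two-channel EMG epochs (or continuous recordings with event tables)
  whose bursts realize the simulated PMT/MT, so every stage is testable
  without access to the original recordings.

## Worked example

```python
import emgchrono as ec

design = ec.build_design(n_participants=1, seed=0)
trials = ec.simulate_trials(design, seed=1)
trial = trials[~trials.timeout].iloc[0]
print(f"true PMT={trial.true_pmt:.1f} ms  MT={trial.true_mt:.1f} ms  RT={trial.true_rt:.1f} ms")

epoch = ec.render_epoch(trial, rng=2)       # raw 2-channel EMG at 1000 Hz
det = ec.detect_epoch(epoch)                # onset + windows + validation
chron = ec.fractionate(det.onset_ms, epoch.press_time_ms)
print(f"detected onset={det.onset_ms:.0f} ms  valid={det.valid}  partial={det.partial}")
print(f"fractionated PMT={chron.pmt:.0f} ms  MT={chron.mt:.1f} ms  RT={chron.rt:.1f} ms")
```

prints

```
true PMT=577.2 ms  MT=131.3 ms  RT=708.6 ms
detected onset=577 ms  valid=True  partial=False
fractionated PMT=577 ms  MT=131.6 ms  RT=708.6 ms
```

The trial's simulated premotor time is 577.2 ms; the detector places the
burst onset at the correct sample (577 ms), the epoch passes last-window
validation, no covert activation is found on the non-response channel, and
the recovered PMT/MT reproduce the simulated ones to within one sample.

The same flow is available from the shell:

```sh
emgchrono run --config cfg.yaml --seed 1 --out out/
```

runs simulate → detect → fractionate → caf → fit and leaves inspectable
CSV/PNG artifacts (trial tables, detection table, per-measure analysis
tables, CAF table and plot, coefficient/contrast tables) plus a resolved
configuration copy in `out/`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates the full design (46 participants, 240 experimental trials per
block) from the generative defaults, refits the lexicality × bias mixed
models for RT, PMT, MT (gaussian LMEs) and for partial errors on correct
trials (logistic GLME), and writes the across-replicate mean
estimated-marginal word − pseudoword contrasts per bias level (ms for
chronometric measures, log-odds for partial errors) to the given JSON
file. Runs in a few minutes on one CPU.

## Layout

```
src/emgchrono/
  params.py         generative + detection parameter containers, defaults
  synthetic.py      design builder, trial simulator, EMG renderer
  preprocessing.py  filters, epoching, baseline statistics
  detection.py      integrated-profile onset, burst windows, validation
  chronometry.py    fractionation, trial classes, exclusions
  caf.py            quantile binning, CAF tables, polynomial scores
  inference.py      mixed-model specs, fitting, simplification, contrasts
  recovery.py       simulate-and-refit parameter-recovery harness
  io.py, pipeline.py, cli.py   artifact formats and the CLI
```

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
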