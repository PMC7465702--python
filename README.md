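# smrfes

A tested, reusable implementation of a sensorimotor-rhythm (SMR)
brain-computer-interface pipeline with a semi-asynchronous, fixed-sequence
control loop of the kind used to drive functional electrical stimulation
(FES). The package covers the full chain:

1. **`smrfes.synthetic`** — reproducible synthetic EEG sessions (32
   channels, 256 Hz) with motor-imagery structure: 12-s trials
   (rest / reference / imagery / stimulation-init / feedback), two imagery
   classes (slow one-time grasping at 1/3 Hz, fast cyclic opening at 1 Hz),
   mu/beta rhythms with multiplicative ERD, ocular artifacts, and a
   stimulation artifact pulse train. Also provides probabilistic
   `VirtualSubject` decision sources for control-loop testing.
2. **`smrfes.preprocess`** — 60 Hz notch, 1–29 Hz band-pass (zero-phase),
   trial rejection (150 µV amplitude ceiling; entropy/kurtosis z > 3),
   95 %-variance PCA, template-based ICA cleaning (offline only), and a
   discrete small-Laplacian spatial filter.
3. **`smrfes.features`** — seven contiguous 4-Hz sub-bands (1–29 Hz),
   Hamming-windowed periodogram band power on 640-sample segments, ERD/ERS
   relative band power, per-band CSP from trace-normalized class
   covariances, log-variance features, and weighted score fusion.
4. **`smrfes.classify`** — Fisher LDA, least-squares SVM with a quadratic
   kernel, a weighted-majority LDA+SVM ensemble (weights from 10-fold CV),
   stratified cross-validation, within-subject standardization, and the
   exact-binomial "true chance level".
5. **`smrfes.adaptive`** — pooled-mean (PMean) unsupervised bias
   adaptation: `mu_t = (1-eta) mu_{t-1} + eta x_t`, bias `= -w·mu_t`,
   active after a 10-trial warm-up.
6. **`smrfes.fsm`** — the semi-asynchronous control loop: OPEN →
   STOP_FES → break → move → GRAB → move ball → HOLD, with 1-s decision
   windows, SMR→ACT role switching on the same window, a 6-s maximum
   analysis time with auto-trigger, and per-step outcome logging.
7. **`smrfes.metrics`** — completion rate, delay-vs-error semi-asynchronous
   accuracy, Wolpaw information transfer rate, sequential expected accuracy
   of a detect-then-classify cascade, t-ratio arithmetic, and summary-table
   aggregation.
8. **`smrfes.session_io`** — EDF+ session round-trip (own minimal EDF+
   reader/writer with annotations), YAML/JSON configs, model JSON, trial-log
   JSONL, offline training glue, and a model-backed online decoding source.

## CLI

```sh
smrfes simulate --trials 120 --seed 7 -o out/sim          # EDF+ + metadata
smrfes preprocess --session out/sim/session.edf -o out/prep
smrfes train --session out/sim/session.edf --seed 7 -o out/models
smrfes run-online --models out/models/models.json --seed 7 -o out/online
smrfes run-online --subject-config subject.yaml --seed 7 -o out/online
smrfes report --logs out/online/trial_logs.jsonl -o out/report
```

Every command writes a JSON run log (parameters, seed, version) next to its
outputs. `run-online` accepts either trained models (decodes synthesized
EEG windows) or a `VirtualSubject` YAML (probabilistic plumbing).

## Reproducibility

Every generator and training routine is a pure function of its inputs and
an integer seed; the full `simulate → preprocess → train → run-online →
report` pipeline is byte-deterministic under a fixed seed (covered by the
acceptance test suite).
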