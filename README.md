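# somnostage

Automatic sleep stage classification from polysomnographic (PSG) recordings.
The package implements an end-to-end staging pipeline:

- **I/O** — EDF/EDF+ reading (and writing, for fixtures), hypnogram parsing in
  three plain-text dialects, R&K → AASM rescoring (S4 merges into N3), and a
  configurable stage-token map. Stages are the 5-class AASM vocabulary
  `W, N1, N2, N3, REM` plus `UNKNOWN` for unscored epochs.
- **Preprocessing** — zero-phase FIR band-pass 0.3–30 Hz (Hamming windowed-sinc,
  53 dB stopband), per-channel z-scoring, HEOG derivation (left − right EOG),
  and resampling so every 30-s epoch is exactly 2,560 samples (2560/30 Hz).
- **Augmentation views** — signal permutations over (EEG channel | HEOG | both)
  with independent polarity flips; two EEG channels plus EOG yield 14 views.
- **Model** — per-signal 1-D ResNet encoders (epoch → 1,280 features), a
  three-layer mixer/compressor (→ 512), a context-free fully-connected head,
  and a bidirectional-GRU context head, all emitting length-5 log-softmax
  stage distributions. Implemented on a small, gradient-checked NumPy
  reverse-mode autodiff engine (`somnostage.nn`) — no deep-learning framework
  required.
- **Training** — dual-mode loss (context-free + context-aware) from one shared
  forward pass, class-weighted cross-entropy (`W:1, N1:2.4, N2:1, N3:1.2,
  REM:1.4`), contiguous per-PSG batching with a carried (detached) GRU hidden
  state, AdamW, per-epoch validation checkpoints, rank-sum top-k selection and
  checkpoint weight averaging.
- **Inference** — offline bidirectional, forward (streaming / BCI-style via
  `stream_step`), and context-free modes; per-epoch certainty
  (cross-entropy of the output distribution against its own argmax) and
  certainty-based permutation consensus; latent extraction at the mixer and
  both heads' penultimate stages.
- **Metrics** — confusion matrices, multiclass (Gorodkin) MCC, per-stage and
  macro F1, accuracy, Cohen's kappa, stage proportions, transition rate, and
  the light-sleep (N1+N2) merge; per-PSG values with median aggregation.
- **Synthetic PSG generator** — Markov-chain hypnograms and stage-signature
  signals (alpha in wake, theta, spindles/K-complexes, slow oscillations,
  REM eye-movement deflections) so the whole pipeline is testable offline.

## CLI

```bash
# generate synthetic nights (EDF + hypnogram CSV pairs)
somnostage simulate --nights 10 --epochs-per-night 100 --sfreq 128 --seed 0 --out data/

# train (YAML config: montage, model, training sections)
somnostage train --config cfg.yaml --data-dir data/ --out model.ckpt

# score a recording (permutation consensus by default)
somnostage score data/night_000.edf --model model.ckpt --mode bidirectional \
    --out pred.csv --probs probs.csv

# compare against a reference hypnogram
somnostage eval --true data/night_000.csv --pred pred.csv --light-sleep --out report.json
```

Config example:

```yaml
montage:
  eeg: [C3, C4]
  eog: {left: EOG-L, right: EOG-R}
train:
  lr: 3.0e-5
  n_epochs: 20
  batches_per_psg: 128
```

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property/oracle tests (finite-
difference gradient checks of the autodiff engine, brute-force enumeration
and metric oracles), and `tests/test_acceptance.py` with the desk-scale
acceptance criteria. The expensive part is a 3-seed training run of a reduced
model (5 epochs × 50 synthetic nights) shared through a session fixture;
expect roughly 10–15 minutes total on one CPU.

## Notes

- Checkpoints are single-file zip archives (parameters + model config +
  preprocessing fingerprint + version); scoring refuses recordings whose
  preprocessing fingerprint disagrees with the model's.
- UMAP visualization of extracted latents is intentionally left to the user
  (`umap-learn` with `n_neighbors=15, min_dist=0.1` works well on the
  512-length latents); it is not part of the tested core.
- Out of scope: EMG handling, artifact rejection, benchmark-corpus training
  (SHHS/CFS/NCHSDB/WSC/DREEM), and cross-classifier statistical comparisons.
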