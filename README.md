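# sleepgeom

Population-geometry analyses of cortical activity across wakefulness and NREM
sleep, packaged as a tested, reusable pipeline together with a synthetic
session generator that emulates the statistical structure the analyses
assume.

The pipeline covers:

- **Synthetic sessions** (`sleepgeom.synthetic`): deconvolved-event rasters
  (neurons × 43 ms frames) with alternating silence / sound blocks, a
  state-dependent multiplicative response gain with a zero-gain "gated"
  mixture component, low-rank autocorrelated spontaneous dynamics with
  population bursts, controlled overlap between evoked and spontaneous
  subspaces, and 1250 Hz physiological channels (EMG, hippocampal, auditory
  cortex and olfactory-bulb LFP) — with full ground truth for recovery tests.
- **Signal transforms** (`sleepgeom.signal`): neuropil correction, event
  binning and Gaussian smoothing, zero-phase band-pass Hilbert power,
  windowed averages.
- **Sleep scoring** (`sleepgeom.scoring`): two-step automatic scoring
  (EMG/OB-gamma two-Gaussian intersection threshold, then hippocampal
  theta/delta split of sleep into NREM/REM with 3 s bout merging), awakening
  statistics, sigma-band spindle detection (2 SD threshold, 200 ms merge,
  0.4–3 s duration rules), and event-related band-power contrasts.
- **Responses** (`sleepgeom.responses`): trial tables with hypnogram states,
  window-averaged response matrices (stimulus + 250 ms) with 500 ms
  pre-onset baselines, per-sound firing-rate summaries, wake-max rescaling.
- **RSA** (`sleepgeom.rsa`): noise-corrected representational similarity
  within and across states, with split-half reliability normalization,
  identity-shuffled chance, and the 4-way-split ceiling centered at 1.
- **Subspaces** (`sleepgeom.subspace`): cross-validated PCA scree with a
  per-neuron circular-shift null, dimensionality estimation, and the
  spontaneous/evoked inclusion index.
- **Decoding** (`sleepgeom.decoding`): balanced, stratified 5-fold linear
  (SVC) sound-identity decoding scored by weighted F1, with cross-state
  trial-count equalization.
- **Gating** (`sleepgeom.gating`): bootstrap detection of "non-responsive"
  trials (cosine similarity to template responses, neuron bootstrap, 5th–95th
  percentile rule).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the release criteria (RSA ceiling, decoder
chance level, brute-force oracle equivalence, parameter recovery, scoring and
spindle recovery, and the directional wake/NREM quartet).

## CLI

All stages are exposed through one entry point:

```bash
sleepgeom simulate --seed 1 --out runs/demo          # synthetic session
sleepgeom score --physio runs/demo/physio.bin --out runs/demo/hypnogram.csv
sleepgeom spindles --physio runs/demo/physio.bin \
    --hypnogram runs/demo/hypnogram.csv --out runs/demo/spindles.csv
sleepgeom responses --raster runs/demo/raster.h5 --trials runs/demo/trials.csv \
    --hypnogram runs/demo/hypnogram.csv --out runs/demo
sleepgeom rsa --responses runs/demo/responses.h5 \
    --trials runs/demo/trials_scored.csv --mode cross --states wake,nrem \
    --out runs/demo/similarity.csv
sleepgeom decode --responses runs/demo/responses.h5 \
    --trials runs/demo/trials_scored.csv --state wake --out runs/demo/decoding.json
sleepgeom run --config config.yaml --seed 1 --out runs/full   # end to end
```

`sleepgeom run` executes every enabled stage in dependency order and writes a
JSON manifest (parameters, seeds, QC counters, artifact SHA-256 digests);
identical config + seed reproduces identical digests. Exit codes: 0 ok,
2 config error, 3 data error.

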