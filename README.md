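# chromlgn

Silent-substitution stimulus design and a fully synthetic analysis pipeline
for chromatic responses of LGN neurons.

The package covers, end to end:

- **photoreceptors** — Govardovskii A1 opsin sensitivity templates (S, L,
  rod, melanopsin), prereceptoral lens filtering, opsin-effective photon
  flux and Michelson-contrast arithmetic.
- **stimdesign** — a multiprimary "silent substitution" solver that hits
  target opsin contrasts while silencing or minimizing the others, with
  first-principles validation from the emitted spectra, plus square-wave,
  melanopsin-high/low step and rod/L/S white-noise waveform builders.
- **synthdata** — ground-truth model neurons (non-opponent ON/OFF,
  L-ON/S-OFF, S-ON/L-OFF, melanopsin-responsive) and LN-Poisson spike-train
  synthesis for full-field, step, spatial and white-noise sessions.
- **respanalysis** — 100-bin cycle histograms, shuffle-null response
  detection, opponency and melanopsin-response classification, cone
  preference indices and a chi-square periodogram.
- **sta** — spike-triggered averages of rod/L/S contrast sequences with a
  shuffled floor.
- **rfmap** — bar/square receptive-field maps, 1-D/2-D Gaussian center
  fits, RF-based opponency typing, and cone-preference-vs-elevation trends
  with an extra sum-of-squares F-test.
- **retinamodel** — the "random wiring" center-surround model over a
  parametric dorsal-ventral cone-opsin gradient.
- **pipeline** — session orchestration, moving-window anatomical maps,
  confusion matrices against ground truth, and the CLI.

Everything runs on synthetic data; no downloads are required.

## CLI

```sh
chromlgn design-stimuli --out stimuli_out      # solve the stimulus battery
chromlgn analyze --seed 1 --out analyze_out    # full synthetic pipeline
chromlgn sta --seed 1 --out sta_out            # white-noise STA session
chromlgn rf-map --seed 1 --out rfmap_out       # square-mapping session
chromlgn retina-model --out retina_out         # random-wiring sweep
```

`--config PATH` accepts a YAML file overriding the defaults in
`chromlgn.pipeline.DEFAULT_CONFIG`.

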