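# mfxtools

Analysis pipeline for 3D MINFLUX single-molecule localization data:

* **Structural branch** — localization-level corrections (axial
  refractive-index factor, EFO multi-emitter cut), trace quality filters,
  two-step 3D DBSCAN with spherical Gaussian-mixture EM refinement to
  assign one position per labelled protomer, isolation-based trimer
  identification, and per-molecule 3D inter-position ("interblade")
  distance statistics.
* **Tracking branch** — gap-truncated trajectory building, all-pairs
  lag-binned MSD curves with displacement-pair weights, and weighted
  zero-intercept fits of MSD(τ) = 6Dτ over microscopic (5–50 ms) and
  macroscopic (50–350 ms) lag windows, per trajectory and pooled.
* **Statistics** — two-sample KS, F test of variance equality,
  percentile-bootstrap median CIs, Kruskal–Wallis with Dunn's post hoc.
* **Colocalization** — ROI masking from a reference channel (blur +
  fixed threshold), per-ROI Pearson/Spearman intensity correlation, and
  puncta FWHM from 1D Gaussian fits.
* **Synthetic data** — generators for trimer scenes (DNA-PAINT-like
  blinking traces, bimodal EFO, background, labelling dropout), Brownian
  3D trajectories (irregular sampling, dark gaps, static error,
  confinement), and two-channel spot images, so the full pipeline is
  testable without external data.

## CLI

Each subcommand takes an optional YAML config, a seed, and an output
directory; all outputs come with a JSON run manifest recording the
config, versions, and row counts removed at every filter stage.

```sh
mfxtools simulate-scene  --config scene.yaml  --seed 1 --out runs/scene
mfxtools simulate-tracks --config tracks.yaml --seed 1 --out runs/tracks
mfxtools analyze-structure runs/scene/localizations.csv  --seed 1 --out runs/structure
mfxtools analyze-tracks    runs/tracks/localizations.csv --out runs/diffusion
mfxtools coloc ref.tif other.tif --threshold 40 --out runs/coloc
```

Localization tables are CSV/TSV with header
`trace_id,t,x,y,z,efo,valid` (nm, seconds, Hz); Imspector `.mat`
exports (metres) are read with `--dialect imspector-mat`.

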