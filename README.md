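# hdesi

Synthetic high-density EEG (hdEEG) electric source imaging pipeline:

1. **Forward model** — 256-channel-style electrode cap on a three-shell
   concentric-sphere head (brain/skull/scalp, 0.33/0.004/0.33 S/m), a regular
   volumetric source grid (default 5 mm), and an analytic series lead field
   validated against the homogeneous-sphere closed form.
2. **Synthetic data** — spike-and-slow-wave templates, 1/f background noise,
   ground-truthed event injection through the lead field, and spherical
   resection masks for scoring.
3. **Spike detection** — per-channel matched filtering with a logistic
   probability score, probability thresholding (events with probability
   < 0.9 excluded), clustering by the peak-amplitude electrode, and a
   simulated reviewer.
4. **Epoching & averaging** — ±2 s epochs around marks, peak-to-peak artifact
   rejection, cluster averaging, and the 50 % rising-phase sample.
5. **Inverse** — depth-weighted minimum-norm estimation (wMNE) with
   noise-covariance regularization, applied at the half-rise sample; source
   maximum extraction.
6. **Evaluation** — shortest Euclidean distance from the source maximum to
   the resection mask, sublobar/hemispheric concordance against a geometric
   19-regions-per-hemisphere atlas surrogate, and the spike-count
   subsampling experiment (distance of reduced-N averages to the full-average
   maximum and to the mask).

Agreement metrics (sensitivity, positive predictive value, per-rank cluster
success rate, epoch-based Cohen's κ) compare reference marks against
automated and reviewed detections.

## CLI

```bash
hdesi simulate  --config cfg.yaml --seed 1 --out out/   # EDF + events TSV + sfp + lead field
hdesi detect    --edf out/recording.edf --out out/      # detected events TSV
hdesi average   --edf ... --events ... --out out/       # cluster average + half-rise
hdesi localize  --edf ... --events ... --leadfield out/leadfield.h5 --out out/
hdesi evaluate  --source-map out/source_map.tsv --leadfield ... --mask-center 42 --out out/
hdesi subsample --config cfg.yaml --out out/            # spike-count curve
hdesi compare-detection --n-recordings 5 --out out/     # cohort agreement report
hdesi run-all   --config cfg.yaml --seed 1 --out out/   # everything, report.json
```

Configs are YAML mappings of `hdesi.pipeline.PipelineConfig` fields; every
random stage draws from the explicit seed, so reports are byte-identical
across reruns.

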