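# adaptkit

Analysis toolkit for split-belt treadmill locomotor adaptation studies with
functional near-infrared spectroscopy (fNIRS), built around a two-visit
crossover design (two groups, a stimulation ON/OFF condition per visit).

It covers the full path from raw signals to group statistics:

- **Gait events** (`adaptkit.gait`) — zero-lag Butterworth filtering of
  vertical ground-reaction forces, threshold heel-strike detection, and
  step lengths as the anterior–posterior between-heel distance at heel
  strike (body-centred, translation-invariant).
- **Adaptation metrics** (`adaptkit.stride`, `adaptkit.adaptation`) — step
  length asymmetry `SLA = (fast − slow)/(fast + slow)`, baseline adjustment
  (last 30 tied-belt strides), single-exponential fits `y = a·e^{bn} + c`
  by particle-swarm optimization with a bounded least-squares polish, and
  the derived outcomes: window means at Initial (strides 1–5), Early
  (6–30) and Late (last 30) for adaptation/deadaptation, early change,
  adaptation magnitude, after-effect, and visit-to-visit savings.
- **fNIRS pipeline** (`adaptkit.fnirs`) — optical density, modified
  Beer–Lambert conversion (no DPF), robust z spike detection (10
  iterations, 5-s lag, 3.5 threshold, 0.5 influence), TDDR motion repair
  with monotonic spike bridging, short-channel regression (highest
  correlated short channel), 0.01 Hz high-pass + 0.4 Hz Gaussian low-pass,
  z-normalization, double-gamma block GLM, ROI aggregation
  (PMd/PMv/M1/S1/SPL/IPL) and EarlyAdapt−Baseline / ON−OFF contrasts.
  Scalp-coupling indices are reported as QC only (no automatic rejection).
- **Statistics** (`adaptkit.stats`) — random-intercept linear mixed models
  (in-house REML with Satterthwaite degrees of freedom, validated against
  statsmodels MixedLM), Type III ANOVAs, estimated-marginal-mean pairwise
  contrasts with Benjamini–Hochberg FDR within explicit families, Cohen's
  d (pooled-raw and model-SE variants), Pearson correlations, and backward
  stepwise regression.
- **Synthetic cohort** (`adaptkit.synthetic`) — a first-class generator for
  a counterbalanced crossover cohort (default 28 + 20 participants, two
  visits, 1000-stride phases) with known injected effects on *generating*
  parameters, plus block-design fNIRS recordings (60-s rest, paired 30-s
  blocks, HRF-convolved activation, drift, 1.1 Hz cardiac, 0.1 Hz Mayer,
  spikes, shared scalp component with short channels). Every stochastic
  draw's ground truth is stored; generation is bit-reproducible per seed.

## CLI

```sh
adaptkit simulate --out run/simulate --seed 1 --n-pwms 28 --n-hc 20
adaptkit adapt run/simulate/strides.csv --out run --seed 1
adaptkit stats run/outcomes.tsv run/savings.tsv --out run
adaptkit all --out run --seed 1          # full pipeline + report.json
```

`adaptkit all` accepts `--config config.yaml` (keys mirror
`adaptkit.pipeline.RunConfig`). Outputs are plain CSV/TSV/JSON; a
provenance manifest records the config hash and seed, and reruns with the
same config are byte-identical.

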