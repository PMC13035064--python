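# startlescreen

Analysis toolkit for high-throughput acoustic-startle behavioral drug
screens in larval zebrafish, with a synthetic-data generator so every stage
is testable without raw recordings.

The pipeline covers:

- **Assay schedules** — the 60-stimulus drug-screen assay (PPI phase of
  low/high/paired stimuli at 20 s ISIs, then 30 high-intensity stimuli at
  1.5 s ISIs) and the 50-stimulus habituation assay (30 s pre-habituation
  ISIs, 3 s habituation ISIs), with the named stimulus-index windows that
  define every behavioral statistic.
- **Synthetic cohorts** — Bernoulli SLC startle responses calibrated to
  25%/75% design rates, exponential habituation decay by genotype capacity
  and dose-scaled drug shifts, prepulse suppression, latency-separated
  SLC/LLC classes, Gaussian kinematics, non-responder larvae, daily screen
  structure (treated groups + two non-treated control groups), compound
  libraries with target-class annotations, and 3-D ratio stacks with
  planted group-difference blobs.
- **Behavioral metrics** — per-larva initiation percentages, habituation
  and PPI percentages (`100 × (1 − late/first SLC-rate ratio)`), kinematic
  means, the 60%-non-response exclusion rule, and group mean ± SEM.
- **Screen statistics** — control distributions pooled from non-treated
  group averages, z-scores
  `(treated mean − control mean) / control SD` thresholded at the
  one-sided 99% normal quantile (2.326), and one-sided Fisher-exact
  target-class enrichment.
- **Brain mapping** — voxelwise Mann–Whitney z-maps between groups of
  registered ratio volumes, Benjamini–Hochberg FDR masking, ROI signal
  summaries and label enrichment ratios.
- **Quantification utilities** — background-corrected fluorescence
  (`integrated density − ROI area × background mean`, per brain area),
  ELISA replicate averaging, two-locus Punnett expectations, and
  classifier PPV/NPV.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (threshold
constants, design-rate calibration, oracle equivalence against exhaustive
enumeration/permutation oracles, and end-to-end parameter recovery).

## CLI

```sh
startlescreen simulate --assay screen --n-larvae 32 --seed 1 --out events.tsv
startlescreen metrics --assay screen --events events.tsv --out perlarva.tsv --group-out group.tsv
startlescreen score --treated treated.tsv --controls controls.tsv \
    --readout hab_pct_41_50 --direction increase --alpha 0.01 --out z.tsv
startlescreen enrich --hits hits.tsv --library library.tsv --out enrichment.tsv
startlescreen map --group-a a.tif --group-b b.tif --q 0.00005 --out zmap.tif
startlescreen quant punnett --parent1 '+/-;-/-' --parent2 '-/-;+/-'
startlescreen run --config run.yaml            # full pipeline + manifest
```

Every stochastic subcommand requires an explicit `--seed`; `run` writes a
`manifest.json` with the seed, config, and SHA-256 hashes of all outputs,
and two runs with identical manifests are byte-identical.

A minimal `run.yaml`:

```yaml
seed: 7
n_days: 2
compounds_per_day: 14
group_size: 32
class_sizes: {adrenergic: 4, retinoid: 3}
behavior:
  nonresponder_fraction: 0.05
  drug_effects:
    C0001: {habituation_shift: 0.4}
```

## Layout

- `src/startlescreen/schedule.py` — stimulus schedules and windows
- `src/startlescreen/simulate.py` — synthetic cohorts, libraries, stacks
- `src/startlescreen/metrics.py` — per-larva/group behavioral statistics
- `src/startlescreen/screen.py` — z-score hit calling, Fisher enrichment
- `src/startlescreen/brainmap.py` — voxelwise Mann–Whitney maps, FDR, ROIs
- `src/startlescreen/quantify.py` — fluorescence/ELISA/Punnett/PPV-NPV
- `src/startlescreen/io.py`, `config.py`, `pipeline.py`, `cli.py` — I/O,
  run configuration, orchestration, command line
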