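# hifdyn

An ODE model of gene activation under hypoxia that accounts for both
HIF-1 and HIF-2, together with the surrounding analysis pipeline:

- **reaction network** — 15 dynamic species: *HIF1A*/*HIF2A* mRNA
  turnover, translation, oxygen/PHD-dependent Michaelis–Menten
  hydroxylation of the two HIF α proteins, reversible dimerization with
  HIF1B, competitive binding of both heterodimers to two HRE motif
  classes (motif counts act as binding-site totals), and target-gene
  transcription driven by the four HIF–HRE complexes.
- **simulation** — stiff-capable integration under piecewise-constant
  oxygen protocols; derived observables (α-protein totals, free/occupied
  HRE pools, gene fold induction); HIF1B titration and per-gene
  induction prediction from HRE counts.
- **ELISA scaling** — anchor ratios k₁ (HIF1A, 2 h) and k₂ (HIF2A, 8 h),
  the scaling constant m = k₂/k₁ (≈ 5.26), scaled HIF2A series and
  back-inferred absolute concentrations.
- **two-step fitting** — cytoplasmic sub-model first, then the full
  model with cytoplasmic parameters frozen except the three
  HIF2A-involving reactions; bounded log-space least squares with
  seeded multi-start.
- **evaluation** — the goodness-of-fit statistic
  |log₂(mean over timepoints of observed/predicted)|, combined-α
  summaries and observed-vs-predicted tables.
- **synthetic data** — seeded generator emitting datasets in the exact
  training-table layout (multiplicative log-normal noise, blanked gene
  cells), plus parameter-recovery experiments.

All packaged inputs (the 12-timepoint training series, ELISA anchors,
initial conditions, HRE counts 12/18) ship in `hifdyn.datasets`.

## CLI

```sh
hifdyn fixtures fixtures/                  # write packaged input tables
hifdyn scale fixtures/timeseries.tsv -o scaled.tsv
hifdyn simulate --init fixtures/initial_conditions.tsv -o traj.tsv
hifdyn fit-cyto fixtures/timeseries.tsv -o out/cyto
hifdyn fit-full fixtures/timeseries.tsv --cyto-params out/cyto/cyto_params.tsv -o out/full
hifdyn titrate --params out/full/full_params.tsv --levels 1,30,60 -o out/titration
hifdyn predict-gene --params out/full/full_params.tsv --hre1 3 --hre2 4
hifdyn evaluate --observed 2,4,8 --predicted 1,2,4
hifdyn synth --seed 7 -o synthetic.tsv
hifdyn export-sbml -o model.xml            # needs python-libsbml
```

Oxygen protocols are given as `t:level` steps
(`hifdyn simulate --protocol "0:1,24:0.333" ...`); level 1 is the
training hypoxia.

## Layout

```
src/hifdyn/
  network.py     species, reactions, flux laws, ODE right-hand side
  simulate.py    oxygen protocols, integration, titration, prediction
  scaling.py     absolute/relative concentration bridging
  fitting.py     two-step parameter estimation
  evaluation.py  goodness of fit and summaries
  synth.py       synthetic datasets and recovery experiments
  datasets.py    packaged input tables
  io.py          TSV/YAML readers and writers, manifest, run config
  cli.py         command-line entry points
  sbml.py        optional SBML L3 export
```
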