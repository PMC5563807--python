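# mortprof

Age-at-death analysis of cattle dental assemblages: fractional attribution
of teeth to ordinal age classes, per-context mortality profiles with
Dirichlet credible intervals, and correspondence analysis (CA) of stacked
Dirichlet deviates with husbandry reference profiles projected as
supplementary points. A synthetic-assemblage generator makes the whole
pipeline testable without archaeological data.

## How it works

1. **Records → counts** (`io_model`, `age_attribution`). Each row of a
   tooth-record CSV is a single tooth (context, tooth type, wear stage,
   optional crown measurements). A wear-stage map sends each
   (tooth, stage) pair to a contiguous run of age classes; a tooth
   admissible in several classes is split among them in proportion to the
   time each class contributes to the run's age interval, so fractional
   splitting conserves tooth counts exactly. The default scheme has seven
   classes (0–6, 6–15, 15–26, 26–36 months, 3–6, 6–8, >8 years); the
   open-ended last class is given a nominal 24-month length for splitting.
2. **Counts → profiles** (`profiles`). Per-context proportions with
   equal-tailed credible intervals from `nsim` draws of
   Dirichlet(n + α₀) (defaults α₀ = 0.5, nsim = 2000, level 95%).
3. **Profiles → ordination** (`ca`). The per-context deviates are stacked
   into one active matrix and analysed by CA implemented from first
   principles (SVD of the standardized-residual matrix). Reference
   husbandry profiles and per-context mean profiles are projected as
   supplementary points and contribute nothing to the inertia. A
   Table-style summary reports masses, coordinates and contributions in
   per-mille, and contexts are classified by nearest reference in the
   F1–F2 plane.
4. **Simulation** (`synthetic_data`, `reference_models`). Assemblages are
   drawn multinomially from a named reference profile, emitted as wear
   stages (optionally ambiguous multi-class stages), and written in the
   same CSV dialect the reader consumes, together with a truth table for
   recovery experiments.

The shipped wear-stage map and the four reference profiles
(PostLactation1/2, IntenseMilk, Meat) are **schematic fixtures**: they
have the right qualitative shapes but are not transcriptions of any
published scoring table or assemblage. Supply your own files to analyse
real material.

## CLI

```sh
# synthetic dataset: 27 contexts cycling over the four schematic models
mortprof simulate --n-contexts 27 --n-teeth 42 --ambiguity 0.3 \
    --seed 1 --outdir out/sim

# per-context mortality profiles with credible intervals (CSV + SVG panels)
mortprof profile --records out/sim/tooth_records.csv --seed 1 --outdir out/prof

# CA of stacked deviates; references enter as supplementary (open markers)
mortprof ca --records out/sim/tooth_records.csv --seed 1 --outdir out/ca

# nearest-reference table from the prior `ca` run
mortprof classify --ca-dir out/ca
```

All randomness flows from `--seed`; per-context streams are derived from
(seed, context index), so re-runs are byte-identical and adding a context
does not perturb the others. Every command writes a `provenance.json`
echoing its configuration. `--scheme`, `--stage-map` and `--references`
override the shipped defaults.

## Layout

```
src/mortprof/
  io_model.py          tooth records, schemes, stage maps, readers/writers
  age_attribution.py   fractional splitting, per-context count tables
  profiles.py          Dirichlet deviates, credible intervals, profile plots
  ca.py                correspondence analysis, supplementary projection,
                       axis summaries, nearest-reference classification
  reference_models.py  named husbandry profiles (schematic defaults)
  synthetic_data.py    seeded assemblage/dataset simulation
  cli.py               `mortprof` command group
  data/                scheme + demo stage map + schematic references
tests/                 unit, property (hypothesis) and acceptance suites
scripts/acceptance.py  acceptance report (see above)
```
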