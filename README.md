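# replifork

Strand-specific nascent-strand sequencing analytics for replication-origin
firing and fork progression, plus a stochastic S-phase simulator that
generates every input with known ground truth.

The package analyses two kinds of aligned, strand-specific read data:

* **Okazaki-fragment reads** (BED6 or BEDPE) — per-origin productive-firing
  efficiency (the *origin efficiency metric*, OEM), origin-anchored
  strand-bias profiles, between-condition delta profiles and paired tests,
  max-normalised meta-coverage around early origins, fork-front positions,
  and coverage-similarity timepoint matching between conditions.
* **Ribonucleotide 5′-end reads** (BED6, single-base) — restriction-site
  (SbfI) normalised genome-wide ribonucleotide density with configurable
  chromosome exclusions, origin-anchored ribo strand bias, and a
  polarity-matched comparison against the Okazaki strand-bias change that
  tests for polymerase take-over on the lagging strand.

The simulator models per-origin firing competence, truncated-normal firing
times, constant-speed bidirectional forks with passive replication and exact
termination at fork-meeting points, Okazaki fragments tiling lagging strands,
polymerase-specific ribonucleotide incorporation (leading-strand Pol ε,
lagging-strand Pol δ, fragment-5′-biased Pol α, optional rerouting), SbfI
loading-control reads, and a global depletion factor scaling competence
and/or fork speed.  An independent probability-calculus oracle
(`expected_oem_oracle`) predicts per-origin OEM without sampling, so every
pipeline statistic is verified by parameter recovery.

## Key conventions

* Coordinates are 0-based, half-open (BED) throughout; Watson = `+`,
  Crick = `-`.  Crick-mapped Okazaki fragments mark rightward-moving forks.
* `OEM = W_L/(W_L+C_L) − W_R/(W_R+C_R)` over ±10 kb flanks (fragment
  midpoints, left flank `[mid−flank, mid)`, right `[mid, mid+flank)`);
  undefined (NaN, excluded from aggregates) when either flank is empty.
* Fragments are binned by midpoint, so coverage totals conserve read counts.
* Strand-bias profiles pool counts across origins before taking fractions.
* Meta-coverage is normalised by the single global maximum, so a fully
  replicated ±20 kb window is a flat line at exactly 1.0.

## Command line

```sh
replifork simulate    --config sim.yaml --out outdir [--seed N]
replifork oem         --genome g.chrom.sizes --origins origins.bed \
                      --fragments okazaki.bed [--fragments-b other.bed] --out outdir
replifork profile     --genome ... --origins ... --fragments ... \
                      [--fragments-b ...] --halfwidth 10000 --bin 100 --out outdir
replifork progression --genome ... --origins ... --fragments ... \
                      [--min-oem 0.4 | --top-n 50] [--mode stranded] --out outdir
replifork hyden       --genome ... --origins ... --ribo hyden.bed \
                      --sbfi-sites sites.bed [--exclude-chrom chrXII] --out outdir
replifork match       --genome ... --fragments-a t1.bed --fragments-a t2.bed \
                      --fragments-b u1.bed --fragments-b u2.bed --out outdir
```

Every command writes TSV outputs with a commented header naming units and
conventions, plus a `config_echo.yaml` with the fully resolved configuration;
runs are pure functions of (inputs, config, seed).  A simulation config looks
like:

```yaml
genome: {chrI: 150000}            # or a path to a chrom-sizes TSV
origins:                          # or a path to a BED file
  - {chrom: chrI, start: 34900, end: 35100, id: early}
model:
  competence: [0.9, 0.6]          # scalars broadcast over origins
  firing_mean: [5.0, 12.0]        # minutes
  firing_sd: 2.0
  fork_speed: 1500.0              # bp/min
  fragment_rate: 1.0              # Okazaki fragments per lagging-strand kb
  ribo_rate_pol_eps: 1.0          # ribos per nascent kb, per polymerase
  sbfi_sites: [[chrI, 20000]]
  depletion: 1.0                  # multiplies competence and fork speed
sample_time: 25.0
n_cells: 500
sbfi_depth: 200.0
seed: 1
```

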