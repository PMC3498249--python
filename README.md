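# forestrec

Forest-recovery assessment from paired plot censuses.

The core quantity is a size-aware recovery index: the mean of the
quantitative Bray-Curtis similarities of species composition computed
separately on per-species stem counts and on per-species basal areas.
Unlike proportionate indices (Morisita-Horn, abundance-based
Chao-Jaccard — both included as comparators), it distinguishes a
recovering stand from a reference stand with the same relative
composition but different stem numbers or size structure.

Around the index the package provides the full assessment workflow:

- **`census_io`** — data model and CSV/TSV readers/writers for plot
  censuses (per-species stem counts + summed basal area) and plot
  metadata (pair membership, gap/control/reference treatment, area).
- **`similarity`** — quantitative Bray-Curtis (similarity orientation),
  the combined density+basal-area recovery index, Morisita-Horn, and
  abundance-based Chao-Jaccard (bias-corrected by default, uncorrected
  variant available).
- **`recovery`** — temporal (pre-gap vs post-gap) and spatial (post-gap
  vs post-control) comparisons normalized by the maximum-attainable
  similarity (pre/post-control and pre-gap/pre-control respectively),
  percent-of-maximum recovery, paired t-tests, and baseline inter-plot
  variability among reference plots.
- **`community_stats`** — importance values
  (IV = (relative density + relative basal area)/2), paired gap-vs-control
  change tests (stem density, species density, endemic density, basal
  area in m² ha⁻¹, with optional species exclusion), and individual-based
  rarefaction (analytic hypergeometric + seeded resampling mode).
- **`indicator`** — Dufrêne-Legendre indicator species analysis
  (IndVal, 0–1 scale) with Monte Carlo or exact permutation p-values.
- **`synthetic_data`** — seeded generator of paired gap/control censuses
  with size-biased disturbance mortality, pioneer recruitment and an
  optional alien invader, plus single-census reference plots.
- **`cli`** — `forestrec` command with subcommands
  `similarity`, `assess`, `baseline`, `iv`, `change-tests`, `rarefy`,
  `indval`, `simulate`.

## CLI quick start

```sh
# generate a synthetic paired-census dataset
forestrec --no-timestamp simulate --seed 7 --out-prefix demo

# temporal + spatial recovery assessment with the combined index
forestrec --no-timestamp assess --census-table demo_census.csv \
    --meta-table demo_meta.csv --mode both --index tanner --out assess.csv

# importance values for the post-disturbance gap plots
forestrec --no-timestamp iv --census-table demo_census.csv \
    --meta-table demo_meta.csv --plots G1,G2,G3,G4 --census post --out iv.csv

# indicator species analysis, gap vs control
forestrec --no-timestamp indval --census-table demo_census.csv \
    --meta-table demo_meta.csv --census post --permutations 999 --seed 1 \
    --out indval.csv
```

All output CSVs start with `#` header lines (tool version, seed, input
checksums); `--no-timestamp` suppresses the timestamp line so re-runs are
byte-identical. Exit codes: 0 ok, 1 data/validation error, 2 usage error.

## Library quick start

```python
from forestrec import SimConfig, simulate, assess_recovery

collection = simulate(SimConfig(seed=7))
a = assess_recovery(collection, "temporal", "tanner")
print(a.mean_observed, a.mean_maximum, a.percent_of_maximum)
```

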