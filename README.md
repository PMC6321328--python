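# cliffscape

Activity-landscape analysis for compound series tested against one or two
biological targets — built for medicinal and computational chemists who want
to know, before trusting a QSAR model or picking the next analog, whether
their structure–activity relationship is smooth or riddled with activity
cliffs, and which structural changes flip selectivity between two targets
(for example the epigenetic pair G9a / DNMT1 in dual-inhibitor programs).

## What it computes

For a table of n compounds (SMILES + pIC50 per target), all n(n−1)/2
unordered pairs are compared:

- **SAS map** — structural similarity `sim(i,j)` (Tanimoto over MACCS,
  ECFP4, or 881-bit PubChem-style keys) on the X-axis vs the absolute
  activity difference `|A_i − A_j|` (log units) on the Y-axis, for one
  target.  Thresholds `t_sim` (default: the dataset's mean pairwise
  similarity per fingerprint) and `t_act` (default 1 log unit) cut the map
  into four regions: **activity cliff** (high sim, large ΔA), **smooth SAR**
  (high, small), **similarity cliff** / scaffold hop (low, small), and
  **not descriptive** (low, large).
- **SALI** — the structure–activity landscape index
  `SALI(i,j) = |A_i − A_j| / (1 − sim(i,j))`,
  which scores cliff severity and colors the maps green → red.
- **Consensus region counts** — per-region counts are computed for each
  fingerprint scheme and averaged (rounded to nearest) into a consensus row,
  since no single fingerprint's similarity scale is authoritative.
- **Activity-cliff generators** — compounds ranked by their share of
  activity-cliff pair memberships (normalized to sum to 1), plus a
  cross-fingerprint mean-rank consensus.
- **DAD map** — for two targets X and Y, `|ΔA_X|` vs `|ΔA_Y|` per pair,
  labeling each pair **DUAL**, **SELECTIVE_X**, **SELECTIVE_Y**, or
  **SILENT**; selective labels flag potential selectivity switches.
- **Synthetic analog series** — a scaffold + R-group generator with additive
  per-target activity contributions, Gaussian noise, and deliberately
  injected cliffs/switches, so every stage can be validated against known
  ground truth.

## Worked example

```python
from cliffscape import (
    build_sas_map, build_dad_map, summarize_regions,
    default_series_spec, generate_series,
)

table, truth = generate_series(default_series_spec(seed=7))
sas = build_sas_map(table)          # MACCS + ECFP4 + PubChem-style, auto thresholds
print(summarize_regions(sas, "G9a").to_dataframe().iloc[:, :4].to_string(index=False))
```

```
target fingerprint  ACTIVITY_CLIFF  ACTIVITY_CLIFF_pct
   G9a       MACCS             230                18.8
   G9a       ECFP4             192                15.7
   G9a     PUBCHEM             224                18.3
   G9a   Consensus             215                17.6
```

About 18% of the 1225 pairs of this synthetic 50-compound series are
activity cliffs for the first target — a rough landscape (large R-group
effects plus five injected 2.8-log-unit cliffs around the designated
generator, compound 12) — while the same analysis for the second target
yields ~2%, a smooth landscape safe for additive QSAR.  The DAD map labels
524 pairs `SELECTIVE_X` (seed 7), including every injected switch pair.

The scripts in `examples/` walk through each capability end to end
(`01_synthetic_series.py`, `02_sas_map.py`, `03_cliff_generators.py`,
`04_dad_map.py`); each prints the numbers it computes and what they mean.

## Command line

```bash
cliffscape synth --seed 7 --out run/          # series.csv + ground_truth.json
cliffscape sasmap --input run/series.csv --out run/sas
cliffscape dadmap --input run/series.csv --targets G9a --targets DNMT1 --out run/dad
cliffscape generators --input run/series.csv --out run/gen
```

All tabular outputs are UTF-8 CSV (summaries also JSON); plots are PNG.

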