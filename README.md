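# fissionfusion

Multi-level social-network analysis of fission–fusion association data, built
for longitudinal field studies of individually identified animals (the
motivating system is adult female Asian elephants surveyed over five seasons,
but nothing in the code is species-specific).

In a fission–fusion society the parties observers encounter in the field
change composition from day to day, while deeper affiliations persist over
seasons and years. This package takes raw sighting records — one row per
identified individual per group encounter per day — and quantifies social
structure at three levels:

- **Dyads**: per-season association matrices using the Simple Ratio Index,
  `SRI = X_AB / (X_t − X_n)`, where `X_AB` counts sampling days a pair spent
  together, `X_t` the total sampling days, and `X_n` the days neither was
  seen; "fill" permutation tests of nonrandom association (preserving each
  individual's sighting-day count and the daily group-size distribution);
  Mantel tests between seasons; and K-means clustering of temporal SRI
  trajectories (correlation distance, K chosen by BIC) into stable (A),
  single-peak (B), and cyclic (C) bond types.
- **Ego-networks**: top-n companion ranking and the companion-slot statistic
  `f_i(m) = k_i(m)·m/(S·n)` (the fraction of an individual's `S·n` companion
  slots held by her m-season associates, against the analytic
  random-reshuffle null); companion turnover; and the classical ego measures
  Size, Ties, Pairs, Density, 2-Step Reach with a day-resampling bootstrap
  for between-season comparison.
- **Population**: Girvan–Newman community detection swept over an SRI
  threshold grid, yielding *network structure curves* (mean cluster count vs
  threshold, with maximum modularity Q_max per threshold) and Mann–Whitney
  localization of their slope changes.

A synthetic data generator (`fissionfusion.synthetic`) plants latent social
units that fission into small parties, fuse across units with season-specific
probability, and are observed through group-level detection. It carries
analytic ground truth (per-dyad co-occurrence probabilities, unit
memberships), so every stage of the pipeline is validated end-to-end against
known structure.

## Worked example

```python
import datetime as dt
import fissionfusion as ff

rows = [
    ("2007-01-01", "g1", ["KAM", "KAN", "KAR"]), ("2007-01-01", "g2", ["T71"]),
    ("2007-01-02", "g1", ["KAM", "KAN"]), ("2007-01-02", "g2", ["KAR", "T71"]),
    ("2007-01-03", "g1", ["KAM", "KAN", "KAR", "T71"]),
    ("2007-01-04", "g1", ["KAM"]), ("2007-01-04", "g2", ["KAN"]),
    ("2007-01-05", "g1", ["T71"]),
]
records = [
    ff.SightingRecord(dt.date.fromisoformat(d), g, m)
    for d, g, members in rows for m in members
]
table = ff.SightingTable.from_records(records)
daily = ff.aggregate_daily(table, exclude_lonely_singletons=False)
matrix = ff.compute_sri(daily)
print(matrix.to_long_frame().round(3).to_string(index=False))
```

prints

```
id_a id_b  sri  x_ab  x_t  x_n
 KAM  KAN 0.75     3    5    1
 KAM  KAR 0.50     2    5    1
 KAM  T71 0.20     1    5    0
 KAN  KAR 0.50     2    5    1
 KAN  T71 0.20     1    5    0
 KAR  T71 0.50     2    5    1
```

KAM and KAN shared a (merged) group on 3 of the 4 sampling days on which at
least one of them was seen, so their SRI is 0.75 — they spend roughly three
quarters of their observable time together. `ff.estimate_sri_uncertainty(daily)`
adds a delete-one-day jackknife standard error per dyad.

## The analysis series

The `analysis/` scripts run the full study on the bundled synthetic
population (24 latent units, ~200 individuals, five seasons with a dry-season
fusion boost) and write small tables under `results/`:

| script | output |
|---|---|
| `01_simulate_study.py` | data summary per season, cohort sizes |
| `02_association_structure.py` | SRI summaries + jackknife uncertainty |
| `03_permutation_inference.py` | fill-permutation and Mantel tests |
| `04_dyad_trajectories.py` | trajectory typing (A/B/C) with BIC K-selection |
| `05_companionship.py` | companion slots F(m) vs null, turnover, trade-off |
| `06_ego_networks.py` | ego statistics with day bootstrap |
| `07_population_structure.py` | structure curves, slope changes, unit recovery |

Run them in order from `analysis/` (e.g. `python 01_simulate_study.py`).
On the bundled study, all five seasons test significantly nonrandom (fill
permutations, p ≈ 0.005 at 200 permutations), matched seasonal SRI matrices
correlate at r ≈ 0.65–0.74, observed long-term companion slots far exceed the
reshuffle null (22.1% vs 0.006% for this cohort size), and the network
structure curves are peaked with the partitions at the peak recovering the
planted units at ≥ 0.98 pairwise agreement.

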