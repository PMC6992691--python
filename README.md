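# lcscreen

Rapid, range-based screening of plant species for likely **Least Concern
(LC)** Red List status — with assessment documentation generated in the
IUCN SIS Connect multi-CSV exchange format.

Most of the world's plant species have never been assessed for the IUCN
Red List, and a large majority of them are expected to be non-threatened.
`lcscreen` is for conservation practitioners and Red List assessors who
want to triage long species lists: flag the species whose geographic
range statistics make Least Concern likely, document those automatically
for batch upload, and concentrate expert time on the rest.

## What it computes

Given a species binomial, the pipeline:

1. resolves the name against a pluggable taxonomic backbone
   (exact / fuzzy / higher-rank match, with confidence scores);
2. retrieves the taxon's **native** and introduced range as WGSRPD
   Level-3 "botanical country" codes from a pluggable checklist provider;
3. fetches georeferenced, issue-free occurrence records (capped between
   1,000 and 10,000, default 3,000) or takes user-supplied points;
4. discards every record outside the native Level-3 polygons — the key
   cleaning step, since aggregated occurrence data do not distinguish
   native from introduced occurrences and raw metrics overestimate range;
5. computes four range statistics from the retained points, projected
   with a per-species cylindrical equal-area projection:

   | statistic | definition | LC threshold (default) |
   |---|---|---|
   | EOO | area of the minimum convex polygon, km² | ≥ 30,000 |
   | AOO | occupied 10 km × 10 km grid cells × 100 km² | ≥ 3,000 |
   | RecordCount | unique coordinate pairs in the native range | ≥ 75 |
   | TDWGCount | native Level-3 regions containing ≥ 1 point | ≥ 5 |

6. flags the species *likely Least Concern* iff **all four** statistics
   meet or exceed their (adjustable) thresholds and no warning was raised.

The 10-km AOO cell is a deliberate coarsening of the 2-km IUCN reference
scale to absorb georeference error; it is a screening statistic, not an
assessment-grade AOO. The screen is range-based only: range-wide declines
(criteria A–E triggers) must still be judged by the assessor, which is why
bundles are only written after explicit acceptance (`--accept-lc`).

Thresholds can be calibrated with `lcscreen.sweep_all`, which re-scores
species of known Red List category over a grid of candidate thresholds,
one parameter at a time, and reports confusion-matrix accuracy, TPR and
FPR per grid value.

## Worked example

```bash
lcscreen fixtures demo --seed 0       # write an offline demo world
lcscreen single "Aloe zebrina" --fixtures demo
```

prints

```
species: Aloe zebrina  (checklist id 530536-1)
  EOO_km2         4988186.0  threshold    30000.0  PASS
  AOO_km2           23600.0  threshold     3000.0  PASS
  RecordCount         240.0  threshold       75.0  PASS
  TDWGCount             8.0  threshold        5.0  PASS
likely Least Concern: True
```

The demo species' native-filtered points span eight Level-3 regions with a
convex hull of ~5.0 million km² and 236 occupied 10-km cells (23,600 km²),
so every gauge passes and the species is proposed as Least Concern; ten
points planted in an introduced region were excluded before any statistic
was computed. `lcscreen batch demo/names.csv --fixtures demo --out-dir out
--accept-lc` screens a whole list, writes `results.csv` (one row per input
name, with warnings for synonyms/unmatched names) and exports the seven
linked assessment CSVs plus the point file for the LC subset. The
`examples/` directory contains narrative scripts for each capability.

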