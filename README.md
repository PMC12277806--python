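# mtscreen

Analytics for plate-based 3D microtissue drug screens, built around a
cytokine-reduction readout: percent-decrease scoring against vehicle
controls, viability exclusion by microtissue diameter, negative-control-
anchored hit thresholds, Z′-factor assay QC, hit ranking and cross-platform
intersection — plus longitudinal net-death statistics for survival imaging,
differential-secretome statistics (log2FC, unpaired t, Benjamini–Hochberg
q-values) and cell-type composition comparisons over time.

A synthetic-data module generates screens, survival series and composition
tables with known ground truth, so the whole pipeline is testable end to end
without external data. All generators are deterministic given their seed.

## Layout

| module | what it does |
| --- | --- |
| `mtscreen.screen_data` | well/dataset domain types, layout validation, CSV I/O |
| `mtscreen.synthetic_screen` | seeded generators with configurable effect sizes, noise, toxicity |
| `mtscreen.assay_qc` | control summaries, Z′-factor (log scale by default) with verdicts |
| `mtscreen.hit_calling` | percent decrease, viability filter, thresholds, hits, ranking, intersection |
| `mtscreen.survival_kinetics` | net death, trajectory AUC, decay fits, pairwise comparisons (Šídák/BH) |
| `mtscreen.secretome_diff` | log2FC, unpaired t (pooled/Welch), BH q-values, volcano tables |
| `mtscreen.composition_stats` | marker proportions and per-(marker, timepoint) group tests |
| `mtscreen.cli` | `mtscreen` command line tying the stages together |

## CLI

Every subcommand writes its outputs plus a `manifest.json` recording the
parameters, seed and input checksums. Thresholds, tolerance and floor values
are repeated in every report.

```sh
# simulate a 190-compound dual-platform screen with ground truth
mtscreen simulate-screen --seed 7 --out screen_out

# Z'-factor QC of positive vs vehicle separation
mtscreen qc --screen screen_out/screen.csv --out qc_out

# score, viability-filter, threshold and rank (top 15 by default)
mtscreen call-hits --screen screen_out/screen.csv --floor 15 --tolerance 0.2 \
    --k 15 --out hits_out

# Venn-style intersection of two platforms' hit tables
mtscreen intersect --a sm_hits.csv --b spheroid_hits.csv --out venn_out

# survival series -> net death + pairwise Šídák-adjusted comparisons
mtscreen simulate-survival --seed 1 --out surv_out
mtscreen survival --input surv_out/survival.csv --out death_out

# differential secretome (wide CSV + sample->group map)
mtscreen diff --input wide.csv --groups groups.csv --out diff_out

# composition proportions and genotype comparisons
mtscreen simulate-composition --sampling multinomial --decline 0.1 --out comp_out
mtscreen composition --input comp_out/composition.csv --out compstats_out
```

## Conventions

- Concentrations in pg/mL, diameters in μm, doses in μM (the LPS positive
  control records its dose in μg/mL in the same column by convention).
- Percent decrease = 100 × (1 − value / vehicle mean); hits require a
  *strict* exceedance of the threshold.
- Hit thresholds come from the negative control's percent decrease with a
  configurable floor (default 15%); the provenance (negative control vs
  floor) is reported per platform × analyte.
- Viability exclusion removes compounds whose diameter falls below
  (1 − tolerance) × reference mean (default tolerance 0.2, vehicle
  reference); missing diameters are flagged unknown, not excluded.
- BH significance is inclusive: q ≤ 0.05.

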