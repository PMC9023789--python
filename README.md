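# celldiv

Sample-level cell type diversity analysis for single-cell composition data.

`celldiv` summarizes each sample's cell type composition with a single
normalized-entropy statistic

```
Es = (-Σ_i p_i · log(p_i)) / log(k) - 1
```

where `p_i` are the sample's cell type proportions over a fixed panel of
`k` types. `Es` ranges over `[-1, 0]`: `0` for a perfectly even
composition, `-1` when every cell belongs to one type. Because the
normalization uses the panel size, the statistic is comparable across
samples and across panel resolutions (e.g. 12 subtypes vs 2 lineages).

The package covers the full workflow:

- **composition** — count per-cell annotation tables into sample × cell-type
  matrices, normalize to proportions, and aggregate a fine panel into a
  coarser one via a fine→coarse hierarchy mapping (totals are conserved).
- **diversity** — the `Es` statistic per proportion vector and per sample.
- **group_stats** — one-way ANOVA across sample groups plus pairwise
  two-sample t-tests (pooled or Welch; optional Holm / Benjamini-Hochberg
  adjustment; all-pairs or reference-vs-rest contrasts).
- **synthetic_data** — Dirichlet-multinomial cohort simulation with
  per-sample seeded streams, a bundled 4-group PBMC-like preset
  (12/26/14/14 samples, 12 subtypes collapsible to 2 lineages), and a
  Monte-Carlo calibration/power experiment helper.
- **cli** — `simulate`, `diversity`, `compare`, and `plot-composition`
  subcommands operating on plain CSV/TSV files.

## Quick start

```sh
# simulate a 66-sample, 12-type cohort with group structure
celldiv simulate --preset paper-shaped --seed 1 --write-cells --outdir demo

# per-sample diversity at both resolutions
celldiv diversity --cells demo/cells.csv --hierarchy demo/hierarchy.csv \
    --resolution subtype --resolution lineage --outdir demo

# ANOVA + pairwise t-tests + boxplots across the four groups
celldiv compare --diversity demo/diversity_subtype.csv \
    --diversity demo/diversity_lineage.csv \
    --metadata demo/metadata.csv --outdir demo

# stacked per-sample proportion bars
celldiv plot-composition --counts demo/counts.csv \
    --metadata demo/metadata.csv --out demo/composition.png
```

Input formats (CSV or TSV, extension-sniffed):

- cell table: columns `cell_id, sample_id, cell_type` (names configurable
  in the library API);
- count matrix: first column `sample_id`, one integer column per type;
- hierarchy: two columns `fine, coarse` with a header;
- sample metadata: two columns `sample_id, group` — group order in the
  file drives pair enumeration and plot ordering.

From Python:

```python
import celldiv

cells = celldiv.read_cell_table("cells.csv")
comp = celldiv.count_composition(cells)
div = celldiv.diversity_per_sample(celldiv.to_proportions(comp), "subtype")
result = celldiv.compare_groups(div, celldiv.read_sample_groups("metadata.csv"))
```

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for
the statistic's invariants (range, permutation and log-base invariance,
monotonicity in evenness), and `tests/test_acceptance.py` with end-to-end
checks including type-I-error calibration of the ANOVA under a null
Dirichlet-multinomial simulation.

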