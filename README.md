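# bloodmirna

Which blood cells do circulating miRNAs come from? Disease studies routinely
measure miRNA levels in whole blood, but interpreting them requires knowing
how much each hematopoietic lineage — platelets, T-cells, B-cells,
granulocytes, erythrocytes — contributes to the blood's miRNA content.
`bloodmirna` is a tested Python pipeline for that cross-lineage accounting
from hybridization-count miRNA profiles and capillary-electrophoresis RNA
size traces:

- **Normalization** — per-sample scaling to the cohort mean of top-100
  geometric means, then background subtraction at `mean + 2·SD` of the
  negative-control probes (with a configurable override for lineages with
  anomalous negative controls, e.g. erythrocytes).
- **Relative abundance & detection** — per-probe fractions of total counts,
  lineage rankings, top-n unions, and detection/expression-class summaries
  (low < 10, high > 5,000 counts).
- **Mass budget** — total RNA per cell (ng × 10⁶ / cells), miRNA fraction
  of total RNA from electropherogram area-under-curve fractions
  (< 150 nt of the total-RNA trace × < 40 nt of the small-RNA trace), and
  miRNA mass per µl of blood (fg/cell × cells/µl × 10⁻³).
- **Blood-volume apportionment** — each miRNA's blood mass split across
  lineages, `share_c(m) = 100 · f_c(m)·μ_c·n_c / Σ_c' f_c'(m)·μ_c'·n_c'`
  (f = lineage-average relative abundance, μ = miRNA fg/cell, n = cells/µl);
  every row conserves 100% before display rounding.
- **Differential expression** — per-probe Welch one-way ANOVA
  (unequal-variance, Welch–Satterthwaite df) on log2(x+1), Benjamini–
  Hochberg FDR at q < 0.05, and studentized-range post-hoc tests (Tukey HSD
  when a miRNA is present in all lineages, Student–Newman–Keuls when absent
  in one or more) to assign miRNAs to lineage-specific DE lists.
- **Normalizer selection** — model-based stability values (Andersen-style
  inter/intra-lineage decomposition with shrinkage) and coefficient of
  variation, ranked side by side, plus the `2^−ΔCt` transform for qRT-PCR
  validation.
- **Clustering** — complete linkage on 1 − Pearson correlation over the
  union of each lineage's top-20 miRNAs, with Newick export and log-ratio
  heatmap matrices.
- **Synthetic studies** — a generator that emulates the full study design
  (5 donors × 5 lineages, 623 endogenous probes + negative controls,
  planted lineage markers and stable normalizers, two-component
  electropherograms with known mass fractions) so every stage is testable
  against ground truth.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

```python
import bloodmirna as bm

# a full synthetic study with planted ground truth
cfg = bm.default_config(seed=1)
matrix, truth = bm.generate_count_dataset(cfg)

proc = bm.normalize_pipeline(matrix)          # top-100 geomean + background
abund = bm.relative_abundance(proc)
budget = bm.build_mass_budget(
    bm.generate_cell_records(seed=1), bm.generate_study_traces(seed=1)
)
print(budget.table[["mirna_fg_per_cell", "mirna_pg_per_ul_blood"]].round(2))
shares = bm.apportion_blood_shares(abund, budget)
de = bm.de_by_cell_type(proc)
print("DE probes at q<0.05:", de.n_de)
```

prints

```
             mirna_fg_per_cell  mirna_pg_per_ul_blood
platelet                  0.05                  16.86
T-cell                    3.29                   3.56
B-cell                    3.17                   0.64
granulocyte              10.27                  50.41
erythrocyte               0.04                 186.05
DE probes at q<0.05: 31
```

— per-cell miRNA mass is ~100-fold higher in nucleated cells, yet
erythrocytes dominate the per-volume contribution
(erythrocyte > granulocyte > platelet > T > B) because of their sheer
number; 31 probes come out differentially expressed, recovering the
generator's planted lineage markers. `shares.rounded()` gives the
per-miRNA percentage table (each row ≈ 100%).

The same flow is scriptable from a shell:

```sh
bloodmirna simulate --seed 1 --outdir sim/
bloodmirna normalize sim/counts.csv sim/samples.csv --outdir norm/
bloodmirna abundance norm/processed.csv sim/samples.csv --outdir ab/
bloodmirna budget sim/cell_records.csv --traces-dir sim/ \
    --abundance ab/cell_type_abundance.csv --outdir budget/
bloodmirna de norm/processed.csv sim/samples.csv --outdir de/
bloodmirna stability norm/processed.csv sim/samples.csv --out stability.csv
bloodmirna cluster norm/processed.csv sim/samples.csv --outdir clust/
```

Deposited GEO series-matrix files can be converted into the pipeline's CSV
pair with `bloodmirna convert <series_matrix.txt> <mapping.csv> --outdir ...`
(the reader takes a local path; no network access).

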