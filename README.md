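# wgdtx

Whole-genome duplication (WGD) is one of the most common macro-evolutionary
events in high grade serous ovarian cancer and many other tumour types. Its
*timing* — whether the duplication happened before or after the bulk of
chromosomal losses — carries biological and clinical signal, but connecting
it to gene expression is statistically awkward: genome-doubled tumours have
systematically higher copy number at almost every gene, so naive
differential expression between WGD and non-WGD tumours mostly re-discovers
gene dosage. `wgdtx` implements the full analysis chain for this problem,
for cancer genomicists who have allele-specific copy-number segments (e.g.
FACETS output), a bulk RNA-seq count matrix, and survival metadata per
sample:

1. **WGD calling** — a tumour is WGD when the major (parental) copy number
   is ≥ 2 over more than half of the covered autosome:
   `is_wgd ⇔ Σ len(seg : MCN ≥ 2) / Σ len(seg) > 0.5`.
2. **WGD timing** — among segments with total copy number 2, more
   heterozygous (1+1) length means duplication preceded the losses
   (*early*); more homozygous (2+0) length means it followed them
   (*late*).
3. **Normalization** — TMM scaling factors (30 % trim on M-values, 5 % on
   A-values, inverse-asymptotic-variance weights) and
   `log2((count + 0.5)/(lib·factor + 1) × 10⁶)`.
4. **Copy-number-aware differential expression** — per gene *g* and sample
   *s*, an ordinary gaussian GLM

   ```
   y_gs ~ β₀ + β_WGD·WGD_s + β_HR·HR_s + β_p·purity_s + β_CN·cnlr_gs
   ```

   where `cnlr_gs` is the purity-mixed copy-number log-ratio of the segment
   carrying the gene, referenced to the sample's own ploidy (the quantity a
   coverage-based caller reports). Because the copy-number covariate varies
   by gene *and* sample, off-the-shelf DGE tools cannot fit this model; the
   WGD coefficient (log2-expression units) is the effect size, with BH
   adjustment across genes.
5. **Cross-cohort enrichment** — candidate up/down gene lists filtered by
   per-cohort coefficient thresholds, p-values merged across discovery and
   validation cohorts with Brown's method, pathways scored by the ranked
   hypergeometric statistic (minimum over prefixes of the hypergeometric
   tail), Holm-adjusted.
6. **Survival** — Kaplan–Meier curves and the k-group log-rank test across
   early / late / no-WGD groups.

Because the real cohorts this kind of analysis targets are access
controlled, the package ships a first-class synthetic-cohort generator
(`wgdtx.simulate`) with planted ground truth — WGD status and timing, a
recurrent-loss landscape, a copy-number dose effect, a down-regulated gene
module in early-WGD tumours, purity dilution, and group-specific survival
hazards — so every stage of the chain is testable end to end.

## Worked example

Run the whole chain on the default synthetic cohort (80 samples — 30
early-WGD, 20 late-WGD, 30 without WGD — and 2,000 genes with a 20-gene
module planted at −2 log2 units in early-WGD tumours; a validation cohort
of the same design is simulated alongside):

```python
from wgdtx import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(outdir="demo", seed=7))
```

or, from the shell, `wgdtx run-all --seed 7 --out demo`. The report (also
written to `demo/report.json`) contains, among other sections:

```
"wgd":        {"n_samples": 80, "n_wgd": 50,
               "by_timing": {"early": 30, "late": 20, "none": 30}}
"intersect":  {"n_genes": 20, "n_down": 20, "n_up": 0}
"enrichment": {"top": {"down": {"pathway": "MODULE_PATHWAY",
                                "p_adj": 9.998e-30, "significant": true}}}
"survival":   {"logrank_statistic": 6.287, "df": 2, "p": 0.0431}
```

Reading: every planted WGD call and timing label was recovered (50/80 WGD,
30/20/30 by timing); the cross-cohort intersect of significantly changed
genes is exactly the 20 planted module genes, all down-regulated; the
pathway containing the module dominates the down-regulated enrichment; and
survival differs across timing groups (the early group is simulated at a
twofold hazard). Note that the planted effect sits in *early*-WGD tumours
only, so the WGD-vs-rest coefficient in the three-arm default cohort is
diluted to about −1.2 and no single gene passes the conservative ±1.5
stand-alone threshold — the signal is recovered through the cross-cohort
intersect and enrichment, exactly the role those stages play on real
cohorts. Per-stage artifacts (WGD calls, normalized matrix, DGE tables,
KM tables, volcano and KM figures) are written beside the report, and each
stage is also available as a library call or CLI subcommand
(`simulate`, `call-wgd`, `normalize`, `dge`, `enrich`, `survival`).

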