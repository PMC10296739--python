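# mirtally

Combinatorial miRNA target-count analysis of paired miRNA/mRNA expression
studies.

## The problem

Prenatal alcohol exposure (PAE) studies in primate models repeatedly
observe a *global downregulation* of hippocampal mRNA expression together
with a predominance of *upregulated* miRNAs. Because a single mRNA is
typically a predicted target of many miRNAs, linking the two observations
needs more than per-pair correlation: the question is whether genes
targeted by *more* of the upregulated miRNAs are *more* downregulated —
combinatorial repression — and whether that relationship is specific to the
differentially expressed miRNA list rather than a property of miRNA
targeting in general.

`mirtally` implements that analysis as a tested, reusable pipeline for
anyone with (a) miRNA microarray data in a two-factor design, (b) a paired
mRNA fold-change table, and (c) one or more target-prediction files
(TargetScan-style, miRWalk-style, or generic two-column).

## The statistic

For each gene *g* with fold-change data, define the **independent target
count**

&nbsp;&nbsp;&nbsp;&nbsp;*c*(g) = |{ m ∈ M : g ∈ T(m) }|

— the number of *distinct* miRNAs from a list *M* predicted to target *g*
(binding-site multiplicity never counts). With *M* the DE-miRNA list, genes
are grouped by *c* and the mean log₂ fold change of each group is compared,
per category, against the same grouping under an equally sized list of
non-differentially expressed miRNAs (main-effect p-values nearest 1,
strong-interaction miRNAs excluded):

&nbsp;&nbsp;&nbsp;&nbsp;residual(*c*) = mean FC(count_DE = *c*) − mean FC(count_ctrl = *c*)

Predominantly negative residuals, a negative count–FC correlation, and a
depressed mean fold change in the ≥4-hit DE-target group (two-sided Welch
test) together indicate DE-list-specific repression, despite the strong
overlap between any two target lists (quantified here as the Pearson
correlation between the two count vectors).

Upstream of the statistic the package provides the standard microarray
chain: MAS5-style detection calls (one-sided rank test of probe intensities
against background probes), the detection filter (present on ≥ 6 arrays at
p < 0.05), RMA-style quantile normalization and median-polish
summarization, a species/sequence annotation funnel, per-feature two-factor
(age × exposure) Type III ANOVA on the unbalanced 6/6/5/6 design, Storey
q-values, and a PC-ordered co-expression analysis of the DE list with
genomic-cluster statistics.

## Worked example

```bash
mirtally simulate --out fixture --seed 1
mirtally run --fixture fixture --out results
```

or in Python:

```python
import mirtally as mt

ds = mt.generate_paired_dataset(mt.SynthConfig(seed=1))
fit = mt.add_qvalues(mt.fit_two_factor_anova(ds.mirna_expr, ds.design))
up, down = mt.select_de(fit)                      # p < 0.05, |log2 FC| > 1
control = mt.select_control_list(fit)             # 24 p-values nearest 1
counts = mt.build_count_table(ds.maps["synthA"], up, control, ds.mrna_fc)
summary, corr = mt.group_fold_change(counts)
ttest = mt.compare_fc_ttest(counts, min_hits=4)
overlap = mt.map_overlap_correlation(counts)
print(len(up), len(down))
print(round(corr["pearson_r"], 3), f'{corr["pearson_p"]:.2e}')
print(round(ttest["mean_de"], 4), round(ttest["mean_control"], 4),
      f'{ttest["p"]:.2e}')
print(round(overlap["r"], 3))
```

prints

```
24 3
-0.167 2.20e-100
-0.1067 -0.0935 4.92e-03
0.71
```

meaning: the ANOVA recovers 24 upregulated and 3 downregulated miRNAs
(exactly the planted sets); the per-gene fold change correlates negatively
with the independent target count (r = −0.167 over 16,000 genes); genes
targeted ≥ 4 times by the DE list are more depressed than genes targeted
≥ 4 times by the control list (−0.107 vs −0.094, Welch p = 4.9 × 10⁻³)
even though the two count vectors correlate at r = 0.71 — the
combinatorial-repression signature the pipeline is built to detect.

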