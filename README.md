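# foldsea

Fold-change-specific enrichment analysis (FSEA) for transcriptomics,
with a classic singular enrichment (SEA) baseline and simulation-based
validation.

## The problem

Standard overrepresentation analysis tells you *which* functional gene
groups (e.g. Gene Ontology terms) are enriched among differentially
expressed genes (DEGs), but not *how strongly* their members respond.
Many regulatory modules respond coordinately — all their genes shift by
a similar fold change — and that coordination is invisible to a test
that only compares DEGs against a genome background. `foldsea` detects
it: for each annotation term it asks whether the term's DEGs
concentrate in a specific *fold-change interval* of the
|log₂FC|-sorted DEG list.

## The method

For one regulation direction, the DEG list `G` (size `n`) is sorted by
|log₂FC| and cut into `k` rank-based quantiles `Q₁…Q_k`. Every
contiguous union of neighboring quantiles except the full range is a
candidate interval — `k(k+1)/2 − 1` of them (14 for `k = 5`). For each
term `GOᵢ` and interval `Q_r` a one-sided Fisher exact test is applied
to the 2×2 table

|            | in `Q_r`            | not in `Q_r`        |
|------------|---------------------|---------------------|
| in `GOᵢ`   | A = \|GOᵢ ∩ Q_r\|   | B = \|GOᵢ \ Q_r\|   |
| not in `GOᵢ` | C = \|Q_r \ GOᵢ\| | D = \|G \ (GOᵢ ∪ Q_r)\| |

All `m = s·(k(k+1)/2 − 1)` p-values (`s` = number of terms) are
corrected jointly (Benjamini–Hochberg by default); per term the
minimal-p interval is reported, and a term whose best interval survives
the correction is *fold-change-specific* — for `k = 5` its interval
reads as the response magnitude, from 1 (very weak) to 5 (very strong).
Up- and down-regulated genes are analyzed as two independent runs.

Two validation procedures ship with the package: a null
false-positive-rate estimator (gene identifiers of an
annotation-independent dataset are permuted many times; the fraction of
permutations with any significant term estimates the false-positive
rate) and a sensitivity estimator (equicorrelated multivariate-normal
gene groups of sizes 5–50, mean 1, correlation 0.75, planted among 100
uncorrelated DEGs and 700 non-DEGs, serve as pseudo-terms; the
per-group-size detection rate estimates power). See `docs/methods.md`.

## Worked example

With a DE table `deg.tsv` (columns `gene_id`, `log_fc`, `padj`; 120
genes) and a two-column annotation `map.tsv` containing one term
(`GO:STRONG`) holding the ten strongest upregulated genes plus six
random 12-gene decoy terms:

```sh
foldsea fsea --deg deg.tsv --annotation map.tsv --padj-col padj \
        --quantiles 5 --fdr 0.05 --out run1
```

logs

```
INFO foldsea: up: 44 DEGs
INFO foldsea: up: s=7, k=5, m=98, significant=1
INFO foldsea: down: 51 DEGs
INFO foldsea: down: s=6, k=5, m=84, significant=0
```

and `run1.up.tsv` begins

```
term_id    term_name  direction  interval_lo  interval_hi  A  B  C  D   p_raw         p_adj         significant
GO:STRONG             up         5            5            9  1  0  34  1.410575e-08  1.382364e-06  True
GO:DECOY3             up         2            2            3  1  6  34  2.258547e-02  4.426752e-01  False
```

Reading the first row: among the 44 upregulated DEGs, 9 of the term's
10 genes fall in the top quantile (interval [5,5] — very strong
response), none of the other 35 DEGs do (C = 0), giving a raw Fisher
p of 1.4 × 10⁻⁸; after joint BH correction over the 98 term × interval
tests it remains significant, so `GO:STRONG` is fold-change-specific
with a very strong response. The decoy term's nominal p = 0.023 does
not survive the correction — the point of the joint budget.

Other subcommands: `foldsea sea` (classic Fisher enrichment against a
gene universe), `foldsea simulate-fpr` and
`foldsea simulate-sensitivity` (the two validation estimators, TSV
output). The library API (`foldsea.run_fsea`, `run_sea`,
`compare_fsea_sea`, `estimate_fpr`, `estimate_sensitivity`, …) exposes
the same functionality programmatically, including GAF 2.x / gene2go
annotation parsing and optional ontology propagation from an OBO file
(`--obo ... --propagate`).

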