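# Methods

## The question FSEA answers

Classic overrepresentation analysis (SEA) asks whether a functional
gene group — typically a Gene Ontology term — contains more
differentially expressed genes (DEGs) than expected from a background
universe. It is blind to *how strongly* those genes respond.
Fold-change-specific enrichment analysis (FSEA) asks the sharper
question: do the term's DEGs concentrate in a particular band of the
fold-change distribution? A term whose members all respond weakly, or
all respond strongly, points at a coordinately regulated module; a term
whose members are scattered across the whole fold-change range does
not, even if the term is overrepresented among DEGs overall.

## Procedure

For one regulation direction (up or down), take the DEG list `G` of
size `n` with absolute log2 fold changes `X`, sorted ascending (ties in
value are ordered lexicographically by gene id so every run is
deterministic).

1. **Quantile partition.** The sorted list is cut into `k` quantiles by
   rank: the gene at 1-based rank `p` goes to quantile `ceil(p·k/n)`.
   Quantile sizes differ by at most one, the maximum always falls in
   the top quantile, and ties never make the assignment ambiguous.
   Rank-based assignment agrees with value-based cuts whenever the
   values are distinct. Reported boundaries are the |logFC| of the last
   gene of each quantile.
2. **Interval enumeration.** Every contiguous union of neighboring
   quantiles `[lo, hi]` is a candidate fold-change interval, *except*
   the full range `[1, k]`, which is the comparison background itself.
   There are `k(k+1)/2 − 1` intervals (14 for the default `k = 5`).
3. **Fisher tests.** For each annotation term `GO_i` (restricted to the
   direction's DEG list; terms left without genes are dropped and the
   term count `s` updated) and each interval `Q_r`, a 2×2 table is
   formed: `A = |GO_i ∩ Q_r|`, `B = |GO_i \ Q_r|`, `C = |Q_r \ GO_i|`,
   `D = |G \ (GO_i ∪ Q_r)|`. The one-sided (enrichment) Fisher exact
   p-value is the hypergeometric upper tail `P(X ≥ A)`.
4. **Correction and verdict.** All `m = s·(k(k+1)/2 − 1)` raw p-values
   are corrected jointly — Benjamini–Hochberg by default, Bonferroni by
   flag. Per term the interval with the minimal raw p is reported
   (ties broken toward the widest interval, then the smallest `lo`, a
   conservative-reporting rule). A term is *fold-change-specific* when
   the adjusted p of its best interval is at most the FDR threshold
   (default 0.05). For `k = 5` the intervals read as response
   magnitude: 1 = very weak … 5 = very strong.

Up- and down-regulated lists are analyzed as two independent runs, each
with its own `s` and `m`, because the two directions are separate
families of hypotheses.

The SEA baseline is the standard one-sided Fisher test of term
membership against DEG status over a user-configurable gene universe
(default: all genes of the input table), BH-corrected across the `s`
terms. `compare_fsea_sea` partitions significant terms into
both / FSEA-only / SEA-only, the three interpretive classes: coordinated
and overrepresented, overrepresented but non-coordinated, and
coordinated but at background frequency.

## Multiple-testing design

The correction budget is deliberately the *full* term × interval grid,
not the per-term minima: selecting the minimum of 14 dependent tests
per term and then correcting only `s` values would understate the
selection effect. Joint BH over all `m` tests realizes the stated
budget `s·Σ_{n=2..k} n` while remaining a standard FDR procedure; the
null simulation below confirms the resulting family-wise false-positive
rate is well below the nominal level (the positively dependent interval
tests make the procedure conservative). Bonferroni (`p·m`, clipped) is
available for users who want family-wise control in the strict sense.

## Numerical choices

- Fisher p-values come from `scipy.stats.hypergeom.sf`, vectorized over
  the whole term × interval grid in one call; the test suite checks it
  against an exact integer-arithmetic tail sum for every 2×2 table with
  `N ≤ 60`.
- BH is implemented directly (sort, step-up, monotone enforcement,
  clip at 1) and checked against `statsmodels.stats.multitest`.
- An empty margin or empty table yields p = 1, never NaN.
- A term's contingency table is always well-formed because interval
  genes are a subset of the DEG list by construction; the public
  `contingency_table` validates this precondition.

## Annotation handling

Annotations are read from two-column TSV, GAF 2.x (rows whose qualifier
contains `NOT` are dropped; aspect/taxon/evidence filters optional), or
NCBI gene2go. True-path propagation over an OBO ontology
(`is_a`/`part_of` transitive closure, via obonet/networkx) is
**off by default**: maps exported from pre-built annotation packages are
usually already propagated, and silent re-propagation would be a no-op
at best and misleading at worst. Term-size filtering defaults to a
minimum of 2 genes — a single-gene term cannot support an interval
enrichment and only inflates the correction budget. Gene identifiers
are opaque case-sensitive strings; no identifier translation is
attempted.

## The synthetic validation datasets

**Null generator** (`synth_null_dataset`): `n_genes = 1000` gene ids
with |logFC| drawn as |Normal(0, 1)| + 0.1 and random signs; the 300
largest |logFC| rows are flagged as DEGs via the adjusted-p column; 100
terms of 5–50 genes are assigned uniformly at random, independent of
expression. `estimate_fpr` then permutes the gene-identifier column
(the multiset of expression rows is untouched), splits DEGs into
directions, runs FSEA on both, and reports the fraction of permutations
with at least one significant term. 200 permutations give a Monte-Carlo
standard error of about 1 percentage point near a 2.5% rate, enough to
distinguish a controlled from an uncontrolled procedure; the count is a
flag for users who want tighter estimates. Because only the
independence of annotation and fold change matters under the null, the
synthetic substrate stands in for shuffled real datasets without loss.

**Sensitivity generator** (`sample_mvn_dataset`): a block multivariate
normal with six equicorrelated groups of 5, 10, 20, 30, 40, 50 genes
(mean μ = 1, sd σ = 1, within-group correlation ρ = 0.75 — the design
calls for ρ above 0.7), 100 independent DEGs with mean 1, and 700
non-DEGs with mean 0. Each group is sampled as
`μ + σ(√ρ·z₀ + √(1−ρ)·zᵢ)` with a shared `z₀`, which realizes the
equicorrelation covariance exactly and is positive definite for all
`0 ≤ ρ < 1`. The shared shift moves the whole group into a narrow band
of the ranking — the exact signature FSEA targets. The six groups form
the pseudo-annotation (`s = 6`; the uncorrelated DEGs can be added as a
seventh decoy term by flag). FSEA runs on the 255-gene DEG list with
the sampled values as the ranking variable; since only ranks matter,
negative draws need no transformation. Detection rate per group size is
averaged over 200 datasets by default (flag-overridable).

**What the simulations do not emulate**: real annotation structure
(nested, overlapping GO terms with heavy-tailed sizes), inter-gene
correlation outside the planted groups, measurement error in fold
changes, and discreteness of count-based DE estimates. Passing the
validations shows the procedure controls false positives under
annotation-independence and detects coordinated groups of realistic
size; it does not certify behavior on any particular real dataset or
annotation release.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 5 | quantile count; 5 makes intervals readable as very weak … very strong |
| `fdr` | 0.05 | adjusted-p threshold for significance |
| `method` | `bh` | joint BH over all `m` tests; `bonferroni` optional |
| `min_abs_lfc` | 0 | DEG |logFC| cutoff (the caller's DE pipeline sets the real criterion) |
| `max_padj` | 0.05 | DEG significance cutoff, applied only when a p-adj column is given |
| `min_term_size` | 2 | smallest testable term |
| `rho` | 0.75 | within-group correlation of planted groups |
| `n_shuffles` / `n_datasets` | 200 | Monte-Carlo replicates for the validation estimators |

## Known limitations

- The interval grid tests are positively dependent; joint BH is
  conservative here, so the realized FDR sits well below the nominal
  threshold (the null simulation typically reports a 0–1% family-wise
  hit rate at the 5% nominal level).
- Detection of very small groups (≤ 10 genes) is weak by construction —
  a handful of genes cannot dominate a quantile's contingency table —
  matching the intended operating range of the method.
- No GSEA-style whole-ranking statistic, no topGO-style decorrelation
  of nested terms, no identifier mapping: inputs are taken as given.
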