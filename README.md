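# isletdiff

Staged-differentiation differential expression and GWAS credible-interval
enrichment for in-vitro islet development time courses.

Studies that differentiate human iPSC lines through the stages of pancreatic
islet development (iPSC → definitive endoderm → gut tube → posterior foregut
→ pancreatic endoderm → endocrine precursor → endocrine-like → beta-like
cells) ask two linked questions: *which genes switch on at which stage*, and
*do the genes inside type 2 diabetes GWAS credible intervals switch on at a
particular stage*?  `isletdiff` implements that analysis chain as a tested
library:

1. **Differential expression** — CPM filter (CPM > 1 in all donors of ≥ 1
   stage), log-CPM with mean–variance precision weights, per-gene weighted
   linear models of stage + donor with iPSC as baseline, empirical-Bayes
   variance moderation (moderated t on $d_0 + d$ df), per-contrast BH, and DE
   calls at q < 0.01 and |log2FC| > 1.
2. **Stage assignment** — each DE gene goes to the stage where it is most
   upregulated; genes with no positive contrast fall back to iPSC.
3. **Credible-interval mapping** — 99% credible sets become half-open
   genomic intervals, expanded by 0/50/100/200/500 kb flanks; a gene is
   captured by ≥ 1 bp gene-body overlap.
4. **Enrichment** — per stage: exact log-space hypergeometric upper tail plus
   a gene-identity permutation null, with exclusion analyses (drop chosen
   genes and their locus co-members); and MAGENTA-style min-p gene scores
   (length/SNP-count adjusted) feeding a weighted KS GSEA in two directions
   (stage sets in the score ranking; significant-score genes in each stage's
   q ranking).
5. **Synthetic data** — a generator for the full input bundle (counts,
   annotation, credible intervals, SNP statistics) with known planted truth,
   so every step is testable without access-controlled data.

See `docs/methods.md` for the model and its assumptions.

## Worked example

The `analysis/` scripts run the chain on the reference synthetic dataset
(2,000 genes, 3 donors × 8 stages, 20 of 40 credible intervals planted over
beta-like-cell markers):

```sh
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_assign_stages.py
python analysis/04_map_credible_intervals.py
python analysis/05_enrichment.py
```

which prints, at the default seed:

```
tested 2000 genes after the expression filter
280 genes differentially expressed in >= 1 contrast (q < 0.01, |log2FC| > 1)
...
flank     0 kb: BLC overlap 20/38, permuted p = 9.999e-05
flank   500 kb: BLC overlap 28/38, permuted p = 0.0008999
BLC permuted p after excluding planted genes + co-members: 1
direction A (score-ranked GSEA): minimal q = 0.003998 at stage BLC
```

Reading this: of the 280 genes passing the DE thresholds, 38 peak at the
beta-like-cell (BLC) stage; 20 of them sit inside credible intervals —
overwhelmingly unlikely under random same-size gene sets (permuted
p ≈ 10⁻⁴, the floor at 10,000 permutations).  The signal attenuates as the
intervals are widened (more bystander genes enter the target set), vanishes
when the planted genes and their locus co-members are excluded, and is
independently recovered by the score-ranked GSEA, which puts its minimal q at
BLC.  All of this matches the planted ground truth in
`results/data/truth.json`.

The same steps are available as a CLI (`isletdiff simulate|de|assign|
map-genes|enrich`) for arbitrary input files in the documented TSV/BED
formats.

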