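# Methods

`isletdiff` implements the statistical machinery of a staged in-vitro islet
differentiation study: bulk RNA-seq differential expression across a
time course of 8 stages (iPSC baseline, then DE, GT, PF, PE, EP, EN, BLC) in
3 donors, assignment of each DE gene to its stage of peak upregulation, and
two families of enrichment tests relating those stage sets to type 2 diabetes
GWAS credible intervals.  Because the real data of such studies are
access-controlled, the package ships a first-class synthetic-data generator
with known ground truth; every downstream claim in the test suite is a
property of the method measured against that truth.

## Differential expression model

For gene $g$ and sample $i$, the response is
$y_{gi} = \log_2\!\big((c_{gi} + c_0) / (N_i + 2c_0) \cdot 10^6\big)$ with
prior count $c_0 = 0.5$ and library size $N_i$ the column sum of the filtered
count matrix.  The design is additive in stage and donor,

$$y_{gi} = \mu_g + \beta_{g,s(i)} + \gamma_{g,d(i)} + \varepsilon_{gi},$$

with iPSC as the reference stage so $\beta_{gs}$ is directly the log2 fold
change of stage $s$ versus baseline, and donor indicators absorbing
donor-specific offsets.  Genes enter the analysis only if their CPM exceeds 1
(strictly) in *every* donor's sample of at least one stage.

Counts are heteroscedastic on the log scale, so each observation receives a
precision weight: a preliminary unweighted fit yields per-gene residual SDs;
$\sqrt{\text{SD}}$ is regressed on mean log2-count by lowess (span 0.5,
configurable), the trend is evaluated at each observation's fitted log2-count
with flat extrapolation beyond the fitted range, and the weight is the
inverse fourth power (i.e. inverse predicted variance).  A `simple_mode`
switch sets all weights to 1, which makes the fit identical to ordinary least
squares — that is the mode used for oracle comparisons.

With one differentiation per donor the residual degrees of freedom are
$d = n - (\#\text{stages} + \#\text{donors} - 1) = 24 - 10 = 14$.  Inference
at 3 donors is only practical because variances are moderated across genes:
residual variances are modelled as scaled-inverse-$\chi^2$ with prior
$(d_0, s_0^2)$, estimated by moment matching on $\log s_g^2$ (digamma mean
correction, trigamma inversion of the excess variance; non-positive excess
variance means exchangeable variances and yields the pooled $d_0 = \infty$
branch).  The posterior variance
$\tilde s_g^2 = (d_0 s_0^2 + d\, s_g^2)/(d_0 + d)$ gives the moderated
$t = \hat\beta / (\mathrm{se}_u \cdot \tilde s_g)$ on $d_0 + d$ df.  The
implementation is cross-checked against limma's `lmFit`/`eBayes`/`voom` in
the test suite (agreement to ~1e-10 on coefficients and hyperparameters,
weights within a fraction of a percent); limma is never used as the
computational path.

P-values are Benjamini–Hochberg adjusted *within each contrast*, and a gene
is DE in a contrast iff $q < 0.01$ and $|\log_2\text{FC}| > 1$, both strict,
so boundary values are excluded.  `eBayes`-style trend fitting on top of the
weights is not applied by default.

## Stage assignment

A gene qualifies if it is DE in at least one contrast.  Its assigned stage is
the argmax of log2FC over **all seven** contrasts (not only the significant
ones; an `argmax_over="de"` mode restricts to significant contrasts).  If the
maximum is $\le 0$ the gene is assigned to iPSC — an exact zero is not
upregulation.  Exact ties break toward the earlier stage of the
differentiation order, making assignment deterministic.  The qualifying genes
are partitioned exactly once across the 8 stages.

## Credible-interval gene capture

All coordinates are 0-based half-open internally; BED is native, and a
1-based source (GTF) would be converted at the parser boundary.  An interval
expanded by a flank $f \in \{0, 50, 100, 200, 500\}$ kb captures a gene iff
the gene body overlaps it by $\ge 1$ bp (`gene.start < iv.end` and
`iv.start < gene.end`); adjacency does not count, partial containment does.
Gene-body overlap is used rather than CDS-feature overlap because credible
intervals are locus-scale objects.  The analysis universe is restricted to
autosomal protein-coding and lincRNA genes.  Capture is monotone in the
flank, which is the mechanism behind the attenuation of enrichment signal
with distance.

## Enrichment

**Over-representation.**  For a stage set of size $n$ and a target set of
size $K$ inside a universe of $N$ genes (all genes tested for DE), the
hypergeometric upper tail $P(X \ge k)$ is accumulated entirely in log space
(gammaln log-binomials plus a suffix log-sum-exp), so tails far below
double-precision pmf underflow remain exact; the implementation is verified
against exact rational enumeration on the full grid $N \le 60$ and against
scipy's survival function on random larger configurations.  The permutation
null draws random same-size gene sets uniformly without replacement from the
universe (gene-identity permutation — the natural null for "all genes tested
as background"); $p = (1 + \#\{\text{null} \ge \text{obs}\})/(n_\text{perm} + 1)$
never reaches 0.  The exclusion analysis removes a chosen gene list (e.g.
monogenic diabetes genes) and, in `genes_and_comembers` mode, every gene
sharing a capturing locus with an excluded gene.

**Gene scores.**  Each SNP within gene body $\pm$ 50 kb (configurable) is
assigned to the gene; the raw score is the minimum SNP p.  Longer genes with
more SNPs win the minimum by chance, so $-\log_{10}(\text{raw})$ is regressed
on $\log_{10}(\text{gene length})$ and $\log_{10}(\text{SNP count}+1)$ and
scores are re-expressed as residual ranks mapped to $(0,1]$.  This is a
deliberately simplified gene-scoring scheme: LD-unit and recombination-
hotspot corrections are out of scope because the synthetic inputs carry no
LD.  Genes with no SNP in the window carry no score.

**GSEA.**  For a ranked list of $L$ genes with metric $m$, the running
deviation at rank $i$ is the cumulative in-set weight
$\sum_{\text{hits} \le i} |m|^w / \sum_{\text{set}} |m|^w$ minus the uniform
reference $i/L$ — a weighted Kolmogorov–Smirnov statistic against the
diagonal.  ES is the deviation of largest magnitude; a singleton set at rank
1 scores exactly $1 - 1/L$, and a set equal to the whole list returns to 0
(degenerate, reported as ES = 0).  The null permutes gene identity
($n_\text{perm}$ random same-size sets); NES divides ES by the mean |null ES|
of matching sign, and the permutation p is sign-matched with a +1
pseudocount.  Defaults: weight exponent 1, 1000 permutations.  Two
directional analyses mirror the study design: direction A ranks all scored
genes by $-\log_{10}(\text{score p})$ and tests each stage's DE set;
direction B ranks each stage's DE genes by $-\log_{10}(q)$ of that stage's
contrast (best q across contrasts for the iPSC fallback set) and tests the
significant-score genes (score p < 0.05).  Each direction is BH-adjusted
across its family of 8 stages.

## Synthetic data

The generator emulates the study design, not any particular dataset.
Baseline abundances are log-normal ($\log_2$ mean 4, SD 2), matching the
heavy-tailed abundance distribution of real RNA-seq and thereby exercising
the mean-variance trend.  Counts are negative binomial with dispersion 0.1
(dispersion 0 degenerates to Poisson), mean proportional to
$\text{baseline}_g \cdot 2^{\gamma_{dg} + \beta_{gs}}$ rescaled to the
sample's library size.  Donor effects $\gamma_{dg}$ are gene-specific
Gaussian shifts (SD 0.1 log2 units) constant across stages — the additive
structure the donor blocking removes.  By default 2% of genes per stage are
markers with true log2FC drawn uniformly from [2, 4].  Library sizes default
to ~$10^6$ reads, far below real sequencing depth but sufficient for
desk-scale statistics; no claim of equivalence to ~$1.5\times10^8$-read
libraries is made.  Gene bodies are laid non-overlapping on two synthetic
chromosomes; credible intervals are planted to overlap marker gene bodies of
a chosen stage (a configured fraction of 40 loci; planted loci are tagged),
and SNP p-values inside planted intervals follow $p = U^k$ with $k = 10$
(mean $1/(k+1)$), against a uniform background.  A single root seed spawns
independent sub-streams per generator, so enlarging the locus set never
perturbs the counts.

What the generator does **not** emulate: LD among SNPs, read-level noise,
GC/length biases within a gene, correlated gene-gene expression modules,
sample quality differences, or partial confounding of donor with batch.
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under the stated model, not robustness to every
artefact of real data.

## Numerical choices and problem sizes

- Weighted per-gene fits are batched (`einsum` normal equations) rather than
  looped; residual variance uses weighted RSS over $n - p$ df.
- Trigamma inversion uses Newton iteration with the standard asymptotic
  guards; t-distribution df is capped at $10^9$ where $d_0 = \infty$.
- Permutation draws realise subsets by ranking i.i.d. uniform keys
  (chunked to bound memory at ~$2\times10^7$ keys), which is an exact
  uniform draw without replacement.
- Test and acceptance problem sizes are chosen for desk-scale runtime:
  1,500–5,000 genes, 20 replicates for recovery claims, $10^5$ permutations
  for the permutation-vs-closed-form check, 1,000–10,000 otherwise.

## Known limitations

- The gene score is a simplified min-p scheme; absolute scores are only
  meaningful after the rank-residual adjustment.
- Direction-B GSEA is fragile when few genes reach score p < 0.05 inside a
  stage set; such rows are flagged (`empty_set`) rather than computed.
- With one sample per (donor, stage) there is no within-condition replication;
  all inference leans on the moderated variance model.
- BH families are fixed (per contrast for DE, per direction for GSEA);
  alternative family definitions would change q values.
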