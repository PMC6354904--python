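"""Stage-set enrichment against GWAS-derived gene sets.

Two complementary machineries:

* Over-representation: upper-tail hypergeometric p for the overlap between a
  stage's DE gene set and the genes captured by credible intervals, with a
  Monte-Carlo permutation null drawing random same-size gene sets from the
  background universe (all genes tested for differential expression), plus an
  exclusion analysis that removes chosen genes (e.g. monogenic diabetes genes)
  and optionally every gene sharing a credible interval with them.

* Score-based: a MAGENTA-style per-gene association score (best SNP p in a
  window around the gene body, rank-residual-adjusted for gene length and SNP
  count) feeding a weighted Kolmogorov-Smirnov GSEA in two directions: stage
  sets tested in the genome-wide score ranking, and significant-score genes
  tested in each stage's q-value ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .de import adjust_bh
from .gwas import comembers
from .stages import DEFAULT_STAGES, stage_set

__all__ = [
    "hypergeom_p",
    "permutation_p",
    "exclusion_filter",
    "score_genes",
    "gsea",
    "GseaResult",
    "stage_overlap_table",
    "run_directional_analyses",
]


def hypergeom_p(n_universe: int, n_target: int, n_stage: int, n_overlap):
    """Upper-tail P(X >= n_overlap), X ~ Hypergeometric(N, K, n).

    N = background universe size, K = target genes in the universe, n = stage
    set size.  The tail is accumulated entirely in log space (gammaln log
    binomials + a suffix log-sum-exp) so extreme enrichment p-values do not
    underflow.  ``n_overlap`` may be a scalar or an integer array.
    """
    N, K, n = int(n_universe), int(n_target), int(n_stage)
    scalar = np.isscalar(n_overlap)
    k = np.atleast_1d(np.asarray(n_overlap, dtype=int))
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("target and stage sets must fit inside the universe")
    kmax = min(K, n)
    if (k < 0).any() or (k > kmax).any():
        raise ValueError("overlap must lie in [0, min(n_target, n_stage)]")
    i = np.arange(kmax + 1)
    lo = max(0, n - (N - K))
    with np.errstate(divide="ignore"):
        logpmf = np.where(
            i >= lo,
            special.gammaln(K + 1)
            - special.gammaln(i + 1)
            - special.gammaln(K - i + 1)
            + special.gammaln(N - K + 1)
            - special.gammaln(np.maximum(n - i, 0) + 1)
            - special.gammaln(np.maximum(N - K - n + i, 0) + 1)
            - (special.gammaln(N + 1) - special.gammaln(n + 1)
               - special.gammaln(N - n + 1)),
            -np.inf,
        )
    # Suffix log-sum-exp: log P(X >= i) for every i.
    log_sf = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    p = np.minimum(1.0, np.exp(log_sf[k]))
    p[k == 0] = 1.0
    return float(p[0]) if scalar else p


def _random_overlap_counts(
    n_universe: int, target_mask: np.ndarray, n_draw: int, n_perm: int, rng
) -> np.ndarray:
    """Overlap of ``n_perm`` uniform size-``n_draw`` subsets with a fixed set.

    Subsets are realised by ranking i.i.d. uniform keys per permutation and
    taking the ``n_draw`` smallest, i.e. genuine draws without replacement.
    """
    counts = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, int(2e7 // max(1, n_universe)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n_universe))
        idx = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
        counts[done : done + m] = target_mask[idx].sum(axis=1)
        done += m
    return counts


def permutation_p(
    stage_set_genes,
    target_set,
    universe,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Monte-Carlo p for the stage/target overlap under gene-identity permutation.

    Random gene sets of size |stage| are drawn uniformly without replacement
    from the universe; ``p = (1 + #{null >= observed}) / (n_perm + 1)`` so the
    reported p never reaches 0 (floor 1/(n_perm+1)).
    """
    universe = list(universe)
    stage = set(stage_set_genes)
    target = set(target_set)
    uni = set(universe)
    if not stage <= uni or not target <= uni:
        raise ValueError("stage and target sets must be subsets of the universe")
    if len(stage) > len(universe):
        raise ValueError("stage set larger than universe")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = len(stage & target)
    if len(stage) == 0:
        return 1.0, np.zeros(n_perm, dtype=np.int64)
    mask = np.fromiter((g in target for g in universe), dtype=bool, count=len(universe))
    null = _random_overlap_counts(len(universe), mask, len(stage), n_perm, rng)
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return p, null


def exclusion_filter(
    stage_set_genes,
    exclude_genes,
    capture_map: dict[str, set[str]] | None = None,
    mode: str = "genes_only",
) -> set[str]:
    """Remove excluded genes (and optionally their locus co-members) from a set.

    ``genes_and_comembers`` additionally drops every gene sharing >= 1
    capturing credible interval with an excluded gene, mirroring sensitivity
    analyses that strip monogenic diabetes genes and their interval neighbours.
    """
    stage = set(stage_set_genes)
    excluded = set(exclude_genes)
    if mode == "genes_only":
        return stage - excluded
    if mode == "genes_and_comembers":
        if capture_map is None:
            raise ValueError("genes_and_comembers mode needs a capture map")
        closure = set(excluded)
        for g in excluded:
            closure |= comembers(capture_map, g)
        return stage - closure
    raise ValueError("mode must be 'genes_only' or 'genes_and_comembers'")


def score_genes(
    snps: pd.DataFrame,
    annotation: pd.DataFrame,
    window_kb: float = 50.0,
    adjust: bool = True,
) -> pd.DataFrame:
    """MAGENTA-style gene association scores from SNP summary statistics.

    Each SNP within ``gene body +/- window`` is assigned to the gene; the raw
    score is the minimum SNP p.  Because longer genes with more SNPs win the
    min by chance, ``adjust`` regresses -log10(raw score) on log10 gene length
    and log10(n_snps + 1) and re-expresses scores as residual ranks mapped to
    (0, 1] — genes more significant than their footprint predicts get small
    score p.  Genes with no SNP in the window carry no score.
    """
    window = int(round(window_kb * 1000))
    gene_rows = []
    by_chrom = {c: sub.sort_values("pos") for c, sub in snps.groupby("chrom")}
    for row in annotation.itertuples():
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, row.start - window, side="left")
        hi = np.searchsorted(pos, row.end + window, side="left")
        if hi > lo:
            pvals = sub["p"].to_numpy()[lo:hi]
            gene_rows.append(
                (row.gene_id, float(pvals.min()), hi - lo, row.end - row.start)
            )
    if not gene_rows:
        raise ValueError("no SNP falls inside any gene window")
    table = pd.DataFrame(gene_rows, columns=["gene_id", "score_p", "n_snps", "length"])
    if adjust:
        y = -np.log10(np.clip(table["score_p"].to_numpy(), 1e-300, 1.0))
        X = np.column_stack(
            [
                np.ones(len(table)),
                np.log10(table["length"].to_numpy()),
                np.log10(table["n_snps"].to_numpy() + 1.0),
            ]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        # Larger residual = more significant than expected -> smaller score p.
        ranks = stats.rankdata(-resid, method="average")
        table["score_p"] = ranks / len(table)
    table["adjusted"] = bool(adjust)
    table["significant"] = table["score_p"] < 0.05
    return table.drop(columns="length")


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    q: float
    n_perm: int
    seed: int | None
    n_set: int
    note: str = ""


def _es_from_positions(
    positions: np.ndarray, w: np.ndarray, n_total: int
) -> np.ndarray:
    """Enrichment score per permutation from sorted 0-based hit positions.

    ``positions`` is (n_perm, n_set).  The running deviation at rank i is the
    normalised cumulative hit weight minus the uniform reference i/n_total, a
    weighted Kolmogorov-Smirnov statistic against the diagonal: a singleton
    set at rank 1 scores 1 - 1/n_total and a set equal to the whole list
    returns to 0.  Between hits the deviation falls linearly, so its extrema
    occur immediately after a hit or immediately before the next one; only
    those 2 * n_set candidates are evaluated.
    """
    n_perm, n_set = positions.shape
    wpos = w[positions]
    denom = wpos.sum(axis=1, keepdims=True)
    # Equal hit increments when all in-set weights vanish (e.g. exponent x 0).
    safe = np.where(denom > 0, denom, 1.0)
    uniform = (np.arange(1, n_set + 1) / n_set)[None, :]
    cum = np.where(denom > 0, np.cumsum(wpos, axis=1) / safe, uniform)
    wnorm = np.where(denom > 0, wpos / safe, 1.0 / n_set)
    after = cum - (positions + 1) / n_total
    before = (cum - wnorm) - positions / n_total
    cand = np.concatenate([after, before], axis=1)
    pick = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), pick]


def gsea(
    ranked_genes,
    metric,
    gene_set,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    set_name: str = "set",
) -> GseaResult:
    """Weighted Kolmogorov-Smirnov enrichment of a gene set in a ranked list.

    The running deviation accumulates |metric|^weight_exponent (normalised
    over in-set genes) at each hit and is referenced against the uniform
    expectation i/n_total at every rank; ES is the deviation of largest
    magnitude.  The null permutes gene identity: ``n_perm`` random same-size
    sets of positions.  NES divides ES by the mean |null ES| of the same sign;
    the permutation p carries a +1 pseudocount and is sign-matched.
    """
    ranked_genes = list(ranked_genes)
    metric = np.asarray(metric, dtype=float)
    if len(ranked_genes) != len(metric):
        raise ValueError("ranked_genes and metric must align")
    if not np.all(np.isfinite(metric)):
        raise ValueError("ranking metric must be finite")
    pos_index = {g: i for i, g in enumerate(ranked_genes)}
    hits = sorted(pos_index[g] for g in gene_set if g in pos_index)
    n_total, n_set = len(ranked_genes), len(hits)
    if n_set == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if len(set(gene_set)) > n_total:
        raise ValueError("gene set larger than the ranked list")
    if n_set == n_total:
        # Degenerate: every gene is a hit, the running sum returns to ~0.
        return GseaResult(set_name, 0.0, 0.0, 1.0, np.nan, n_perm, seed, n_set,
                          note="set_equals_list")

    w = np.abs(metric) ** weight_exponent
    es = float(_es_from_positions(np.asarray([hits]), w, n_total)[0])

    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    chunk = max(1, int(2e7 // max(1, n_total)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n_total))
        idx = np.argpartition(keys, n_set - 1, axis=1)[:, :n_set]
        idx.sort(axis=1)
        null[done : done + m] = _es_from_positions(idx, w, n_total)
        done += m

    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same.size:
        p = (1.0 + float((np.abs(same) >= abs(es)).sum())) / (same.size + 1.0)
        nes = es / np.abs(same).mean()
    else:
        p, nes = 1.0 / (n_perm + 1.0), np.nan
    return GseaResult(set_name, es, float(nes), float(p), np.nan, n_perm, seed, n_set)


def stage_overlap_table(
    assignments: pd.DataFrame,
    target_genes,
    universe,
    stages_ordered=DEFAULT_STAGES,
    n_perm: int = 10_000,
    seed: int | None = None,
    target_set_name: str = "target",
    flank_kb: float = 0.0,
) -> pd.DataFrame:
    """Hypergeometric + permutation enrichment of every stage set in a target set.

    The universe is the background of all genes tested for differential
    expression; the target set is intersected with it.  One row per stage.
    """
    universe = list(universe)
    uni = set(universe)
    target = set(target_genes) & uni
    ss = np.random.SeedSequence(seed).spawn(len(stages_ordered))
    rows = []
    for stage, child in zip(stages_ordered, ss):
        sset = stage_set(assignments, stage, stages_ordered) & uni
        overlap = len(sset & target)
        p_hyp = hypergeom_p(len(uni), len(target), len(sset), overlap)
        if sset:
            p_perm, _ = permutation_p(
                sset, target, universe, n_perm=n_perm,
                rng=np.random.default_rng(child),
            )
        else:
            p_perm = 1.0
        rows.append(
            {
                "stage": stage,
                "target_set_name": target_set_name,
                "flank_kb": flank_kb,
                "n_universe": len(uni),
                "n_target": len(target),
                "n_stage": len(sset),
                "n_overlap": overlap,
                "p_hyper": p_hyp,
                "p_perm": p_perm,
                "n_perm": n_perm,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def run_directional_analyses(
    de_table: pd.DataFrame,
    assignments: pd.DataFrame,
    scores: pd.DataFrame,
    stages_ordered=DEFAULT_STAGES,
    baseline: str = "iPSC",
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    sig_threshold: float = 0.05,
) -> pd.DataFrame:
    """The two directional GSEA analyses over stages.

    Direction A ranks all scored genes by -log10(score p) and tests each
    stage's DE set in that ranking.  Direction B ranks each stage's DE genes by
    -log10(q) of that stage's contrast (the gene's best q for the baseline
    fallback set) and tests the significant-score genes (score p < threshold)
    in it.  Each direction is BH-adjusted across its family of stages.
    """
    scores = scores.dropna(subset=["score_p"])
    sig_genes = set(scores.loc[scores["significant"], "gene_id"])

    # Direction A: genome-wide score ranking.
    ranked_a = scores.sort_values("score_p", kind="mergesort")
    genes_a = list(ranked_a["gene_id"])
    metric_a = -np.log10(np.clip(ranked_a["score_p"].to_numpy(), 1e-300, 1.0))

    qtab = de_table.pivot(index="gene_id", columns="contrast", values="q")
    best_q = qtab.min(axis=1)

    ss = np.random.SeedSequence(seed).spawn(2 * len(stages_ordered))
    rows: list[dict] = []
    for i, stage in enumerate(stages_ordered):
        sset = stage_set(assignments, stage, stages_ordered)
        base = {"direction": "A", "stage": stage, "n_set": len(sset & set(genes_a))}
        if not sset & set(genes_a):
            rows.append({**base, "es": np.nan, "nes": np.nan, "p_perm": np.nan,
                         "note": "empty_set"})
            continue
        r = gsea(genes_a, metric_a, sset, weight_exponent, n_perm,
                 rng=np.random.default_rng(ss[i]), set_name=stage)
        rows.append({**base, "es": r.es, "nes": r.nes, "p_perm": r.p_perm,
                     "note": r.note})

    for i, stage in enumerate(stages_ordered):
        sset = stage_set(assignments, stage, stages_ordered)
        if stage == baseline:
            qvals = best_q.reindex(list(sset))
        else:
            qvals = qtab[stage].reindex(list(sset)) if stage in qtab.columns else None
        base = {"direction": "B", "stage": stage}
        if qvals is None or qvals.dropna().empty:
            rows.append({**base, "n_set": 0, "es": np.nan, "nes": np.nan,
                         "p_perm": np.nan, "note": "empty_stage"})
            continue
        qvals = qvals.dropna().sort_values(kind="mergesort")
        genes_b = list(qvals.index)
        metric_b = -np.log10(np.clip(qvals.to_numpy(), 1e-300, 1.0))
        in_set = sig_genes & set(genes_b)
        if not in_set:
            rows.append({**base, "n_set": 0, "es": np.nan, "nes": np.nan,
                         "p_perm": np.nan, "note": "empty_set"})
            continue
        r = gsea(genes_b, metric_b, in_set, weight_exponent, n_perm,
                 rng=np.random.default_rng(ss[len(stages_ordered) + i]),
                 set_name=stage)
        rows.append({**base, "n_set": r.n_set, "es": r.es, "nes": r.nes,
                     "p_perm": r.p_perm, "note": r.note})

    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for direction, idx in out.groupby("direction").groups.items():
        sub = out.loc[idx]
        ok = sub["p_perm"].notna()
        if ok.any():
            out.loc[sub.index[ok], "q"] = adjust_bh(sub.loc[ok, "p_perm"].to_numpy())
    out["n_perm"] = n_perm
    out["seed"] = seed
    return out
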