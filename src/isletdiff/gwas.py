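"""Credible-interval gene mapping.

Turns 99% credible sets (trait-labelled genomic intervals) into gene captures:
an interval expanded by a distance bin (0/50/100/200/500 kb flanks) captures
every gene whose body overlaps it by at least 1 bp.  All coordinates are
0-based half-open internally; BED files are read and written natively and GTF
(1-based closed) would be converted at the parser boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "analysis_universe",
    "expand_intervals",
    "genes_in_intervals",
    "comembers",
    "subset_loci",
]

ANNOTATION_COLS = ["gene_id", "chrom", "start", "end", "biotype", "autosomal"]
INTERVAL_COLS = ["locus_id", "trait", "chrom", "start", "end", "tags"]


def analysis_universe(annotation: pd.DataFrame) -> pd.DataFrame:
    """Restrict to autosomal protein-coding and lincRNA genes (the DE universe)."""
    keep = annotation["autosomal"] & annotation["biotype"].isin(
        ["protein_coding", "lincRNA"]
    )
    return annotation.loc[keep].reset_index(drop=True)


def expand_intervals(intervals: pd.DataFrame, flank_kb: float) -> pd.DataFrame:
    """Widen each interval by ``flank_kb`` on both sides, clamping starts at 0."""
    if flank_kb < 0:
        raise ValueError("flank must be non-negative")
    flank = int(round(flank_kb * 1000))
    out = intervals.copy()
    out["start"] = np.maximum(0, out["start"].to_numpy() - flank)
    out["end"] = out["end"].to_numpy() + flank
    return out


def genes_in_intervals(
    annotation: pd.DataFrame, intervals: pd.DataFrame, flank_kb: float = 0.0
) -> dict[str, set[str]]:
    """Map gene_id -> set of capturing locus ids at the given flank.

    A gene is captured iff its body overlaps an expanded interval by >= 1 bp
    under half-open arithmetic (``gene.start < iv.end and iv.start < gene.end``);
    adjacency does not count.  Partial containment suffices.
    """
    unmatched = sorted(set(intervals["chrom"]) - set(annotation["chrom"]))
    if unmatched:
        raise ValueError(
            f"interval chromosomes absent from the annotation: {unmatched}"
        )
    expanded = expand_intervals(intervals, flank_kb)
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in expanded.groupby("chrom"):
        tree = IntervalTree()
        for row in sub.itertuples():
            if row.end > row.start:
                tree.addi(row.start, row.end, row.locus_id)
        trees[chrom] = tree
    capture: dict[str, set[str]] = {}
    for row in annotation.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        hits = tree.overlap(row.start, row.end)
        if hits:
            capture[row.gene_id] = {iv.data for iv in hits}
    return capture


def comembers(capture_map: dict[str, set[str]], gene_id: str) -> set[str]:
    """Genes sharing >= 1 capturing locus with ``gene_id`` (itself excluded).

    A gene absent from the map has no locus, hence no co-members.
    """
    loci = capture_map.get(gene_id)
    if not loci:
        return set()
    return {
        g for g, ls in capture_map.items() if g != gene_id and not ls.isdisjoint(loci)
    }


def _tag_set(tags) -> set[str]:
    if isinstance(tags, str):
        return {t for t in tags.split(",") if t}
    if tags is None or (isinstance(tags, float) and np.isnan(tags)):
        return set()
    return set(tags)


def subset_loci(
    intervals: pd.DataFrame, tag: str, known_tags: set[str] | None = None
) -> pd.DataFrame:
    """Loci carrying a subset tag (e.g. ``beta_cell`` for the physiological loci).

    ``known_tags`` declares the valid vocabulary; a known tag carried by no
    locus yields an empty set.  Without it, the tags present in the interval
    set define the vocabulary and an absent tag is an error.
    """
    tag_sets = intervals["tags"].map(_tag_set)
    known = known_tags if known_tags is not None else (
        set().union(*tag_sets) if len(tag_sets) else set()
    )
    if tag not in known:
        raise ValueError(f"unknown tag {tag!r}; known tags: {sorted(known)}")
    return intervals.loc[[tag in ts for ts in tag_sets]].reset_index(drop=True)
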