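"""Synthetic staged-differentiation data with known ground truth.

Emulates the study design the pipeline targets — 3 donors differentiated once
through 8 stages (iPSC baseline plus 7), bulk RNA-seq counts per (donor,
stage) — together with a synthetic genome annotation, GWAS-style credible
intervals planted around chosen marker genes, and SNP summary statistics
enriched inside planted intervals.  Every generator is a pure function of
(config, seed): a single root seed spawns independent sub-streams per
generator, so changing the number of loci never perturbs the counts.

Counts are negative binomial with a log-normal baseline abundance, gene- and
donor-specific log2-scale offsets constant across stages, and planted
stage-specific markers of known log2 fold change.  Default library sizes are
~1e6 reads: orders of magnitude below real sequencing depth, but deep enough
to exercise the mean-variance trend at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .de import CountMatrix
from .stages import DEFAULT_STAGES

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_counts",
    "simulate_annotation",
    "simulate_credible_sets",
    "simulate_snp_stats",
    "simulate_all",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults are the study conditions: 3 donors, the 8-stage
    differentiation (iPSC first = baseline), negative-binomial counts with
    dispersion 0.1, a small fraction of stage-specific markers per stage with
    true log2FC in [2, 4], and mild donor effects (SD 0.1 on the log2 scale).
    """

    n_genes: int = 5000
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_donors: int = 3
    lib_size_range: tuple[int, int] = (800_000, 1_200_000)
    nb_dispersion: float = 0.1
    marker_frac_per_stage: float = 0.02
    effect_log2fc_range: tuple[float, float] = (2.0, 4.0)
    donor_sd: float = 0.1
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 2.0
    n_loci: int = 40
    interval_len_range: tuple[int, int] = (20_000, 150_000)
    planted_frac: float = 0.5
    snps_per_locus: int = 20
    n_background_snps: int = 2000
    snp_enrich_exponent: float = 10.0
    planted_locus_stage: str | None = None
    seed: int = 0

    def validate(self) -> None:
        def bad(name, why):
            raise ConfigError(f"invalid {name}: {why}")

        if self.n_genes < 1:
            bad("n_genes", "must be positive")
        if len(self.stages) < 2:
            bad("stages", "need the baseline plus at least one stage")
        if len(set(self.stages)) != len(self.stages):
            bad("stages", "stage names must be unique")
        if self.n_donors < 1:
            bad("n_donors", "must be positive")
        if self.nb_dispersion < 0:
            bad("nb_dispersion", "must be non-negative")
        if not 0 <= self.marker_frac_per_stage < 1:
            bad("marker_frac_per_stage", "must lie in [0, 1)")
        if self.marker_frac_per_stage * (len(self.stages) - 1) >= 1:
            bad("marker_frac_per_stage", "markers would exceed the gene count")
        if self.donor_sd < 0:
            bad("donor_sd", "must be non-negative")
        if self.n_loci < 0:
            bad("n_loci", "must be non-negative")
        if not 0 <= self.planted_frac <= 1:
            bad("planted_frac", "must lie in [0, 1]")
        if self.snps_per_locus < 1:
            bad("snps_per_locus", "must be positive")
        if self.snp_enrich_exponent < 1:
            bad("snp_enrich_exponent", "must be >= 1")
        for name in ("lib_size_range", "interval_len_range", "effect_log2fc_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                bad(name, "need 0 < low <= high")
        if self.planted_locus_stage is not None and (
            self.planted_locus_stage not in self.stages[1:]
        ):
            bad("planted_locus_stage", "must be a non-baseline stage name")

    @property
    def baseline(self) -> str:
        return self.stages[0]

    def _streams(self):
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(("counts", "annotation", "credible", "snps"), children))


@dataclass
class SimulatedTruth:
    """Ground truth of the planted signal.

    ``true_log2fc`` is a genes x stages DataFrame (baseline column all zero);
    ``true_stage_of_gene`` maps marker genes to their stage (None elsewhere);
    ``planted_interval_genes`` is filled by the credible-set generator.
    """

    true_stage_of_gene: dict[str, str | None]
    true_log2fc: pd.DataFrame
    donor_effects: pd.DataFrame          # donors x genes
    planted_interval_genes: set[str] = field(default_factory=set)

    def markers_of(self, stage: str) -> list[str]:
        return [g for g, s in self.true_stage_of_gene.items() if s == stage]

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_stage_of_gene": self.true_stage_of_gene,
                "true_log2fc": {
                    g: {s: v for s, v in row.items() if v != 0.0}
                    for g, row in self.true_log2fc.iterrows()
                },
                "planted_interval_genes": sorted(self.planted_interval_genes),
            },
            indent=1,
        )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, SimulatedTruth]:
    """Negative-binomial counts for one sample per (donor, stage).

    The expected count of gene g in sample (d, s) is proportional to
    ``baseline_g * 2^(donor_effect_dg + true_log2fc_gs)`` rescaled to the
    sample's library size; dispersion 0 degenerates to Poisson.
    """
    config.validate()
    rng = np.random.default_rng(config._streams()["counts"])
    genes = _gene_ids(config.n_genes)
    stages = list(config.stages)
    donors = [f"D{i+1}" for i in range(config.n_donors)]

    baseline = 2.0 ** rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )
    lfc = pd.DataFrame(0.0, index=genes, columns=stages)
    true_stage: dict[str, str | None] = {g: None for g in genes}
    n_mark = int(round(config.marker_frac_per_stage * config.n_genes))
    perm = rng.permutation(config.n_genes)
    cursor = 0
    for stage in stages[1:]:
        chosen = perm[cursor : cursor + n_mark]
        cursor += n_mark
        lo, hi = config.effect_log2fc_range
        effects = rng.uniform(lo, hi, len(chosen))
        for gi, eff in zip(chosen, effects):
            lfc.iloc[gi, lfc.columns.get_loc(stage)] = eff
            true_stage[genes[gi]] = stage

    donor_eff = pd.DataFrame(
        rng.normal(0.0, config.donor_sd, (config.n_donors, config.n_genes)),
        index=donors,
        columns=genes,
    )

    sample_ids, donor_of, stage_of = [], {}, {}
    cols = {}
    L = lfc.to_numpy()
    D = donor_eff.to_numpy()
    lo, hi = config.lib_size_range
    for di, donor in enumerate(donors):
        for si, stage in enumerate(stages):
            sid = f"{donor}_{stage}"
            sample_ids.append(sid)
            donor_of[sid] = donor
            stage_of[sid] = stage
            lam = baseline * 2.0 ** (D[di] + L[:, si])
            lib = rng.integers(lo, hi + 1)
            mu = lam / lam.sum() * lib
            if config.nb_dispersion > 0:
                r = 1.0 / config.nb_dispersion
                cols[sid] = rng.negative_binomial(r, r / (r + mu))
            else:
                cols[sid] = rng.poisson(mu)
    counts = pd.DataFrame(cols, index=genes)[sample_ids]
    cm = CountMatrix(
        counts=counts,
        donor_of_sample=pd.Series(donor_of),
        stage_of_sample=pd.Series(stage_of),
    )
    truth = SimulatedTruth(
        true_stage_of_gene=true_stage, true_log2fc=lfc, donor_effects=donor_eff
    )
    return cm, truth


def simulate_annotation(config: SimulationConfig, n_chroms: int = 2) -> pd.DataFrame:
    """Non-overlapping gene bodies on synthetic chromosomes (0-based half-open).

    Genes are laid down left to right with random lengths and intergenic gaps;
    ~10% are labelled lincRNA, the rest protein_coding, all autosomal.
    """
    config.validate()
    rng = np.random.default_rng(config._streams()["annotation"])
    genes = _gene_ids(config.n_genes)
    chroms = [f"chr{i+1}" for i in range(n_chroms)]
    per_chrom = np.array_split(np.arange(config.n_genes), n_chroms)
    rows = []
    for chrom, idxs in zip(chroms, per_chrom):
        pos = int(rng.integers(5_000, 20_000))
        for gi in idxs:
            length = int(rng.integers(2_000, 20_000))
            rows.append((genes[gi], chrom, pos, pos + length))
            pos += length + int(rng.integers(5_000, 50_000))
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    ann["biotype"] = np.where(
        rng.random(len(ann)) < 0.1, "lincRNA", "protein_coding"
    )
    ann["autosomal"] = True
    return ann.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def simulate_credible_sets(
    config: SimulationConfig, annotation: pd.DataFrame, truth: SimulatedTruth
) -> pd.DataFrame:
    """Trait-labelled credible intervals, a fraction planted over marker genes.

    ``round(planted_frac * n_loci)`` intervals are placed to overlap gene
    bodies of ``planted_locus_stage`` markers (recorded in
    ``truth.planted_interval_genes`` and tagged ``planted``); the rest are
    placed uniformly on the genome away from those marker genes.
    """
    config.validate()
    rng = np.random.default_rng(config._streams()["credible"])
    ann = annotation.set_index("gene_id")
    n_planted = 0
    planted_genes: list[str] = []
    if config.planted_locus_stage is not None and config.n_loci > 0:
        n_planted = int(round(config.planted_frac * config.n_loci))
        markers = truth.markers_of(config.planted_locus_stage)
        if len(markers) < n_planted:
            raise ValueError(
                f"need {n_planted} markers of stage {config.planted_locus_stage} "
                f"for planted loci but only {len(markers)} exist"
            )
        planted_genes = list(rng.choice(markers, n_planted, replace=False))

    avoid = {
        (ann.loc[g, "chrom"], ann.loc[g, "start"], ann.loc[g, "end"])
        for g in (
            truth.markers_of(config.planted_locus_stage)
            if config.planted_locus_stage
            else []
        )
    }
    chrom_extent = annotation.groupby("chrom")["end"].max().to_dict()
    lo, hi = config.interval_len_range
    rows = []
    for i in range(config.n_loci):
        length = int(rng.integers(lo, hi + 1))
        if i < n_planted:
            g = planted_genes[i]
            gs, ge = int(ann.loc[g, "start"]), int(ann.loc[g, "end"])
            start = int(rng.integers(max(0, gs - length + 1), ge))
            chrom = ann.loc[g, "chrom"]
            tags = "planted"
            truth.planted_interval_genes.add(g)
        else:
            for _ in range(200):
                chrom = rng.choice(list(chrom_extent))
                start = int(rng.integers(0, max(1, chrom_extent[chrom] - length)))
                end = start + length
                if not any(
                    c == chrom and start < e and s < end for c, s, e in avoid
                ):
                    break
            tags = ""
        rows.append((f"L{i:03d}", "t2d", chrom, start, start + length, tags))
    return pd.DataFrame(
        rows, columns=["locus_id", "trait", "chrom", "start", "end", "tags"]
    )


def simulate_snp_stats(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    truth: SimulatedTruth,
    intervals: pd.DataFrame,
) -> pd.DataFrame:
    """SNP summary statistics: locus SNPs plus genome-wide background.

    Background SNP p ~ Uniform(0,1); SNPs inside planted intervals draw
    p = U^k with k = ``snp_enrich_exponent`` (k = 1 is the null).  Positions
    are uniform within each interval / across each chromosome.
    """
    config.validate()
    rng = np.random.default_rng(config._streams()["snps"])
    rows = []
    for row in intervals.itertuples():
        pos = rng.integers(row.start, max(row.start + 1, row.end),
                           config.snps_per_locus)
        u = rng.random(config.snps_per_locus)
        planted = "planted" in str(row.tags)
        p = u**config.snp_enrich_exponent if planted else u
        for pp, pv in zip(pos, p):
            rows.append((row.chrom, int(pp), float(pv)))
    chrom_extent = annotation.groupby("chrom")["end"].max().to_dict()
    chroms = list(chrom_extent)
    which = rng.integers(0, len(chroms), config.n_background_snps)
    for ci in which:
        chrom = chroms[ci]
        rows.append(
            (chrom, int(rng.integers(0, chrom_extent[chrom])), float(rng.random()))
        )
    return (
        pd.DataFrame(rows, columns=["chrom", "pos", "p"])
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )


def simulate_all(config: SimulationConfig):
    """Run all four generators; returns (counts, truth, annotation, intervals, snps)."""
    cm, truth = simulate_counts(config)
    ann = simulate_annotation(config)
    ivs = simulate_credible_sets(config, ann, truth)
    snps = simulate_snp_stats(config, ann, truth, ivs)
    return cm, truth, ann, ivs, snps


def config_summary(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["stages"] = list(config.stages)
    return d
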