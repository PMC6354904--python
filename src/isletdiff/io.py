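"""Plain-text readers and writers for the pipeline's tabular formats.

Formats: counts.tsv (gene_id + one column per sample), samples.tsv
(sample_id, donor, stage), genes.bed (BED6 + biotype column, 0-based
half-open), credible_sets.tsv (locus_id, trait, chrom, start, end, tags),
snps.tsv (chrom, pos, p), de_table.tsv, assignments.tsv, truth.json.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .de import CountMatrix


def write_counts(cm: CountMatrix, counts_path, samples_path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {
            "sample_id": cm.sample_ids,
            "donor": [cm.donor_of_sample[s] for s in cm.sample_ids],
            "stage": [cm.stage_of_sample[s] for s in cm.sample_ids],
        }
    ).to_csv(samples_path, sep="\t", index=False)


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
    return CountMatrix(
        counts=counts,
        donor_of_sample=samples["donor"],
        stage_of_sample=samples["stage"],
    )


def write_bed(annotation: pd.DataFrame, path) -> None:
    """BED6 with gene_id in the name column and biotype as a 7th column."""
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["start"],
            "end": annotation["end"],
            "name": annotation["gene_id"],
            "score": 0,
            "strand": "+",
            "biotype": annotation.get("biotype", "protein_coding"),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand", "biotype"]
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed.columns = cols[: bed.shape[1]]
    ann = pd.DataFrame(
        {
            "gene_id": bed["name"] if "name" in bed else bed.index.astype(str),
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "biotype": bed["biotype"] if "biotype" in bed else "protein_coding",
        }
    )
    ann["autosomal"] = ~ann["chrom"].isin(["chrX", "chrY", "X", "Y", "chrM", "MT"])
    return ann


def write_intervals(intervals: pd.DataFrame, path) -> None:
    intervals.to_csv(path, sep="\t", index=False)


def read_intervals(path) -> pd.DataFrame:
    ivs = pd.read_csv(path, sep="\t")
    if "tags" not in ivs.columns:
        ivs["tags"] = ""
    ivs["tags"] = ivs["tags"].fillna("")
    return ivs


def write_snps(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False)


def read_snps(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
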