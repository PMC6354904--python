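"""Peak-stage assignment of differentially expressed genes.

A gene qualifies if it meets the DE criteria in at least one stage-vs-baseline
contrast.  Each qualifying gene is assigned to the single stage at which it is
most upregulated (argmax of log2FC over the contrasts); if no contrast is
positive the gene is assigned to the iPSC baseline.  Exact ties break toward
the earlier stage in differentiation order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["assign_stages", "stage_set", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("iPSC", "DE", "GT", "PF", "PE", "EP", "EN", "BLC")


class IncompleteTableError(ValueError):
    pass


def assign_stages(
    de_table: pd.DataFrame,
    stages_ordered=DEFAULT_STAGES,
    baseline: str = "iPSC",
    argmax_over: str = "all",
) -> pd.DataFrame:
    """Assign every gene to its stage of peak upregulation.

    Parameters
    ----------
    de_table
        Long DE table with columns gene_id, contrast, log2fc, is_de; one row
        per (gene, non-baseline stage).
    argmax_over
        ``"all"`` (default) takes the argmax over every contrast; ``"de"``
        restricts the argmax to contrasts where the gene was itself called DE.

    Returns a DataFrame (gene_id, assigned_stage, peak_log2fc, qualifying)
    covering every gene in the table; only rows with ``qualifying`` form the
    stage partition.
    """
    if argmax_over not in ("all", "de"):
        raise ValueError("argmax_over must be 'all' or 'de'")
    contrasts = [s for s in stages_ordered if s != baseline]
    lfc = de_table.pivot(index="gene_id", columns="contrast", values="log2fc")
    isde = de_table.pivot(index="gene_id", columns="contrast", values="is_de")
    missing_cols = [c for c in contrasts if c not in lfc.columns]
    if missing_cols:
        raise IncompleteTableError(f"contrasts absent from table: {missing_cols}")
    lfc = lfc[contrasts]
    isde = isde[contrasts].astype(bool)
    bad = lfc.isna().any(axis=1)
    if bad.any():
        raise IncompleteTableError(
            f"incomplete contrasts for genes {list(lfc.index[bad])[:5]}"
        )

    vals = lfc.to_numpy()
    de_mask = isde.to_numpy()
    qualifying = de_mask.any(axis=1)
    if argmax_over == "de":
        vals = np.where(de_mask, vals, -np.inf)
    # np.argmax returns the first maximum; contrasts are in differentiation
    # order, so ties already break toward the earlier stage.
    peak_idx = np.argmax(vals, axis=1)
    peak = vals[np.arange(len(vals)), peak_idx]
    assigned = np.asarray(contrasts, dtype=object)[peak_idx]
    assigned[peak <= 0] = baseline  # zero is not upregulation
    return pd.DataFrame(
        {
            "gene_id": lfc.index,
            "assigned_stage": assigned,
            "peak_log2fc": peak,
            "qualifying": qualifying,
        }
    ).reset_index(drop=True)


def stage_set(assignments: pd.DataFrame, stage: str, stages_ordered=DEFAULT_STAGES) -> set:
    """Qualifying genes assigned to ``stage``; the sets partition the DE genes."""
    if stage not in stages_ordered:
        raise ValueError(f"unknown stage {stage!r}; known: {list(stages_ordered)}")
    sel = assignments["qualifying"] & (assignments["assigned_stage"] == stage)
    return set(assignments.loc[sel, "gene_id"])
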