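"""Comparative-CT (2^-ddCT) fold changes and expressed-gene fractions.

The comparative cycle-threshold method normalises each sample's target CT to
a reference gene (dCT = CT_target - CT_ref), then to a calibrator sample.
The calibrator is the sample with the HIGHEST dCT (lowest target
expression), so every reported fold change is >= 1 and the calibrator's is
exactly 1; one PCR cycle corresponds to a two-fold difference.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["delta_delta_ct", "expressed_fraction"]


def delta_delta_ct(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
) -> pd.DataFrame:
    """Per-sample 2^-ddCT fold changes of ``target_gene`` vs ``reference_gene``.

    ``table`` has columns ``sample_id, gene_id, ct`` (a ``group`` column is
    carried through when present).  Technical replicates (repeated
    sample/gene rows) are averaged at the CT level before dCT.
    """
    if (table["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    ct = (
        table.groupby(["sample_id", "gene_id"], sort=True)["ct"].mean().unstack("gene_id")
    )
    for gene in (target_gene, reference_gene):
        if gene not in ct.columns:
            raise KeyError(f"gene {gene!r} absent from CT table")
        missing = ct.index[ct[gene].isna()]
        if len(missing):
            raise ValueError(f"missing CT for gene {gene!r} in samples {list(missing)}")
    dct = ct[target_gene] - ct[reference_gene]
    ddct = dct - dct.max()  # calibrator = lowest-expression sample
    out = pd.DataFrame(
        {
            "sample_id": dct.index,
            "delta_ct": dct.to_numpy(),
            "delta_delta_ct": ddct.to_numpy(),
            "fold_change": (2.0 ** (-ddct)).to_numpy(),
        }
    ).reset_index(drop=True)
    if "group" in table.columns:
        groups = table.groupby("sample_id")["group"].first()
        out["group"] = out["sample_id"].map(groups)
    return out


def expressed_fraction(
    expression: pd.DataFrame,
    gene_subset,
    threshold: float = 0.0,
) -> pd.Series:
    """Fraction of ``gene_subset`` genes with expression > threshold per stage.

    ``expression`` is a gene x stage matrix (genes on the index).  Raises on
    an empty subset or on subset genes absent from the matrix.
    """
    subset = list(gene_subset)
    if not subset:
        raise ValueError("gene subset is empty")
    missing = [g for g in subset if g not in expression.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:10]}")
    return (expression.loc[subset] > threshold).mean(axis=0)
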