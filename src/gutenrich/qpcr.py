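"""Relative quantification of qPCR transcripts by the ddCt method.

Ct values (cycles to threshold) are compared between a treated and a control
condition, normalised to a reference gene with stable expression:

    dCt_g   = Ct_target,g - Ct_reference,g        (per condition g)
    ddCt    = dCt_treated - dCt_control
    fold    = 2 ** (-ddCt)

An amplification efficiency of 100% (base 2) is assumed.  Folds below 1 are
reported as the negative reciprocal (0.125 -> -8.0).  Technical replicates
are averaged within each biological replicate (sample) first, and biological
replicates are then averaged, so unbalanced technical replication does not
bias the condition mean.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .arraydiff import signed_fold

CT_COLUMNS = ["sample_id", "condition", "gene", "replicate", "ct"]


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return records


def mean_ct(records: pd.DataFrame, condition: str, gene: str) -> float:
    """Mean Ct for one (condition, gene): technical means per sample, then
    the mean over samples."""
    _validate(records)
    sel = records[(records["condition"] == condition) & (records["gene"] == gene)]
    if sel.empty:
        raise ValueError(f"no Ct records for condition={condition!r}, gene={gene!r}")
    return float(sel.groupby("sample_id")["ct"].mean().mean())


def ddct_fold(records: pd.DataFrame, target: str, reference: str) -> float:
    """Signed fold change of ``target`` in treated vs control, normalised to
    ``reference``.  Both genes must be measured in both conditions."""
    dct = {}
    for condition in ("control", "treated"):
        dct[condition] = mean_ct(records, condition, target) - mean_ct(
            records, condition, reference
        )
    ddct = dct["treated"] - dct["control"]
    return signed_fold(2.0 ** (-ddct))


def fold_table(records: pd.DataFrame, targets: Sequence[str], reference: str) -> pd.DataFrame:
    """Signed ddCt folds for several target genes against one reference."""
    rows = [
        {"gene": gene, "reference": reference, "fold": ddct_fold(records, gene, reference)}
        for gene in targets
    ]
    return pd.DataFrame(rows, columns=["gene", "reference", "fold"])
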