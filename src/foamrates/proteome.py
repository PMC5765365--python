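"""Confident protein calls from peptide evidence and the foam-protein set.

A protein is confidently detected when at least ``min_unique_peptides``
distinct peptide sequences match it at or above the ``min_conf`` confidence
threshold (boundary inclusive). High-confidence foam proteins are the
intersection of confidently detected proteins with genes significantly
upregulated in both breeding-condition contrasts of the foam gland.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import pandas as pd

PEPTIDE_COLUMNS = ["protein_id", "peptide", "confidence"]


def call_confident_proteins(
    evidence: pd.DataFrame,
    min_conf: float = 0.99,
    min_unique_peptides: int = 2,
) -> set[str]:
    """Proteins with >= min_unique_peptides distinct peptides at
    confidence >= min_conf. Peptide uniqueness is by exact sequence."""
    if evidence.empty:
        return set()
    ev = evidence[PEPTIDE_COLUMNS].copy()
    if ((ev["confidence"] < 0) | (ev["confidence"] > 1)).any():
        raise ValueError("confidence outside [0, 1]")
    if (ev["peptide"].str.len() == 0).any():
        raise ValueError("empty peptide sequence")
    ok = ev[ev["confidence"] >= min_conf]
    n_unique = ok.groupby("protein_id")["peptide"].nunique()
    return set(n_unique.index[n_unique >= min_unique_peptides])


def intersect_fp(
    confident: Iterable[str], upregulated_both_contrasts: Iterable[str]
) -> set[str]:
    """High-confidence foam proteins: detected in foam AND upregulated in
    both breeding-condition contrasts of the foam gland."""
    out = set(confident) & set(upregulated_both_contrasts)
    if not out:
        warnings.warn("empty foam-protein intersection", stacklevel=2)
    return out
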