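"""Windowed nucleotide diversity from variant calls and its group ANOVAs.

Site diversity uses the unbiased sample-pairwise-difference form
pi_site = 2ab / (n(n-1)) for a biallelic site with allele counts (a, b) over
the n haplotypes called at that site; window pi averages site pi over the
full fixed window length (monomorphic and uncalled positions count as zero),
tiling each contig as [1,500], [501,1000], ...
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd


def pi_windows(
    vcf_path: str,
    contig_lengths: Mapping[str, int],
    window: int = 500,
) -> pd.DataFrame:
    """Per-window nucleotide diversity from a VCF.

    Non-biallelic-SNP records and sites with fewer than 2 called haplotypes
    are skipped (counted in the ``skipped`` attribute of the result).
    Returns DataFrame[contig, start, end, pi] with 1-based inclusive window
    bounds covering every contig in ``contig_lengths``.
    """
    from cyvcf2 import VCF

    acc: dict[tuple[str, int], float] = {}
    skipped = 0
    for rec in VCF(vcf_path):
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        a = b = 0
        for gt in rec.genotypes:  # [allele1, allele2, phased]
            for al in gt[:-1]:
                if al == 0:
                    a += 1
                elif al == 1:
                    b += 1
        n = a + b
        if n < 2:
            skipped += 1
            continue
        site_pi = 2.0 * a * b / (n * (n - 1))
        widx = (rec.POS - 1) // window
        key = (rec.CHROM, widx)
        acc[key] = acc.get(key, 0.0) + site_pi

    rows = []
    for contig, length in contig_lengths.items():
        n_windows = math.ceil(length / window)
        for w in range(n_windows):
            start = w * window + 1
            end = (w + 1) * window
            rows.append((contig, start, end, acc.get((contig, w), 0.0) / window))
    out = pd.DataFrame(rows, columns=["contig", "start", "end", "pi"])
    out.attrs["skipped"] = skipped
    return out


def gene_mean_pi(windows: pd.DataFrame, spans: pd.DataFrame) -> pd.DataFrame:
    """Mean window pi per gene span (any overlap counts a window).

    ``spans`` is BED-like: columns contig, start (0-based), end (half-open),
    gene_id. Genes with no overlapping window are dropped with a warning.
    """
    rows = []
    dropped = []
    for span in spans.itertuples(index=False):
        w = windows[
            (windows["contig"] == span.contig)
            & (windows["start"] <= span.end)  # window 1-based start <= bed end
            & (windows["end"] >= span.start + 1)  # window end >= bed start+1
        ]
        if w.empty:
            dropped.append(span.gene_id)
            continue
        rows.append((span.gene_id, float(w["pi"].mean())))
    if dropped:
        warnings.warn(f"{len(dropped)} genes had no overlapping window", stacklevel=2)
    return pd.DataFrame(rows, columns=["gene_id", "pi"])


def anova_two_way(values: pd.DataFrame) -> pd.DataFrame:
    """Sequential (Type I) two-way ANOVA of pi on tissue, status and their
    interaction. ``values`` needs columns pi, tissue, status. Returns
    DataFrame indexed by term with columns df, F, p."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in ("tissue", "status"):
        if values[col].nunique() < 2:
            raise ValueError(f"factor {col} needs >=2 levels")
    cells = values.groupby(["tissue", "status"]).size()
    if len(cells) < values["tissue"].nunique() * values["status"].nunique():
        raise ValueError("empty factor cell")
    model = smf.ols("pi ~ C(tissue) + C(status) + C(tissue):C(status)", values).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    tab = tab.rename(
        index={
            "C(tissue)": "tissue",
            "C(status)": "status",
            "C(tissue):C(status)": "tissue:status",
            "Residual": "residual",
        }
    )
    return tab[["df", "F", "PR(>F)"]].rename(columns={"PR(>F)": "p"})


def tukey_hsd(values: pd.DataFrame, group_col: str = "label") -> pd.DataFrame:
    """Tukey HSD adjusted p for all pairs of levels of ``group_col``.

    Returns DataFrame[group1, group2, meandiff, p_adj, reject].
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sizes = values.groupby(group_col).size()
    if (sizes < 2).any():
        raise ValueError("every level needs >=2 observations")
    res = pairwise_tukeyhsd(values["pi"].to_numpy(), values[group_col].to_numpy())
    import itertools

    pairs = list(itertools.combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "reject": res.reject,
        }
    )
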