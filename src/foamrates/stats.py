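"""Group-level comparison machinery: bootstrap CIs of the mean, proportion
tests with FDR correction and compact-letter displays, and the stratified
divergence-rate report."""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    ci_low: float
    ci_high: float
    stratum: str = "all"


def bootstrap_ci_mean(
    values: Sequence[float],
    reps: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    label: str = "",
    stratum: str = "all",
) -> GroupSummary:
    """Percentile bootstrap CI of the mean (resampling with replacement)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(reps, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return GroupSummary(label, int(x.size), float(x.mean()), float(lo), float(hi), stratum)


def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float, bool]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (sample odds ratio, p, zero_margin_flag); a zero row or column
    margin yields p = 1 by convention with the flag set.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), 1.0, True
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p), False


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q values, reject-at-alpha mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values outside [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def compact_letters(
    labels: Sequence[str], significant_pairs: Iterable[tuple[str, str]]
) -> dict[str, str]:
    """Compact-letter display: labels share a letter iff not significantly
    different. Insert-and-absorb: start from one group holding every label,
    split any group containing both members of a significant pair, and drop
    groups that become subsets of another."""
    sig = {frozenset(p) for p in significant_pairs}
    groups: list[set[str]] = [set(labels)]
    for pair in sig:
        a, b = tuple(pair)
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.append(g - {a})
                new_groups.append(g - {b})
            else:
                new_groups.append(g)
        # absorb redundant groups
        groups = [
            g
            for i, g in enumerate(new_groups)
            if g
            and not any(
                (g < h) or (g == h and i > j) for j, h in enumerate(new_groups)
            )
        ]
    groups.sort(key=lambda g: sorted(g))
    letters = {lab: "" for lab in labels}
    for g, letter in zip(groups, string.ascii_lowercase):
        for lab in sorted(g):
            letters[lab] += letter
    return {lab: "".join(sorted(v)) for lab, v in letters.items()}


def proportion_panel(
    category_counts: Mapping[str, tuple[int, int]],
    alpha: float = 0.05,
    method: str = "fisher",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """All pairwise proportion tests with BH correction and letters.

    ``category_counts`` maps label -> (k successes, n trials). Categories not
    significantly different (q >= alpha) share a letter.
    """
    labels = list(category_counts)
    if len(labels) < 2:
        raise ValueError("need >=2 categories")
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            ka, na = category_counts[a]
            kb, nb = category_counts[b]
            table = [[ka, na - ka], [kb, nb - kb]]
            if method == "chi2":
                _, p, _, _ = sps.chi2_contingency(np.asarray(table) + 0, correction=True)
                odds = (ka * (nb - kb)) / max((na - ka) * kb, 1e-300)
                flag = False
            else:
                odds, p, flag = fisher_exact(table)
            rows.append((a, b, ka, na, kb, nb, odds, p, flag))
    panel = pd.DataFrame(
        rows,
        columns=["cat1", "cat2", "k1", "n1", "k2", "n2", "odds_ratio", "pvalue", "zero_margin"],
    )
    panel["qvalue"], panel["significant"] = bh_fdr(panel["pvalue"], alpha)
    sig_pairs = [
        (r.cat1, r.cat2) for r in panel.itertuples(index=False) if r.significant
    ]
    return panel, compact_letters(labels, sig_pairs)


def stratified_rate_report(
    rates: pd.DataFrame,
    categories: pd.DataFrame,
    chrom_classes: pd.DataFrame | None = None,
    reps: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrap mean-omega summaries per category x stratum plus a
    CI-overlap comparison table.

    ``rates``: DataFrame[gene_id, omega]; ``categories``:
    DataFrame[gene_id, label]; ``chrom_classes`` (optional):
    DataFrame[gene_id, chrom_class in {autosome, Z, unknown}]. Unknown
    chromosome genes appear in the "all" stratum only. Non-overlap of 95%
    CIs is a descriptive flag, not a formal test.
    """
    df = rates.merge(categories, on="gene_id")
    if chrom_classes is not None:
        df = df.merge(chrom_classes, on="gene_id", how="left")
        df["chrom_class"] = df["chrom_class"].fillna("unknown")
    else:
        df["chrom_class"] = "unknown"
    df = df[np.isfinite(df["omega"])]
    rng = np.random.default_rng(seed)
    summaries: list[GroupSummary] = []
    for label in sorted(df["label"].unique()):
        sub = df[df["label"] == label]
        strata = {"all": sub}
        for cls in ("autosome", "Z"):
            strata[cls] = sub[sub["chrom_class"] == cls]
        for stratum, block in strata.items():
            if block.empty:
                if stratum == "all":
                    warnings.warn(f"category {label} has no usable rates")
                continue
            summaries.append(
                bootstrap_ci_mean(
                    block["omega"].to_numpy(), reps=reps, seed=rng,
                    label=label, stratum=stratum,
                )
            )
    summary_df = pd.DataFrame([s.__dict__ for s in summaries])

    comp_rows = []
    for stratum in summary_df["stratum"].unique():
        block = summary_df[summary_df["stratum"] == stratum].reset_index(drop=True)
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                a, b = block.iloc[i], block.iloc[j]
                overlap = not (a["ci_high"] < b["ci_low"] or b["ci_high"] < a["ci_low"])
                comp_rows.append(
                    (stratum, a["label"], b["label"], a["mean"], b["mean"], overlap)
                )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["stratum", "label1", "label2", "mean1", "mean2", "ci_overlap"],
    )
    return summary_df, comparisons
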