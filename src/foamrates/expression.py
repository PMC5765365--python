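"""Count filtering, TMM normalization, NB differential expression and the
two functional gene groupings.

The differential-expression engine fits per-gene negative-binomial GLMs
(log link, library-size x TMM offsets) with a method-of-moments dispersion
shrunk toward a mean-dispersion trend, and tests contrasts by likelihood
ratio against chi-square(1). This is a documented simplification of the
Cox-Reid tagwise-dispersion machinery of the standard count-model packages;
its calibration and power are what the test suite verifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with per-sample design factors.

    ``design`` is indexed by sample id with at least columns
    tissue in {FG, Testis}, treatment in {LD, SD, SD+T}, male_id.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)[:5]}")
        self.design = self.design.loc[self.counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, mask: pd.Series) -> "CountMatrix":
        cols = self.design.index[mask]
        return CountMatrix(self.counts[cols], self.design.loc[cols])


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million mapped reads, using raw library sizes."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    return counts * 1e6 / lib


def cpm_filter(
    cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 6
) -> CountMatrix:
    """Keep genes with CPM >= min_cpm in at least min_samples samples
    (boundary inclusive)."""
    keep = (cpm(cm.counts) >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        import warnings

        warnings.warn("CPM filter removed every gene", stacklevel=2)
    return CountMatrix(cm.counts.loc[keep], cm.design)


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    30% trim on M, 5% trim on A, inverse asymptotic-variance weights;
    factors rescaled to geometric mean 1. Reference sample: upper-quartile
    CPM closest to the mean upper-quartile, unless given.
    """
    counts = cm.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    c = cpm(counts)
    if ref_sample is None:
        uq = c.quantile(0.75, axis=0)
        ref_sample = (uq - uq.mean()).abs().idxmin()
    yr = counts[ref_sample].to_numpy(float)
    nr = lib[ref_sample]
    factors = {}
    import warnings

    for s in counts.columns:
        if s == ref_sample:
            factors[s] = 1.0
            continue
        ys = counts[s].to_numpy(float)
        ns = lib[s]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            warnings.warn(f"sample {s} shares no expressed genes with reference")
            factors[s] = 1.0
            continue
        ps, pr = ys[ok] / ns, yr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        lo_m, hi_m = np.quantile(m, [0.30, 0.70])
        lo_a, hi_a = np.quantile(a, [0.05, 0.95])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any() or w[keep].sum() == 0:
            factors[s] = 1.0
            continue
        factors[s] = float(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))
    f = pd.Series(factors).loc[counts.columns]
    return f / np.exp(np.log(f).mean())


# ---------------------------------------------------------------------------
# NB GLM machinery (two-group contrast with offsets, vectorized over genes)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood summed over samples; phi per gene (column vector).
    Poisson limit used where phi ~ 0."""
    phi = np.maximum(phi, 1e-12)[:, None]
    r = 1.0 / phi
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu) + 1e-300)
    )
    return ll.sum(axis=1)


def _fit_nb_mean(
    y: np.ndarray, offset: np.ndarray, phi: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Newton-scoring fit of a single intercept per gene, counts y (genes x
    samples) with log-offsets; returns beta (log mean per offset unit)."""
    if mask is not None:
        y = y[:, mask]
        offset = offset[mask]
    t = np.exp(offset)[None, :]
    ybar = np.maximum(y.mean(axis=1), 1e-8)
    beta = np.log(ybar / t.mean())
    phi_col = phi[:, None]
    for _ in range(50):
        mu = np.exp(beta[:, None]) * t
        denom = 1.0 + phi_col * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _moment_dispersion(
    y: np.ndarray, offset: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Pearson method-of-moments NB dispersion per gene, fitted group means."""
    t = np.exp(offset)
    n = y.shape[1]
    mu = np.zeros_like(y, dtype=float)
    p = 0
    for g in np.unique(groups):
        sel = groups == g
        p += 1
        rate = y[:, sel].sum(axis=1) / t[sel].sum()
        mu[:, sel] = rate[:, None] * t[sel][None, :]
    mu = np.maximum(mu, 1e-8)
    resid2 = (y - mu) ** 2
    # solve sum resid2/(mu(1+phi mu)) = n - p by a few Newton steps
    phi = np.maximum(((resid2 - mu) / mu**2).mean(axis=1), 0.0)
    for _ in range(25):
        denom = mu * (1.0 + phi[:, None] * mu)
        f = (resid2 / denom).sum(axis=1) - (n - p)
        fprime = -(resid2 * mu**2 / denom**2).sum(axis=1)
        step = f / np.where(np.abs(fprime) < 1e-12, -1e-12, fprime)
        phi = np.maximum(phi - step, 0.0)
    return phi


def _dispersion_trend(mean_cpm: np.ndarray, phi: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Binned-mean dispersion trend over log expression."""
    order = np.argsort(mean_cpm)
    bins = np.array_split(order, min(n_bins, max(1, len(order) // 10) or 1))
    trend = np.empty_like(phi)
    for b in bins:
        if len(b):
            trend[b] = phi[b].mean()
    return trend


def estimate_dispersions(
    y: np.ndarray,
    offset: np.ndarray,
    groups: np.ndarray,
    mean_cpm: np.ndarray,
    shrink_weight: float = 0.5,
) -> np.ndarray:
    """Tagwise dispersions: moment estimates shrunk toward the binned trend.

    ``shrink_weight`` is the weight on the trend (1 = pure trend, 0 = pure
    tagwise moments).
    """
    phi = _moment_dispersion(y, offset, groups)
    trend = _dispersion_trend(mean_cpm, phi)
    return shrink_weight * trend + (1.0 - shrink_weight) * phi


def test_de(
    cm: CountMatrix,
    contrast: tuple[str, str],
    factor: str = "treatment",
    tissue: str | None = None,
    norm_factors: pd.Series | None = None,
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB GLM likelihood-ratio test of level_a vs level_b.

    Returns a DataFrame with columns gene_id, contrast, log2fc (level_a over
    level_b), pvalue, qvalue (BH), mean_cpm. Genes with zero counts in both
    groups get log2fc 0 and p 1.
    """
    level_a, level_b = contrast
    sub = cm
    if tissue is not None:
        sub = sub.subset_samples(sub.design["tissue"] == tissue)
    sel = sub.design[factor].isin([level_a, level_b])
    sub = sub.subset_samples(sel)
    groups = (sub.design[factor] == level_a).to_numpy()
    if groups.sum() < 2 or (~groups).sum() < 2:
        raise ValueError("each contrast level needs >=2 samples")

    if norm_factors is None:
        norm_factors = tmm_factors(sub)
    else:
        norm_factors = norm_factors.loc[sub.design.index]
    lib = sub.library_sizes.to_numpy(float)
    offset = np.log(lib * norm_factors.to_numpy(float))
    y = sub.counts.to_numpy(float)
    mean_cpm_val = cpm(sub.counts).mean(axis=1).to_numpy()

    phi = estimate_dispersions(
        y, offset, groups.astype(int), mean_cpm_val, shrink_weight
    )

    t = np.exp(offset)
    beta0 = _fit_nb_mean(y, offset, phi)
    beta_a = _fit_nb_mean(y, offset, phi, mask=groups)
    beta_b = _fit_nb_mean(y, offset, phi, mask=~groups)
    mu0 = np.exp(beta0[:, None]) * t[None, :]
    mu1 = np.where(
        groups[None, :], np.exp(beta_a)[:, None] * t[None, :],
        np.exp(beta_b)[:, None] * t[None, :],
    )
    lrt = 2.0 * (_nb_loglik(y, mu1, phi) - _nb_loglik(y, mu0, phi))
    lrt = np.maximum(lrt, 0.0)
    pvals = sps.chi2.sf(lrt, df=1)
    log2fc = (beta_a - beta_b) / np.log(2.0)

    allzero = (y.sum(axis=1) == 0)
    pvals[allzero] = 1.0
    log2fc[allzero] = 0.0

    from .stats import bh_fdr

    qvals, _ = bh_fdr(pvals)
    return pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            "contrast": f"{level_a}_vs_{level_b}" + (f"_{tissue}" if tissue else ""),
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
            "mean_cpm": mean_cpm_val,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene groupings


def _up_set(de: pd.DataFrame, lfc_min: float, q_max: float) -> set[str]:
    sig = de[(de["log2fc"] > lfc_min) & (de["qvalue"] < q_max)]
    return set(sig["gene_id"])


def classify_scheme_a(
    fg_enriched: Iterable[str],
    testis_enriched: Iterable[str],
    de_fg_ld_sd: pd.DataFrame,
    de_fg_sdt_sd: pd.DataFrame,
    de_testis_ld_sd: pd.DataFrame,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Breeding-condition induction classes within each tissue-enriched set.

    A tissue-enriched gene is Induced when significantly up in the breeding
    condition (FG: LD vs SD or SD+T vs SD; testis: LD vs SD) with
    log2FC > lfc_min and q < q_max; genes up in the breeding condition of
    BOTH tissues are dropped entirely; the rest are Not_Induced.
    """
    fg_enriched = set(fg_enriched)
    testis_enriched = set(testis_enriched)
    both = fg_enriched & testis_enriched
    if both:
        raise ValueError(f"genes in both enriched sets: {sorted(both)[:5]}")
    fg_up = _up_set(de_fg_ld_sd, lfc_min, q_max) | _up_set(de_fg_sdt_sd, lfc_min, q_max)
    testis_up = _up_set(de_testis_ld_sd, lfc_min, q_max)
    dropped = fg_up & testis_up
    rows = []
    for g in sorted(fg_enriched - dropped):
        rows.append((g, "FG_Induced" if g in fg_up else "FG_Not_Induced"))
    for g in sorted(testis_enriched - dropped):
        rows.append((g, "Testis_Induced" if g in testis_up else "Testis_Not_Induced"))
    return pd.DataFrame(rows, columns=["gene_id", "label"])


def classify_scheme_b(
    fp_ids: Iterable[str],
    fg_enriched: Iterable[str],
    fg_expressed: Iterable[str],
    all_ids: Iterable[str],
) -> pd.DataFrame:
    """Least-inclusive-designation partition: FP > FG_Enriched > FG_Expressed
    > Other, over the full gene universe."""
    fp_ids, fg_enriched = set(fp_ids), set(fg_enriched)
    fg_expressed = set(fg_expressed)
    rows = []
    for g in sorted(set(all_ids)):
        if g in fp_ids:
            label = "FP"
        elif g in fg_enriched:
            label = "FG_Enriched"
        elif g in fg_expressed:
            label = "FG_Expressed"
        else:
            label = "Other"
        rows.append((g, label))
    return pd.DataFrame(rows, columns=["gene_id", "label"])
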