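"""Count filtering, TMM, NB differential expression, gene groupings."""

import numpy as np
import pandas as pd
import pytest

from foamrates import expression as ex


def _cm(counts, tissues=None, treatments=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    n = counts.shape[1]
    design = pd.DataFrame(
        {
            "tissue": tissues or ["FG"] * n,
            "treatment": treatments or ["LD"] * n,
            "male_id": [f"m{j}" for j in range(n)],
        },
        index=counts.columns,
    )
    return ex.CountMatrix(counts, design)


class TestCountMatrix:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _cm([[1, -2], [3, 4]])

    def test_duplicate_gene_ids_rejected(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["g", "g"], columns=["a", "b"])
        design = pd.DataFrame(
            {"tissue": ["FG", "FG"], "treatment": ["LD", "SD"], "male_id": ["1", "2"]},
            index=["a", "b"],
        )
        with pytest.raises(ValueError):
            ex.CountMatrix(counts, design)

    def test_sample_missing_from_design_rejected(self):
        counts = pd.DataFrame([[1, 2]], index=["g"], columns=["a", "b"])
        design = pd.DataFrame(
            {"tissue": ["FG"], "treatment": ["LD"], "male_id": ["1"]}, index=["a"]
        )
        with pytest.raises(ValueError):
            ex.CountMatrix(counts, design)

    def test_design_reordered_to_count_columns(self):
        counts = pd.DataFrame([[1, 2]], index=["g"], columns=["a", "b"])
        design = pd.DataFrame(
            {"tissue": ["T", "FG"], "treatment": ["SD", "LD"], "male_id": ["2", "1"]},
            index=["b", "a"],
        )
        cm = ex.CountMatrix(counts, design)
        assert list(cm.design.index) == ["a", "b"]
        assert cm.design.loc["a", "tissue"] == "FG"


class TestCPM:
    def test_columns_sum_to_million(self):
        cm = _cm([[10, 5], [90, 195]])
        c = ex.cpm(cm.counts)
        assert np.allclose(c.sum(axis=0), 1e6)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            ex.cpm(pd.DataFrame([[0, 1]]))

    def test_filter_boundary_inclusive(self):
        # gene g0 has CPM exactly 1.0 in both samples (1 read in 1e6)
        cm = _cm([[1, 1], [999_999, 999_999]])
        kept = ex.cpm_filter(cm, min_cpm=1.0, min_samples=2)
        assert list(kept.gene_ids) == ["g0", "g1"]
        kept = ex.cpm_filter(cm, min_cpm=1.0 + 1e-9, min_samples=2)
        assert list(kept.gene_ids) == ["g1"]

    def test_filter_min_samples(self):
        # g0 passes in one sample only
        cm = _cm([[10, 0], [999_990, 1_000_000]])
        assert list(ex.cpm_filter(cm, 1.0, 1).gene_ids) == ["g0", "g1"]
        assert list(ex.cpm_filter(cm, 1.0, 2).gene_ids) == ["g1"]

    def test_filter_all_removed_warns(self):
        cm = _cm([[1, 1], [999_999, 999_999]])
        with pytest.warns(UserWarning):
            out = ex.cpm_filter(cm, min_cpm=1e9, min_samples=1)
        assert out.counts.empty


class TestTMM:
    def test_identical_proportions_give_unit_factors(self, rng):
        base = rng.integers(10, 1000, size=200)
        cm = _cm(np.column_stack([base, base * 2, base * 5]))
        f = ex.tmm_factors(cm)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.integers(0, 500, size=(300, 4))
        counts[0] += 1  # avoid all-zero row edge
        f = ex.tmm_factors(_cm(counts))
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_composition_spike_lowers_factor(self, rng):
        base = rng.integers(50, 500, size=300)
        spiked = base.copy()
        spiked[0] = base[0] * 2000  # one gene dominates the spiked library
        cm = _cm(np.column_stack([base, base, spiked]))
        f = ex.tmm_factors(cm)
        assert f.iloc[2] < f.iloc[0]
        assert f.iloc[0] == pytest.approx(f.iloc[1], rel=1e-9)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            ex.tmm_factors(_cm([[1], [2]]))

    def test_explicit_reference_is_unit_before_rescale(self, rng):
        counts = rng.integers(1, 500, size=(200, 3))
        cm = _cm(counts)
        f_a = ex.tmm_factors(cm, ref_sample="s0")
        f_b = ex.tmm_factors(cm, ref_sample="s1")
        # different references give (nearly) proportional factor vectors
        assert np.allclose(np.log(f_a) - np.log(f_a).mean(),
                           np.log(f_b) - np.log(f_b).mean(), atol=0.15)


def _de_counts(rng, n_null=400, n_up=20, fold=8.0, n_per_group=6, phi=0.1):
    """NB counts for an LD-vs-SD contrast with planted upregulated genes."""
    n_genes = n_null + n_up
    rel = np.exp(rng.normal(np.log(60e-6), 0.8, size=n_genes))
    lib = rng.integers(900_000, 1_100_000, size=2 * n_per_group).astype(float)
    up = np.zeros(n_genes, dtype=bool)
    up[:n_up] = True
    counts = np.empty((n_genes, 2 * n_per_group), dtype=np.int64)
    r = 1.0 / phi
    for j in range(2 * n_per_group):
        breeding = j < n_per_group
        mean = rel * lib[j] * np.where(up & breeding, fold, 1.0)
        counts[:, j] = rng.negative_binomial(r, r / (r + mean))
    treatments = ["LD"] * n_per_group + ["SD"] * n_per_group
    return _cm(counts, treatments=treatments), up


class TestDE:
    def test_planted_upregulation_detected(self, rng):
        cm, up = _de_counts(rng)
        de = ex.test_de(cm, ("LD", "SD"))
        hits = de[(de["qvalue"] < 0.05) & (de["log2fc"] > 1.0)]
        planted = set(cm.gene_ids[up])
        assert len(set(hits["gene_id"]) & planted) >= 0.9 * len(planted)
        # log2fc near the planted fold for the planted genes
        lfc = de.set_index("gene_id").loc[sorted(planted), "log2fc"]
        assert abs(lfc.median() - 3.0) < 0.5

    def test_null_genes_rarely_called(self, rng):
        cm, up = _de_counts(rng)
        de = ex.test_de(cm, ("LD", "SD")).set_index("gene_id")
        null_p = de.loc[cm.gene_ids[~up], "pvalue"]
        assert (null_p < 0.05).mean() < 0.12
        null_q = de.loc[cm.gene_ids[~up], "qvalue"]
        assert (null_q < 0.05).mean() < 0.02

    def test_sign_convention(self, rng):
        cm, up = _de_counts(rng, n_null=50, n_up=5)
        a = ex.test_de(cm, ("LD", "SD")).set_index("gene_id")
        b = ex.test_de(cm, ("SD", "LD")).set_index("gene_id")
        assert np.allclose(a["log2fc"], -b["log2fc"], atol=1e-8)
        assert np.allclose(a["pvalue"], b["pvalue"], atol=1e-8)

    def test_all_zero_gene_neutral(self, rng):
        cm, _ = _de_counts(rng, n_null=40, n_up=0)
        counts = cm.counts.copy()
        counts.iloc[0] = 0
        cm2 = ex.CountMatrix(counts, cm.design)
        de = ex.test_de(cm2, ("LD", "SD")).set_index("gene_id")
        assert de.iloc[0]["pvalue"] == 1.0
        assert de.iloc[0]["log2fc"] == 0.0

    def test_tissue_subsetting(self, rng):
        cm, _ = _de_counts(rng, n_null=40, n_up=0)
        design = cm.design.copy()
        design.loc[design.index[:6], "tissue"] = "Testis"
        mixed = ex.CountMatrix(cm.counts, design)
        with pytest.raises(ValueError):
            # after restricting to FG the LD group is empty
            ex.test_de(mixed, ("LD", "SD"), tissue="FG")

    def test_requires_replication(self):
        cm = _cm([[5, 6, 7], [8, 9, 10]], treatments=["LD", "SD", "SD"])
        with pytest.raises(ValueError):
            ex.test_de(cm, ("LD", "SD"))


def _de_frame(up_ids, all_ids):
    rows = []
    for g in all_ids:
        if g in up_ids:
            rows.append((g, 2.5, 1e-8, 1e-6))
        else:
            rows.append((g, 0.1, 0.6, 0.8))
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue", "qvalue"])


class TestSchemeA:
    def test_labels_and_both_up_dropped(self):
        fg = ["a", "b", "c"]
        te = ["x", "y", "z"]
        ids = fg + te
        out = ex.classify_scheme_a(
            fg, te,
            de_fg_ld_sd=_de_frame({"a", "z"}, ids),
            de_fg_sdt_sd=_de_frame({"a"}, ids),
            de_testis_ld_sd=_de_frame({"x", "z"}, ids),
        )
        lab = dict(zip(out["gene_id"], out["label"]))
        assert lab == {
            "a": "FG_Induced", "b": "FG_Not_Induced", "c": "FG_Not_Induced",
            "x": "Testis_Induced", "y": "Testis_Not_Induced",
        }
        assert "z" not in lab  # up in both tissues: dropped

    def test_either_fg_contrast_counts(self):
        out = ex.classify_scheme_a(
            ["a"], [],
            de_fg_ld_sd=_de_frame(set(), ["a"]),
            de_fg_sdt_sd=_de_frame({"a"}, ["a"]),
            de_testis_ld_sd=_de_frame(set(), ["a"]),
        )
        assert out["label"].tolist() == ["FG_Induced"]

    def test_thresholds_strict(self):
        de = pd.DataFrame(
            [("a", 1.0, 0.001, 0.01)],  # log2fc exactly at the cut: excluded
            columns=["gene_id", "log2fc", "pvalue", "qvalue"],
        )
        out = ex.classify_scheme_a(["a"], [], de, de, _de_frame(set(), ["a"]))
        assert out["label"].tolist() == ["FG_Not_Induced"]

    def test_overlapping_enriched_sets_rejected(self):
        with pytest.raises(ValueError):
            ex.classify_scheme_a(
                ["a"], ["a"],
                _de_frame(set(), ["a"]), _de_frame(set(), ["a"]),
                _de_frame(set(), ["a"]),
            )


class TestSchemeB:
    def test_least_inclusive_cascade(self):
        out = ex.classify_scheme_b(
            fp_ids=["a"],
            fg_enriched=["a", "b"],
            fg_expressed=["a", "b", "c"],
            all_ids=["a", "b", "c", "d"],
        )
        lab = dict(zip(out["gene_id"], out["label"]))
        assert lab == {"a": "FP", "b": "FG_Enriched", "c": "FG_Expressed", "d": "Other"}

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        ids = [f"g{i}" for i in range(50)]
        fp = ids[:3]
        enr = ids[:10]
        expr = ids[:25]
        out = ex.classify_scheme_b(fp, enr, expr, ids)
        assert sorted(out["gene_id"]) == sorted(ids)
        assert out["gene_id"].is_unique
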