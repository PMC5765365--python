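"""Synthetic study generator: determinism, planted truth, file round-trips."""

import numpy as np
import pandas as pd
import pytest

from foamrates import io as frio
from foamrates import molevol as mv
from foamrates import simulate as sim
from foamrates.config import STUDY_CLASSES, SimConfig
from foamrates.proteome import call_confident_proteins


class TestCodonPair:
    def test_deterministic(self):
        a = sim.simulate_codon_pair(50, 0.3, 0.2, seed=123)
        b = sim.simulate_codon_pair(50, 0.3, 0.2, seed=123)
        assert a == b

    def test_zero_divergence(self):
        s1, s2 = sim.simulate_codon_pair(40, 0.5, 0.0, seed=1)
        assert s1 == s2

    def test_stop_free(self):
        for seed in range(5):
            s1, s2 = sim.simulate_codon_pair(60, 1.5, 0.5, seed=seed)
            for s in (s1, s2):
                codons = [s[i:i + 3] for i in range(0, len(s), 3)]
                assert not any(c in mv.STOP_CODONS for c in codons)

    def test_realized_ds_near_target(self):
        s1, s2 = sim.simulate_codon_pair(400, 0.4, 0.2, seed=7)
        est = mv.ng86(mv.CodonAlignment(s1, s2))
        assert 0.1 < est.dS < 0.3

    def test_omega_ordering(self):
        # same seed/geometry: lower omega leaves fewer nonsyn differences
        ests = {}
        for om in (0.05, 1.0):
            s1, s2 = sim.simulate_codon_pair(400, om, 0.25, seed=11)
            ests[om] = mv.ng86(mv.CodonAlignment(s1, s2))
        assert ests[0.05].dN < ests[1.0].dN

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            sim.simulate_codon_pair(1, 0.5, 0.1, 0)
        with pytest.raises(ValueError):
            sim.simulate_codon_pair(10, 0.0, 0.1, 0)
        with pytest.raises(ValueError):
            sim.simulate_codon_pair(10, 0.5, -0.1, 0)


class TestClasses:
    def test_exact_counts_largest_remainder(self, rng):
        cfg = SimConfig(n_genes=997)
        classes = sim.assign_classes(cfg, rng)
        assert len(classes) == 997
        counts = classes.value_counts()
        for c in STUDY_CLASSES:
            assert abs(counts.get(c, 0) - cfg.class_fractions[c] * 997) < 1.0

    def test_deterministic_given_rng_state(self):
        cfg = SimConfig(n_genes=200)
        a = sim.assign_classes(cfg, np.random.default_rng(5))
        b = sim.assign_classes(cfg, np.random.default_rng(5))
        assert a.equals(b)


@pytest.fixture(scope="module")
def study():
    cfg = SimConfig(n_genes=400, seed=17)
    classes = sim.assign_classes(cfg, np.random.default_rng(17))
    cm, truth = sim.simulate_counts(cfg, classes=classes, seed=17)
    return cfg, classes, cm, truth


@pytest.fixture(scope="module")
def full_study(tmp_path_factory):
    cfg = SimConfig(n_genes=300, seed=97)
    out = tmp_path_factory.mktemp("study")
    return cfg, sim.simulate_study(cfg, out), out


class TestCounts:
    def test_design_shape(self, study):
        _, _, cm, _ = study
        d = cm.design
        assert len(d) == 30
        assert (d["tissue"] == "FG").sum() == 18
        assert (d["tissue"] == "Testis").sum() == 12
        # testes not sampled under SD+T
        assert d[(d["tissue"] == "Testis") & (d["treatment"] == "SD+T")].empty

    def test_males_shared_across_tissues(self, study):
        _, _, cm, _ = study
        d = cm.design
        for trt in ("LD", "SD"):
            fg = set(d[(d.tissue == "FG") & (d.treatment == trt)]["male_id"])
            te = set(d[(d.tissue == "Testis") & (d.treatment == trt)]["male_id"])
            assert fg == te

    def test_off_genes_are_low_in_fg(self, study):
        _, classes, cm, _ = study
        fg = cm.design.index[cm.design["tissue"] == "FG"]
        other = classes.index[classes == "other"]
        fg_expr = classes.index[classes == "fp"]
        assert cm.counts.loc[other, fg].mean().mean() < 1.0
        assert cm.counts.loc[fg_expr, fg].mean().mean() > 5.0

    def test_induction_visible_in_raw_means(self, study):
        _, classes, cm, _ = study
        d = cm.design
        ld = d.index[(d.tissue == "FG") & (d.treatment == "LD")]
        sd = d.index[(d.tissue == "FG") & (d.treatment == "SD")]
        ind = classes.index[classes == "fg_induced"]
        flat = classes.index[classes == "fg_not_induced"]
        ratio_ind = cm.counts.loc[ind, ld].mean().mean() / cm.counts.loc[ind, sd].mean().mean()
        ratio_flat = cm.counts.loc[flat, ld].mean().mean() / cm.counts.loc[flat, sd].mean().mean()
        assert ratio_ind > 2.5
        assert 0.5 < ratio_flat < 2.0


class TestPeptides:
    def test_true_fps_always_confident(self, rng):
        fp = [f"fp{i}" for i in range(25)]
        ev = sim.simulate_peptides(fp, n_decoys=100, seed=rng)
        called = call_confident_proteins(ev)
        assert called == set(fp)

    def test_decoys_never_reach_threshold(self, rng):
        ev = sim.simulate_peptides(["fp0"], n_decoys=200, seed=rng)
        decoy_ev = ev[ev["protein_id"] != "fp0"]
        assert (decoy_ev["confidence"] < 0.99).all()

    def test_empty_fp_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_peptides([], 10)


class TestVariants:
    def _spans(self, n=40, length=1500):
        return pd.DataFrame(
            {"contig": [f"g{i}" for i in range(n)], "start": 0,
             "end": length, "gene_id": [f"g{i}" for i in range(n)]}
        )

    def test_mean_pi_near_theta(self):
        theta = 0.003
        spans = self._spans(60)
        recs = sim.simulate_variants(spans, theta, 24, seed=5)
        # overall per-site diversity across all spans
        total_pi = 0.0
        for _, _, _, _, gts in recs:
            alleles = [int(a) for gt in gts for a in gt.split("/")]
            a, b = alleles.count(0), alleles.count(1)
            n = a + b
            total_pi += 2 * a * b / (n * (n - 1))
        sites = 60 * 1500
        assert total_pi / sites == pytest.approx(theta, rel=0.25)

    def test_zero_theta_gives_no_records(self):
        assert sim.simulate_variants(self._spans(5), 0.0, 24, seed=1) == []

    def test_positions_inside_spans_one_based(self):
        recs = sim.simulate_variants(self._spans(10), 0.005, 12, seed=2)
        assert recs
        for contig, pos, ref, alt, gts in recs:
            assert 1 <= pos <= 1500
            assert ref != alt
            assert len(gts) == 6

    def test_per_gene_theta_mapping(self):
        spans = self._spans(20)
        theta = {g: (0.01 if i < 10 else 0.0) for i, g in enumerate(spans["gene_id"])}
        recs = sim.simulate_variants(spans, theta, 24, seed=3)
        contigs = {r[0] for r in recs}
        assert contigs <= {f"g{i}" for i in range(10)}

    def test_invalid_inputs(self):
        spans = self._spans(2)
        with pytest.raises(ValueError):
            sim.simulate_variants(spans, 0.001, 3, seed=0)  # odd haplotypes
        bad = pd.DataFrame(
            {"contig": ["c", "c"], "start": [0, 100], "end": [200, 300],
             "gene_id": ["a", "b"]}
        )
        with pytest.raises(ValueError):
            sim.simulate_variants(bad, 0.001, 4, seed=0)


class TestStudy:
    def test_all_inputs_written(self, full_study):
        _, res, _ = full_study
        for key, path in res["paths"].items():
            assert path.exists(), key
        assert any(res["taxon_hits_dir"].iterdir())

    def test_truth_consistency(self, full_study):
        _, res, _ = full_study
        truth = res["truth"]
        assert truth["is_fp"].sum() > 0
        # foam proteins are FG-induced in scheme A and FP in scheme B
        fp = truth[truth["is_fp"]]
        assert (fp["scheme_a"] == "FG_Induced").all()
        assert (fp["scheme_b"] == "FP").all()
        # dropped genes are exactly the both_up class
        assert set(truth.index[truth["scheme_a"] == "dropped"]) == set(
            truth.index[truth["study_class"] == "both_up"]
        )

    def test_cds_files_consistent_with_truth(self, full_study):
        _, res, _ = full_study
        truth = res["truth"]
        quail = frio.read_fasta(res["paths"]["quail_cds"])
        chicken = frio.read_fasta(res["paths"]["chicken_cds"])
        assert set(quail) == set(truth.index)
        assert set(chicken) == {f"chick_{g}" for g in truth.index[truth["has_ortholog"]]}

    def test_byte_identical_reruns(self, tmp_path):
        cfg = SimConfig(n_genes=120, seed=55)
        a, b = tmp_path / "a", tmp_path / "b"
        ra = sim.simulate_study(cfg, a)
        rb = sim.simulate_study(cfg, b)
        for key in ra["paths"]:
            assert ra["paths"][key].read_bytes() == rb["paths"][key].read_bytes(), key

    def test_seed_changes_output(self, tmp_path):
        ra = sim.simulate_study(SimConfig(n_genes=120, seed=1), tmp_path / "a")
        rb = sim.simulate_study(SimConfig(n_genes=120, seed=2), tmp_path / "b")
        assert ra["paths"]["counts"].read_bytes() != rb["paths"]["counts"].read_bytes()


class TestConfig:
    def test_fraction_sum_enforced(self):
        fr = dict(SimConfig().class_fractions)
        fr["fp"] += 0.01
        with pytest.raises(ValueError):
            SimConfig(class_fractions=fr)

    def test_roundtrip(self, tmp_path):
        from foamrates.config import load_config, save_config

        cfg = SimConfig(n_genes=111, seed=8)
        save_config(cfg, tmp_path / "c.yaml")
        back = load_config(tmp_path / "c.yaml")
        assert back == cfg
        assert back.digest() == cfg.digest()

    def test_digest_sensitive_to_seed(self):
        assert SimConfig(seed=1).digest() != SimConfig(seed=2).digest()


class TestIO:
    def test_fasta_roundtrip(self, tmp_path):
        seqs = {"a": "ATGAAA", "b": "CCCGGGTTT"}
        frio.write_fasta(seqs, tmp_path / "x.fasta")
        assert frio.read_fasta(tmp_path / "x.fasta") == seqs

    def test_bed_roundtrip(self, tmp_path):
        spans = pd.DataFrame(
            [("c1", 0, 100, "g1"), ("c2", 50, 150, "g2")], columns=frio.BED_COLUMNS
        )
        frio.write_bed(spans, tmp_path / "x.bed")
        assert frio.read_bed(tmp_path / "x.bed").equals(spans)
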