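"""Synthetic study generator: every input the pipeline consumes, with known
ground truth.

All randomness flows from one integer seed through spawned numpy
generators; identical configs give byte-identical outputs. The codon-pair
simulator defines omega operationally the same way the NG86 estimator
measures it: substitutions are proposed uniformly per nucleotide site and
accepted with probability 1 when synonymous and min(1, omega) when
nonsynonymous, with proposals creating internal stop codons rejected.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as frio
from .config import ORIGIN_CLASSES, STUDY_CLASSES, SimConfig, save_config
from .expression import CountMatrix
from .molevol import CODON_AA, NUCS, STOP_CODONS, SYN_SITES
from .orthology import HIT_COLUMNS, ORIGIN_RANK

SENSE_CODONS = sorted(c for c in CODON_AA if c not in STOP_CODONS)
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# codon pairs


def simulate_codon_pair(
    length_codons: int,
    omega: float,
    target_ds: float,
    seed,
) -> tuple[str, str]:
    """Simulate a diverged in-frame CDS pair with operational dN/dS = omega.

    Substitutions accumulate on one copy of a random stop-free ancestor until
    the count of accepted synonymous changes reaches ``target_ds`` times the
    ancestor's NG86 synonymous site count.
    """
    if length_codons < 2:
        raise ValueError("need >= 2 codons")
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if target_ds < 0:
        raise ValueError("target_ds must be >= 0")
    rng = _rng(seed)
    codons = list(rng.choice(SENSE_CODONS, size=length_codons))
    seq1 = "".join(codons)
    if target_ds == 0:
        return seq1, seq1
    s_sites = sum(SYN_SITES[c] for c in codons)
    target_syn = target_ds * s_sites
    derived = list(seq1)
    syn_count = 0
    p_accept_non = min(1.0, omega)
    n_sites = 3 * length_codons
    while syn_count < target_syn:
        pos = int(rng.integers(n_sites))
        old = derived[pos]
        new = NUCS[int(rng.integers(4))]
        if new == old:
            continue
        ci = pos // 3
        codon = "".join(derived[3 * ci : 3 * ci + 3])
        alt = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
        if alt in STOP_CODONS:
            continue
        if CODON_AA[codon] == CODON_AA[alt]:
            derived[pos] = new
            syn_count += 1
        elif rng.random() < p_accept_non:
            derived[pos] = new
    return seq1, "".join(derived)


# ---------------------------------------------------------------------------
# counts


def _study_design(cfg: SimConfig) -> pd.DataFrame:
    """30-sample design: FG in LD/SD/SD+T, testis in LD/SD, n_males each.
    LD and SD males contribute both tissues; SD+T males FG only."""
    rows = []
    male_of = {}
    idx = 0
    for trt in cfg.treatments:
        for m in range(cfg.n_males):
            idx += 1
            male_of[(trt, m)] = f"male{idx:02d}"
    for trt in cfg.treatments:
        for m in range(cfg.n_males):
            rows.append((f"FG_{trt}_{m+1}", "FG", trt, male_of[(trt, m)]))
    for trt in cfg.treatments:
        if trt == "SD+T":
            continue  # testes regressed under SD+T; not sampled
        for m in range(cfg.n_males):
            rows.append((f"Testis_{trt}_{m+1}", "Testis", trt, male_of[(trt, m)]))
    df = pd.DataFrame(rows, columns=["sample_id", "tissue", "treatment", "male_id"])
    return df.set_index("sample_id")


def assign_classes(cfg: SimConfig, rng: np.random.Generator) -> pd.Series:
    """Exact-count class assignment (largest-remainder rounding), shuffled."""
    fracs = cfg.class_fractions
    counts = {c: int(math.floor(fracs[c] * cfg.n_genes)) for c in STUDY_CLASSES}
    remainder = cfg.n_genes - sum(counts.values())
    by_frac = sorted(
        STUDY_CLASSES, key=lambda c: fracs[c] * cfg.n_genes - counts[c], reverse=True
    )
    for c in by_frac[:remainder]:
        counts[c] += 1
    labels = np.repeat([c for c in STUDY_CLASSES], [counts[c] for c in STUDY_CLASSES])
    rng.shuffle(labels)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    return pd.Series(labels, index=genes, name="study_class")


_FG_EXPRESSED_CLASSES = {
    "fp", "fg_induced", "fg_not_induced", "fg_expressed", "both_up",
}
_TESTIS_EXPRESSED_CLASSES = {
    "testis_induced", "testis_not_induced", "both_up", "other", "fg_expressed",
}
_FG_INDUCED_CLASSES = {"fp", "fg_induced", "both_up"}
_TESTIS_INDUCED_CLASSES = {"testis_induced", "both_up"}


def simulate_counts(
    cfg: SimConfig,
    classes: pd.Series | None = None,
    seed=None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix for the full 30-sample design plus per-gene truth.

    Induced genes have their mean multiplied by 2**induced_log2fc in the
    breeding-condition samples (FG: LD and SD+T; testis: LD) relative to SD.
    Library sizes are drawn from ``library_size_range``; composition shifts
    from the induced genes make TMM factors differ from 1.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    if classes is None:
        classes = assign_classes(cfg, rng)
    design = _study_design(cfg)
    genes = classes.index.to_numpy()
    n_genes = len(genes)

    base_rel = np.exp(rng.normal(math.log(30e-6), 1.0, size=n_genes))  # rel abundance
    off_rel = 2e-8  # leaky expression where a gene is "off"

    lib_sizes = rng.integers(
        int(cfg.library_size_range[0]), int(cfg.library_size_range[1]) + 1,
        size=len(design),
    ).astype(float)

    cls = classes.to_numpy()
    fg_expr = np.isin(cls, list(_FG_EXPRESSED_CLASSES))
    te_expr = np.isin(cls, list(_TESTIS_EXPRESSED_CLASSES))
    fg_ind = np.isin(cls, list(_FG_INDUCED_CLASSES))
    te_ind = np.isin(cls, list(_TESTIS_INDUCED_CLASSES))

    fold = 2.0 ** cfg.induced_log2fc
    counts = np.empty((n_genes, len(design)), dtype=np.int64)
    for j, (sample, row) in enumerate(design.iterrows()):
        expressed = fg_expr if row.tissue == "FG" else te_expr
        induced = fg_ind if row.tissue == "FG" else te_ind
        breeding = row.treatment in (("LD", "SD+T") if row.tissue == "FG" else ("LD",))
        rel = np.where(expressed, base_rel, off_rel)
        if breeding:
            rel = rel * np.where(induced & expressed, fold, 1.0)
        mean = rel * lib_sizes[j]
        if cfg.nb_dispersion == 0:
            counts[:, j] = rng.poisson(mean)
        else:
            r = 1.0 / cfg.nb_dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mean))
    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=design.index), design
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "study_class": cls,
            "fg_expressed": fg_expr,
            "induced_fg": fg_ind,
            "induced_testis": te_ind,
        }
    ).set_index("gene_id")
    return cm, truth


# ---------------------------------------------------------------------------
# peptides


def simulate_peptides(
    fp_ids: Sequence[str],
    n_decoys: int = 0,
    seed=0,
    decoy_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Peptide-evidence table: every true foam protein gets >=2 distinct
    peptides at confidence >= 0.99; decoys get 0-1 peptides or sub-threshold
    confidences (drawn uniform on [0.5, 0.99) to exercise the boundary)."""
    fp_ids = list(fp_ids)
    if not fp_ids:
        raise ValueError("fp_ids must be nonempty")
    rng = _rng(seed)
    if decoy_ids is None:
        decoy_ids = [f"decoy{i:05d}" for i in range(n_decoys)]
    else:
        decoy_ids = list(decoy_ids)[:n_decoys]

    def peptide() -> str:
        n = int(rng.integers(8, 18))
        return "".join(rng.choice(list(AA20), size=n)) + "K"

    rows = []
    for pid in fp_ids:
        for _ in range(int(rng.integers(2, 5))):
            rows.append((pid, peptide(), float(rng.uniform(0.99, 1.0))))
    for pid in decoy_ids:
        u = rng.random()
        if u < 0.4:
            continue  # no evidence at all
        n_pep = 1 if u < 0.7 else 2
        for _ in range(n_pep):
            rows.append((pid, peptide(), float(rng.uniform(0.5, 0.99))))
    return pd.DataFrame(rows, columns=["protein_id", "peptide", "confidence"])


# ---------------------------------------------------------------------------
# variants


def simulate_variants(
    gene_spans: pd.DataFrame,
    theta,
    n_haplotypes: int,
    seed=0,
) -> list[tuple]:
    """Biallelic SNPs per gene span with per-site heterozygosity ``theta``.

    Each site within a span segregates with probability theta * a_n (a_n the
    Watterson harmonic number), with derived-allele count i drawn from the
    neutral frequency spectrum P(i) ~ 1/i; this makes the expected per-site
    pairwise diversity equal theta. ``theta`` may be a scalar or a mapping
    gene_id -> theta. Spans are BED-style (0-based half-open); VCF records
    are 1-based. Returns records compatible with :func:`foamrates.io.write_vcf`.
    """
    if n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    if n_haplotypes % 2:
        raise ValueError("haplotypes must pair into diploid samples")
    rng = _rng(seed)
    spans = gene_spans.sort_values(["contig", "start"])
    for contig, grp in spans.groupby("contig"):
        ends = grp["end"].to_numpy()
        starts = grp["start"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping spans on contig {contig}")

    n = n_haplotypes
    a_n = sum(1.0 / i for i in range(1, n))
    freqs = np.arange(1, n)
    sfs = (1.0 / freqs) / (1.0 / freqs).sum()
    records = []
    for span in spans.itertuples(index=False):
        th = theta.get(span.gene_id, 0.0) if isinstance(theta, Mapping) else float(theta)
        if th < 0:
            raise ValueError("theta must be >= 0")
        p_seg = min(th * a_n, 0.99)
        if p_seg == 0:
            continue
        length = span.end - span.start
        n_snps = rng.binomial(length, p_seg)
        if n_snps == 0:
            continue
        positions = np.sort(
            rng.choice(np.arange(span.start + 1, span.end + 1), size=n_snps, replace=False)
        )
        for pos in positions:
            i = int(rng.choice(freqs, p=sfs))
            carriers = set(rng.choice(n, size=i, replace=False).tolist())
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            gts = []
            for d in range(n // 2):
                a1 = 1 if 2 * d in carriers else 0
                a2 = 1 if 2 * d + 1 in carriers else 0
                gts.append(f"{a1}/{a2}")
            records.append((span.contig, int(pos), ref, alt, gts))
    return records


# ---------------------------------------------------------------------------
# taxon proteomes (gene ages)


def mutate_protein(prot: str, rate: float, rng: np.random.Generator) -> str:
    out = list(prot)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AA20[int(rng.integers(20))]
    return "".join(out)


def make_taxon_proteomes(
    ages: Mapping[str, str],
    taxa: Mapping[str, str],
    seed=0,
    focal_taxon: str = "quail",
    length: int = 60,
    noise: float = 0.04,
) -> dict[str, dict[str, str]]:
    """Per-taxon protein sets with planted gene ages.

    A gene planted with age class A gets a (noised) homolog in exactly the
    taxa whose class rank is <= A's rank; the focal taxon always carries it.
    Requires every used age class to have a taxon of exactly that class.
    """
    covered = set(taxa.values())
    missing = set(ages.values()) - covered
    if missing:
        raise ValueError(f"no taxon for age classes: {sorted(missing)}")
    rng = _rng(seed)
    proteomes: dict[str, dict[str, str]] = {t: {} for t in taxa}
    proteomes.setdefault(focal_taxon, {})
    for gene, age in ages.items():
        base = "".join(rng.choice(list(AA20), size=length))
        rank = ORIGIN_RANK[age]
        for taxon, cls in taxa.items():
            if taxon == focal_taxon:
                continue
            if ORIGIN_RANK[cls] <= rank:
                proteomes[taxon][f"{gene}_{taxon}"] = mutate_protein(base, noise, rng)
        proteomes[focal_taxon][gene] = base
    return proteomes


# ---------------------------------------------------------------------------
# hit tables from planted truth


def _hit_row(q, s, bitscore, length=150):
    ident = min(99.9, 40.0 + bitscore / 10.0)
    return (q, s, ident, length, 10, 0, 1, length, 1, length, 10.0 ** (-bitscore / 3.0), bitscore)


def hits_from_ortholog_truth(
    pairs: Mapping[str, str],
    all_queries: Iterable[str],
    all_subjects: Iterable[str],
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directional 12-column hit tables realizing planted 1:1 orthologs.

    Each planted pair gets strong reciprocal top hits; a sample of decoy
    cross-hits at lower bitscore exercises the best-hit logic; genes without
    orthologs get either nothing or a sub-cutoff (high e-value) hit.
    """
    rng = _rng(seed)
    all_subjects = list(all_subjects)
    fwd, rev = [], []
    for q, s in pairs.items():
        score = float(rng.uniform(300, 600))
        fwd.append(_hit_row(q, s, score))
        rev.append(_hit_row(s, q, score + float(rng.uniform(-5, 5))))
        # paralog-like decoy hit at clearly lower score
        if len(all_subjects) > 1 and rng.random() < 0.3:
            decoy = all_subjects[int(rng.integers(len(all_subjects)))]
            if decoy != s:
                fwd.append(_hit_row(q, decoy, score * float(rng.uniform(0.3, 0.7))))
    orphan_queries = sorted(set(all_queries) - set(pairs))
    for q in orphan_queries:
        if rng.random() < 0.2 and all_subjects:
            s = all_subjects[int(rng.integers(len(all_subjects)))]
            row = list(_hit_row(q, s, 20.0))
            row[10] = 1e-3  # fails the 1e-6 e-value cutoff
            fwd.append(tuple(row))
    return (
        pd.DataFrame(fwd, columns=HIT_COLUMNS),
        pd.DataFrame(rev, columns=HIT_COLUMNS),
    )


def taxon_hits_from_ages(
    ages: Mapping[str, str],
    taxa: Mapping[str, str],
    focal_taxon: str,
    seed=0,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Cross-taxon hit tables whose RBH graph recovers the planted ages.

    Each gene's homolog is present in the taxa at or below its age rank; all
    taxon pairs sharing the gene exchange reciprocal best hits.
    """
    rng = _rng(seed)
    taxon_list = sorted(taxa)
    tables: dict[tuple[str, str], list] = {}
    for gene, age in ages.items():
        rank = ORIGIN_RANK[age]
        members = [focal_taxon] + [
            t for t in taxon_list
            if t != focal_taxon and ORIGIN_RANK[taxa[t]] <= rank
        ]
        for i, ta in enumerate(members):
            for tb in members[i + 1 :]:
                score = float(rng.uniform(200, 500))
                qa = gene if ta == focal_taxon else f"{gene}_{ta}"
                qb = gene if tb == focal_taxon else f"{gene}_{tb}"
                tables.setdefault((ta, tb), []).append(_hit_row(qa, qb, score))
                tables.setdefault((tb, ta), []).append(_hit_row(qb, qa, score))
    return {
        key: pd.DataFrame(rows, columns=HIT_COLUMNS) for key, rows in tables.items()
    }


# ---------------------------------------------------------------------------
# full study


def simulate_study(cfg: SimConfig, outdir) -> dict:
    """Generate every pipeline input under ``outdir`` and return paths plus
    the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed)
    (
        s_classes, s_counts, s_pept, s_orth, s_ages, s_var, s_chrom,
    ) = [np.random.default_rng(s) for s in root.spawn(7)]

    classes = assign_classes(cfg, s_classes)
    cm, truth = simulate_counts(cfg, classes=classes, seed=s_counts)
    genes = list(classes.index)
    cls = classes

    fg_enriched = sorted(cls.index[cls.isin(["fp", "fg_induced", "fg_not_induced"])])
    testis_enriched = sorted(
        cls.index[cls.isin(["testis_induced", "testis_not_induced", "both_up"])]
    )
    fg_expressed = sorted(cls.index[cls.isin(list(_FG_EXPRESSED_CLASSES))])
    fp_ids = sorted(cls.index[cls == "fp"])

    # peptide evidence: true FPs plus decoys drawn from other FG genes
    decoy_pool = sorted(cls.index[cls.isin(["fg_induced", "fg_expressed"])])
    n_decoys = min(len(decoy_pool), 10 * len(fp_ids))
    decoys = list(s_pept.choice(decoy_pool, size=n_decoys, replace=False))
    peptides = simulate_peptides(fp_ids, n_decoys, seed=s_pept, decoy_ids=decoys)

    # orthologs: presence by class, CDS pairs at planted omega
    has_ortholog = {}
    true_omega = {}
    quail_cds: dict[str, str] = {}
    chicken_cds: dict[str, str] = {}
    pair_map: dict[str, str] = {}
    lo, hi = cfg.cds_codons_range
    for g in genes:
        c = cls[g]
        has = s_orth.random() < cfg.ortholog_fraction.get(c, 0.0)
        has_ortholog[g] = has
        length = int(s_orth.integers(lo, hi + 1))
        omega = cfg.omega_by_class[c]
        seq1, seq2 = simulate_codon_pair(length, omega, cfg.target_ds if has else 0.0, s_orth)
        quail_cds[g] = seq1
        if has:
            chicken_id = f"chick_{g}"
            chicken_cds[chicken_id] = seq2
            pair_map[g] = chicken_id
            true_omega[g] = omega
        else:
            true_omega[g] = float("nan")
    hits_q2c, hits_c2q = hits_from_ortholog_truth(
        pair_map, genes, list(chicken_cds), seed=s_orth
    )

    # chromosome classes keyed by chicken id
    chrom_rows = [
        (cid, "Z" if s_chrom.random() < cfg.z_fraction else "autosome")
        for cid in sorted(chicken_cds)
    ]
    chrom = pd.DataFrame(chrom_rows, columns=["chicken_id", "chrom_class"])

    # gene ages for ortholog genes, multi-taxon hit tables
    ages = {}
    for g in genes:
        if not has_ortholog[g]:
            continue
        w = np.asarray(cfg.age_weights[cls[g]], dtype=float)
        ages[g] = str(s_ages.choice(ORIGIN_CLASSES, p=w / w.sum()))
    taxon_tables = taxon_hits_from_ages(ages, cfg.taxa, cfg.focal_taxon, seed=s_ages)

    # variants
    spans = pd.DataFrame(
        {
            "contig": genes,
            "start": 0,
            "end": cfg.gene_length_bp,
            "gene_id": genes,
        }
    )
    theta_map = {g: cfg.theta_by_class.get(cls[g], cfg.theta) for g in genes}
    var_records = simulate_variants(spans, theta_map, cfg.n_haplotypes, seed=s_var)

    truth = truth.assign(
        scheme_a=[_scheme_a_truth(c) for c in truth["study_class"]],
        scheme_b=[_scheme_b_truth(c) for c in truth["study_class"]],
        is_fp=truth["study_class"] == "fp",
        has_ortholog=[has_ortholog[g] for g in truth.index],
        true_omega=[true_omega[g] for g in truth.index],
        origin=[ages.get(g, "") for g in truth.index],
        theta=[theta_map[g] for g in truth.index],
    )

    paths = {
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "fg_enriched": outdir / "fg_enriched.txt",
        "testis_enriched": outdir / "testis_enriched.txt",
        "fg_expressed": outdir / "fg_expressed.txt",
        "peptides": outdir / "peptides.tsv",
        "quail_cds": outdir / "quail_cds.fasta",
        "chicken_cds": outdir / "chicken_cds.fasta",
        "hits_q2c": outdir / "hits_quail_chicken.tsv",
        "hits_c2q": outdir / "hits_chicken_quail.tsv",
        "chrom": outdir / "chrom_classes.tsv",
        "spans": outdir / "genes.bed",
        "vcf": outdir / "variants.vcf",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.yaml",
        "taxa": outdir / "taxa.tsv",
    }
    frio.write_tsv(cm.counts.rename_axis("gene_id").reset_index(), paths["counts"])
    frio.write_tsv(cm.design.rename_axis("sample_id").reset_index(), paths["design"])
    for key, ids in (
        ("fg_enriched", fg_enriched),
        ("testis_enriched", testis_enriched),
        ("fg_expressed", fg_expressed),
    ):
        paths[key].write_text("\n".join(ids) + "\n")
    frio.write_tsv(peptides, paths["peptides"])
    frio.write_fasta(quail_cds, paths["quail_cds"])
    frio.write_fasta(chicken_cds, paths["chicken_cds"])
    hits_q2c.to_csv(paths["hits_q2c"], sep="\t", header=False, index=False)
    hits_c2q.to_csv(paths["hits_c2q"], sep="\t", header=False, index=False)
    frio.write_tsv(chrom, paths["chrom"])
    frio.write_bed(spans, paths["spans"])
    sample_names = [f"ind{i+1:02d}" for i in range(cfg.n_haplotypes // 2)]
    contig_lengths = {g: cfg.gene_length_bp for g in genes}
    frio.write_vcf(var_records, contig_lengths, sample_names, paths["vcf"])
    frio.write_tsv(truth.reset_index(), paths["truth"])
    save_config(cfg, paths["config"])
    frio.write_tsv(
        pd.DataFrame(sorted(cfg.taxa.items()), columns=["taxon", "origin_class"]),
        paths["taxa"],
    )

    taxa_dir = outdir / "taxon_hits"
    taxa_dir.mkdir(exist_ok=True)
    for (ta, tb), table in sorted(taxon_tables.items()):
        table.to_csv(taxa_dir / f"{ta}__{tb}.tsv", sep="\t", header=False, index=False)

    return {
        "paths": paths,
        "taxon_hits_dir": taxa_dir,
        "count_matrix": cm,
        "truth": truth,
        "classes": classes,
    }


def _scheme_a_truth(study_class: str) -> str:
    return {
        "fp": "FG_Induced",
        "fg_induced": "FG_Induced",
        "fg_not_induced": "FG_Not_Induced",
        "testis_induced": "Testis_Induced",
        "testis_not_induced": "Testis_Not_Induced",
        "both_up": "dropped",
        "fg_expressed": "",
        "other": "",
    }[study_class]


def _scheme_b_truth(study_class: str) -> str:
    return {
        "fp": "FP",
        "fg_induced": "FG_Enriched",
        "fg_not_induced": "FG_Enriched",
        "testis_induced": "Other",
        "testis_not_induced": "Other",
        "both_up": "FG_Expressed",
        "fg_expressed": "FG_Expressed",
        "other": "Other",
    }[study_class]
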