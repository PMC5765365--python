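"""End-to-end study pipeline: simulate -> classify -> orthologs -> rates ->
pi -> report, with logged provenance (config digest, seed, versions).

Each ``stage_*`` function reads the study inputs (and any earlier stage's
outputs) from disk and writes its own outputs, so the numbered driver scripts
under ``analysis/`` can run them independently; :func:`analyze_study` chains
them all.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import expression as expr
from . import io as frio
from . import molevol, orthology, popgen, proteome, stats
from .config import SimConfig, load_config
from .simulate import simulate_study

FG_CONTRAST_LD = "LD_vs_SD_FG"
FG_CONTRAST_SDT = "SD+T_vs_SD_FG"
TESTIS_CONTRAST_LD = "LD_vs_SD_Testis"


def _read_id_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def _de_by_contrast(outdir: Path) -> dict[str, pd.DataFrame]:
    de_all = frio.read_tsv(outdir / "de_results.tsv")
    return {name: grp for name, grp in de_all.groupby("contrast")}


def stage_expression(
    input_dir, outdir, lfc_min: float = 1.0, q_max: float = 0.05
) -> pd.DataFrame:
    """CPM filter, TMM, the three treatment contrasts, and the
    tissue-by-induction grouping (scheme A). Writes de_results.tsv and
    categories_scheme_a.tsv; returns the scheme A table."""
    input_dir, outdir = Path(input_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts = frio.read_tsv(input_dir / "counts.tsv").set_index("gene_id")
    design = frio.read_tsv(input_dir / "design.tsv").set_index("sample_id")
    cm_all = expr.CountMatrix(counts, design)
    cm = expr.cpm_filter(cm_all, min_cpm=1.0, min_samples=6)

    de_fg_ld = expr.test_de(cm, ("LD", "SD"), tissue="FG")
    de_fg_sdt = expr.test_de(cm, ("SD+T", "SD"), tissue="FG")
    de_te_ld = expr.test_de(cm, ("LD", "SD"), tissue="Testis")
    de_all = pd.concat([de_fg_ld, de_fg_sdt, de_te_ld], ignore_index=True)
    frio.write_tsv(de_all, outdir / "de_results.tsv")
    (outdir / "n_genes_after_cpm_filter.txt").write_text(f"{len(cm.counts)}\n")

    scheme_a = expr.classify_scheme_a(
        _read_id_list(input_dir / "fg_enriched.txt"),
        _read_id_list(input_dir / "testis_enriched.txt"),
        de_fg_ld, de_fg_sdt, de_te_ld,
        lfc_min=lfc_min, q_max=q_max,
    )
    frio.write_tsv(scheme_a, outdir / "categories_scheme_a.tsv")
    return scheme_a


def stage_proteome(
    input_dir, outdir, lfc_min: float = 1.0, q_max: float = 0.05
) -> pd.DataFrame:
    """Foam-protein calls (peptide evidence x induced expression) and the
    least-inclusive grouping (scheme B). Needs stage_expression outputs.
    Writes fp_called.txt, categories_scheme_b.tsv and the combined
    categories.tsv; returns the scheme B table."""
    input_dir, outdir = Path(input_dir), Path(outdir)
    de = _de_by_contrast(outdir)
    peptides = frio.read_tsv(input_dir / "peptides.tsv")
    confident = proteome.call_confident_proteins(peptides)
    up_both = expr._up_set(de[FG_CONTRAST_LD], lfc_min, q_max) & expr._up_set(
        de[FG_CONTRAST_SDT], lfc_min, q_max
    )
    fp_ids = proteome.intersect_fp(confident, up_both)
    (outdir / "fp_called.txt").write_text("\n".join(sorted(fp_ids)) + "\n")

    counts = frio.read_tsv(input_dir / "counts.tsv")
    scheme_b = expr.classify_scheme_b(
        fp_ids,
        _read_id_list(input_dir / "fg_enriched.txt"),
        _read_id_list(input_dir / "fg_expressed.txt"),
        counts["gene_id"],
    )
    frio.write_tsv(scheme_b, outdir / "categories_scheme_b.tsv")

    scheme_a = frio.read_tsv(outdir / "categories_scheme_a.tsv")
    categories = pd.concat(
        [scheme_a.assign(scheme="A"), scheme_b.assign(scheme="B")],
        ignore_index=True,
    )
    frio.write_tsv(categories, outdir / "categories.tsv")
    return scheme_b


def stage_rates(input_dir, outdir) -> pd.DataFrame:
    """RBH ortholog pairs, protein-guided codon alignment, NG86 rates and the
    dS quality filters. Writes ortholog_pairs.tsv, rates.tsv,
    chrom_by_gene.tsv and rate_exclusions.tsv; returns the kept rates."""
    input_dir, outdir = Path(input_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    hits_q2c = orthology.read_hits(input_dir / "hits_quail_chicken.tsv")
    hits_c2q = orthology.read_hits(input_dir / "hits_chicken_quail.tsv")
    pairs = orthology.reciprocal_best_hits(hits_q2c, hits_c2q)
    frio.write_tsv(pairs, outdir / "ortholog_pairs.tsv")

    quail_cds = frio.read_fasta(input_dir / "quail_cds.fasta")
    chicken_cds = frio.read_fasta(input_dir / "chicken_cds.fasta")
    estimates, rejected = [], []
    for q, s in pairs.itertuples(index=False):
        try:
            estimates.append(molevol.pair_rates(quail_cds[q], chicken_cds[s], pair_id=q))
        except ValueError:
            rejected.append(q)
    kept, excluded = molevol.filter_rates(estimates)
    rates = pd.DataFrame(
        [
            {
                "gene_id": e.pair_id, "S": e.S, "N": e.N, "Sd": e.Sd, "Nd": e.Nd,
                "dS": e.dS, "dN": e.dN, "omega": e.omega,
                "flags": ",".join(sorted(e.flags)),
            }
            for e in kept
        ]
    )
    frio.write_tsv(rates, outdir / "rates.tsv")
    exclusions = pd.DataFrame(
        [(g, reason) for g, reason in excluded]
        + [(g, "alignment_failed") for g in rejected],
        columns=["gene_id", "reason"],
    )
    frio.write_tsv(exclusions, outdir / "rate_exclusions.tsv")

    chrom_by_chicken = frio.read_tsv(input_dir / "chrom_classes.tsv")
    chrom = pairs.merge(
        chrom_by_chicken, left_on="subject_id", right_on="chicken_id", how="left"
    )[["query_id", "chrom_class"]].rename(columns={"query_id": "gene_id"})
    chrom["chrom_class"] = chrom["chrom_class"].fillna("unknown")
    frio.write_tsv(chrom, outdir / "chrom_by_gene.tsv")
    return rates


def stage_ages(input_dir, outdir) -> pd.DataFrame:
    """Orthogroup clustering over all taxa and gene-age (origin) assignment.
    Writes origins.tsv; returns it."""
    input_dir, outdir = Path(input_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    taxa_df = frio.read_tsv(input_dir / "taxa.tsv")
    taxon_classes = dict(zip(taxa_df["taxon"], taxa_df["origin_class"]))
    taxon_tables = {}
    for path in sorted((input_dir / "taxon_hits").glob("*.tsv")):
        ta, tb = path.stem.split("__")
        taxon_tables[(ta, tb)] = orthology.read_hits(path)
    groups = orthology.build_orthogroups(taxon_tables)
    origins, _ = orthology.assign_origin(groups, taxon_classes, "quail")
    frio.write_tsv(origins, outdir / "origins.tsv")
    return origins


def stage_pi(input_dir, outdir, window: int = 500) -> pd.DataFrame:
    """Windowed nucleotide diversity and per-gene means. Writes
    pi_windows.tsv and gene_pi.tsv; returns the per-gene table."""
    input_dir, outdir = Path(input_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    spans = frio.read_bed(input_dir / "genes.bed")
    contig_lengths = dict(zip(spans["contig"], spans["end"]))
    windows = popgen.pi_windows(str(input_dir / "variants.vcf"), contig_lengths, window)
    frio.write_tsv(windows, outdir / "pi_windows.tsv")
    gene_pi = popgen.gene_mean_pi(windows, spans)
    frio.write_tsv(gene_pi, outdir / "gene_pi.tsv")
    return gene_pi


def stage_report(
    input_dir, outdir, bootstrap_reps: int = 10_000, seed: int = 0
) -> dict:
    """Group-level statistics over all earlier stage outputs: bootstrap omega
    summaries per scheme and chromosome stratum, ortholog-fraction panels
    with compact letters, pi ANOVA/Tukey, and the origin distribution.
    Writes report.json, summary.txt and per-scheme TSVs; returns the report."""
    input_dir, outdir = Path(input_dir), Path(outdir)

    categories = frio.read_tsv(outdir / "categories.tsv")
    scheme_a = categories[categories["scheme"] == "A"][["gene_id", "label"]]
    scheme_b = categories[categories["scheme"] == "B"][["gene_id", "label"]]
    rates = frio.read_tsv(outdir / "rates.tsv")
    pairs = frio.read_tsv(outdir / "ortholog_pairs.tsv")
    chrom = frio.read_tsv(outdir / "chrom_by_gene.tsv")
    origins = frio.read_tsv(outdir / "origins.tsv")
    gene_pi = frio.read_tsv(outdir / "gene_pi.tsv")
    exclusions = frio.read_tsv(outdir / "rate_exclusions.tsv")
    fp_ids = _read_id_list(outdir / "fp_called.txt")

    pi_a = gene_pi.merge(scheme_a, on="gene_id")
    pi_a["tissue"] = np.where(pi_a["label"].str.startswith("FG"), "FG", "Testis")
    pi_a["status"] = np.where(
        pi_a["label"].str.endswith("Not_Induced"), "Not_Induced", "Induced"
    )
    anova_a = popgen.anova_two_way(pi_a)
    pi_b = gene_pi.merge(scheme_b, on="gene_id")
    tukey_b = popgen.tukey_hsd(pi_b)

    rng = np.random.default_rng(seed)
    summaries, comparisons, panels, letters = {}, {}, {}, {}
    with_orth = set(pairs["query_id"])
    for scheme, cats in (("A", scheme_a), ("B", scheme_b)):
        summ, comp = stats.stratified_rate_report(
            rates[["gene_id", "omega"]], cats, chrom,
            reps=bootstrap_reps, seed=int(rng.integers(2**31)),
        )
        summaries[scheme] = summ
        comparisons[scheme] = comp
        counts_by_cat = {
            label: (int(sum(g in with_orth for g in grp["gene_id"])), len(grp))
            for label, grp in cats.groupby("label")
        }
        panel, lett = stats.proportion_panel(counts_by_cat)
        panels[scheme] = panel.assign(scheme=scheme)
        letters[scheme] = lett

    origin_dist = (
        origins.merge(scheme_b, on="gene_id")
        .groupby(["label", "origin"]).size().rename("n_genes").reset_index()
    )

    n_filtered_path = outdir / "n_genes_after_cpm_filter.txt"
    counts = frio.read_tsv(input_dir / "counts.tsv")
    report = {
        "provenance": {
            "package_version": __version__,
            "seed": seed,
            "bootstrap_reps": bootstrap_reps,
            "numpy_version": np.__version__,
            "n_genes_input": int(len(counts)),
            "n_genes_after_cpm_filter": int(n_filtered_path.read_text().strip())
            if n_filtered_path.exists() else None,
        },
        "n_fp_called": len(fp_ids),
        "n_ortholog_pairs": int(len(pairs)),
        "n_rates_kept": int(len(rates)),
        "rate_exclusions": list(map(tuple, exclusions.values)),
        "omega_summaries": {
            s: df.to_dict(orient="records") for s, df in summaries.items()
        },
        "ci_comparisons": {
            s: df.to_dict(orient="records") for s, df in comparisons.items()
        },
        "ortholog_fraction_panels": {
            s: df.to_dict(orient="records") for s, df in panels.items()
        },
        "ortholog_fraction_letters": letters,
        "anova_scheme_a_pi": anova_a.reset_index(names="term").to_dict(orient="records"),
        "tukey_scheme_b_pi": tukey_b.to_dict(orient="records"),
        "origin_distribution": origin_dist.to_dict(orient="records"),
    }
    cfg_path = input_dir / "sim_config.yaml"
    if cfg_path.exists():
        report["provenance"]["config_digest"] = load_config(cfg_path).digest()

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    for scheme in ("A", "B"):
        frio.write_tsv(summaries[scheme], outdir / f"omega_summary_scheme{scheme}.tsv")
        frio.write_tsv(panels[scheme], outdir / f"ortholog_panel_scheme{scheme}.tsv")
    (outdir / "summary.txt").write_text(_summary_text(report))
    return report


def analyze_study(
    input_dir,
    outdir,
    bootstrap_reps: int = 10_000,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
    seed: int = 0,
) -> dict:
    """Run every analysis stage on a directory of study inputs.

    ``input_dir`` must hold the files written by
    :func:`foamrates.simulate.simulate_study` (or equivalently formatted real
    inputs). Writes per-stage TSVs plus report.json and summary.txt under
    ``outdir`` and returns the report dictionary.
    """
    stage_expression(input_dir, outdir, lfc_min=lfc_min, q_max=q_max)
    stage_proteome(input_dir, outdir, lfc_min=lfc_min, q_max=q_max)
    stage_rates(input_dir, outdir)
    stage_ages(input_dir, outdir)
    stage_pi(input_dir, outdir)
    return stage_report(input_dir, outdir, bootstrap_reps=bootstrap_reps, seed=seed)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _summary_text(report: dict) -> str:
    lines = [
        "Synthetic study report",
        "======================",
        f"foam proteins called: {report['n_fp_called']}",
        f"reciprocal-best-hit ortholog pairs: {report['n_ortholog_pairs']}",
        f"rate estimates kept after dS filters: {report['n_rates_kept']}",
        "",
        "mean pairwise omega with 95% bootstrap CI (all genes):",
    ]
    for scheme in ("A", "B"):
        for row in report["omega_summaries"][scheme]:
            if row["stratum"] != "all":
                continue
            lines.append(
                f"  [{scheme}] {row['label']:<20s} n={row['n']:<5d} "
                f"mean={row['mean']:.4f}  CI=({row['ci_low']:.4f}, {row['ci_high']:.4f})"
            )
    lines.append("")
    lines.append("ortholog fractions (shared letters = not significantly different):")
    for scheme in ("A", "B"):
        for label, lett in report["ortholog_fraction_letters"][scheme].items():
            lines.append(f"  [{scheme}] {label:<20s} letters={lett}")
    return "\n".join(lines) + "\n"


def run(config: SimConfig | str | Path, outdir, bootstrap_reps: int = 10_000) -> dict:
    """Simulate the full study and analyze it: the one-command entry point."""
    cfg = config if isinstance(config, SimConfig) else load_config(config)
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    simulate_study(cfg, inputs)
    return analyze_study(
        inputs, outdir / "analysis", bootstrap_reps=bootstrap_reps, seed=cfg.seed
    )
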