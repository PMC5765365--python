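"""Ortholog calling and evolutionary-origin (gene-age) assignment.

Orthologs between the focal transcriptome and a reference proteome are
called by reciprocal best hit (RBH) over 12-column similarity-hit tables.
Across several taxa, genes are clustered into orthogroups (reciprocal-best
edges between taxa, better-than-between-taxa edges within taxa, connected
components) and each focal gene is dated by the most distantly related taxon
represented in its orthogroup, on the fixed order
Aves < Vertebrate < Animal < Eukaryote < Bacteria+Archaea.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .molevol import CODON_AA, NUCS, STOP_CODONS

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

ORIGIN_ORDER = ["Aves", "Vertebrate", "Animal", "Eukaryote", "Bacteria+Archaea"]
ORIGIN_RANK = {c: i for i, c in enumerate(ORIGIN_ORDER)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_longest_orf(
    transcript: str, min_codons: int = 30
) -> tuple[str, int, int, int] | None:
    """Longest stop-free, stop-terminated ORF over all 6 reading frames.

    An ORF is a run of non-stop codons ending at a stop codon (runs that hit
    the end of the sequence without a stop are not complete ORFs and are
    ignored). Returns (protein, frame, start, end) where frame is +1..+3 /
    -1..-3 and (start, end) are 0-based half-open coordinates on the read
    strand, excluding the stop. Ties broken by frame order +1,+2,+3,-1,-2,-3.
    Returns None when no ORF reaches ``min_codons`` codons.
    """
    seq = transcript.upper()
    best: tuple[str, int, int, int] | None = None
    frames = [(seq, 1), (seq, 2), (seq, 3)]
    rc = reverse_complement(seq)
    frames += [(rc, -1), (rc, -2), (rc, -3)]
    for s, frame in frames:
        off = abs(frame) - 1
        codons = [s[i : i + 3] for i in range(off, len(s) - 2, 3)]
        run_start = 0
        for i, codon in enumerate(codons):
            if codon not in STOP_CODONS:
                continue
            run = codons[run_start:i]
            if len(run) >= min_codons and (best is None or len(run) > len(best[0])):
                prot = "".join(
                    CODON_AA[c] if all(b in NUCS for b in c) else "X" for c in run
                )
                start = off + 3 * run_start
                best = (prot, frame, start, start + 3 * len(run))
            run_start = i + 1
    return best


def read_hits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)


def _top_hits(hits: pd.DataFrame, max_evalue: float) -> pd.Series:
    """Best subject per query: highest bitscore, ties by lower e-value then
    lexicographic subject id."""
    ok = hits[hits["evalue"] <= max_evalue]
    if ok.empty:
        return pd.Series(dtype=object)
    ranked = ok.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("qseqid", keep="first")
    return best.set_index("qseqid")["sseqid"]


def reciprocal_best_hits(
    q2s: pd.DataFrame, s2q: pd.DataFrame, max_evalue: float = 1e-6
) -> pd.DataFrame:
    """RBH ortholog pairs from the two directional hit tables.

    A pair (q, s) is emitted iff s is q's top hit (by bit score) and q is s's
    top hit, both passing ``max_evalue``. The result is one-to-one.
    """
    fwd = _top_hits(q2s, max_evalue)
    rev = _top_hits(s2q, max_evalue)
    pairs = [
        (q, s)
        for q, s in fwd.items()
        if rev.get(s) == q
    ]
    return pd.DataFrame(pairs, columns=["query_id", "subject_id"])


def build_orthogroups(
    hit_tables: Mapping[tuple[str, str], pd.DataFrame],
    max_evalue: float = 1e-6,
) -> dict[tuple[str, str], int]:
    """Cluster genes across taxa into orthogroups.

    ``hit_tables`` maps ordered taxon pairs (a, b) to the a->b hit table;
    both directions must be present for RBH edges between distinct taxa.
    Within-taxon tables (a, a), if given, contribute edges whose bitscore
    exceeds the gene's best between-taxa bitscore (recent paralogs). Genes
    are keyed as (taxon, gene id); orthogroups are connected components.
    """
    graph: nx.Graph = nx.Graph()
    # best between-taxa bitscore per (taxon, gene), for within-taxon edges
    best_between: dict[tuple[str, str], float] = {}
    for (ta, tb), hits in hit_tables.items():
        ok = hits[hits["evalue"] <= max_evalue]
        if ta == tb:
            continue
        for q, grp in ok.groupby("qseqid")["bitscore"]:
            key = (ta, q)
            m = float(grp.max())
            if m > best_between.get(key, float("-inf")):
                best_between[key] = m

    taxa_pairs = {(a, b) for (a, b) in hit_tables if a != b}
    done: set[frozenset] = set()
    for ta, tb in sorted(taxa_pairs):
        key = frozenset((ta, tb))
        if key in done or (tb, ta) not in taxa_pairs:
            continue
        done.add(key)
        pairs = reciprocal_best_hits(
            hit_tables[(ta, tb)], hit_tables[(tb, ta)], max_evalue
        )
        for q, s in pairs.itertuples(index=False):
            graph.add_edge((ta, q), (tb, s))

    for (ta, tb), hits in hit_tables.items():
        if ta != tb:
            continue
        ok = hits[(hits["evalue"] <= max_evalue) & (hits["qseqid"] != hits["sseqid"])]
        for row in ok.itertuples(index=False):
            thresh = best_between.get((ta, row.qseqid))
            if thresh is not None and row.bitscore > thresh:
                graph.add_edge((ta, row.qseqid), (ta, row.sseqid))

    membership: dict[tuple[str, str], int] = {}
    for gid, comp in enumerate(sorted(nx.connected_components(graph), key=sorted)):
        for node in comp:
            membership[node] = gid
    return membership


def assign_origin(
    orthogroups: Mapping[tuple[str, str], int],
    taxon_classes: Mapping[str, str],
    focal_taxon: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Date each focal gene by the most distant taxon in its orthogroup.

    Returns (DataFrame[gene_id, origin], unclassified focal gene ids are not
    known here — callers compare against their full gene list). The second
    element lists focal genes present in the membership map but whose group
    contains no classifiable taxon (should not happen with valid input).
    """
    by_group: dict[int, list[tuple[str, str]]] = {}
    for node, gid in orthogroups.items():
        by_group.setdefault(gid, []).append(node)
    rows = []
    problems: list[str] = []
    for node, gid in orthogroups.items():
        taxon, gene = node
        if taxon != focal_taxon:
            continue
        ranks = [
            ORIGIN_RANK[taxon_classes[t]]
            for t, _ in by_group[gid]
            if t in taxon_classes
        ]
        if not ranks:
            problems.append(gene)
            continue
        rows.append((gene, ORIGIN_ORDER[max(ranks)]))
    df = pd.DataFrame(rows, columns=["gene_id", "origin"]).sort_values("gene_id")
    return df.reset_index(drop=True), problems


def all_pairs_hits(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    min_identity: float = 0.5,
) -> pd.DataFrame:
    """Derive a 12-column similarity-hit table from two protein sets.

    Global edit distance (edlib) provides the similarity: identity is
    1 - dist/max_len; hits below ``min_identity`` are suppressed (mimicking a
    search tool's reporting threshold). Bitscore is scaled identity x length;
    the e-value is a decreasing function of the score, adequate for
    thresholding at 1e-6 in downstream RBH calls.
    """
    import edlib

    rows = []
    for q, pq in proteins_a.items():
        for s, ps in proteins_b.items():
            dist = edlib.align(pq, ps, task="distance")["editDistance"]
            length = max(len(pq), len(ps))
            ident = 1.0 - dist / length
            if ident < min_identity:
                continue
            bitscore = round(2.0 * ident * length, 1)
            evalue = 10.0 ** (-min(bitscore / 2.0, 180.0))
            rows.append(
                (q, s, round(100 * ident, 2), length, dist, 0, 1, len(pq), 1, len(ps), evalue, bitscore)
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)
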