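"""Pairwise protein-coding divergence: codon alignments and NG86 dN/dS.

The estimator is the Nei–Gojobori (1986) counting method with Jukes–Cantor
multiple-hit correction. Synonymous site counts treat each codon position as
contributing the fraction of its three possible single-nucleotide changes
that are synonymous; changes creating stop codons count as nonsynonymous.
Codons differing at more than one position average synonymous/nonsynonymous
difference counts over all minimal mutational pathways with equal weights,
excluding pathways that pass through a stop codon.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

NUCS = "ACGT"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, with '*' for stops
CODON_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_AA[_stop] = "*"

STOP_CODONS = frozenset(_STANDARD.stop_codons)


def translate_codon(codon: str) -> str:
    return CODON_AA[codon]


def _synonymous_fraction(codon: str) -> float:
    """Number of synonymous sites in one codon (sum over 3 positions of the
    fraction of the 3 possible changes that are synonymous)."""
    aa = CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for n in NUCS:
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1 :]
            if CODON_AA[alt] == aa:  # stops ('*') never match a sense codon
                syn += 1
        s += syn / 3.0
    return s


#: per-codon synonymous site counts, precomputed for all 61 sense codons
SYN_SITES: dict[str, float] = {
    c: _synonymous_fraction(c) for c in CODON_AA if c not in STOP_CODONS
}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) difference counts between two
    codons over all minimal mutational pathways, excluding pathways through
    stop codons. Returns None if every pathway is blocked by a stop."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = 0.0
    non_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = 0
        non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_AA[cur] == CODON_AA[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_tot += syn
            non_tot += non
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_tot / n_paths, non_tot / n_paths


@dataclass
class CodonAlignment:
    """Two gap-aligned in-frame CDS strings (gaps in whole-codon triplets)."""

    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.seq2):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq1) % 3:
            raise ValueError("alignment length not a multiple of 3")

    def codon_pairs(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq1), 3):
            yield self.seq1[i : i + 3], self.seq2[i : i + 3]


@dataclass
class RateEstimate:
    pair_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # nan when saturated
    dN: float
    omega: float  # nan when dS == 0 or saturated
    flags: set[str] = field(default_factory=set)

    @property
    def codons_compared(self) -> float:
        return (self.S + self.N) / 3.0


def _jc_correct(p: float) -> float:
    """Jukes-Cantor correction; nan when p >= 3/4 (saturated)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(alignment: CodonAlignment, pair_id: str = "") -> RateEstimate:
    """NG86 pairwise rate estimate on a codon alignment.

    Codon columns containing gaps, ambiguous bases, or stop codons are
    skipped. Raises ValueError when no synonymous sites remain.
    """
    S = N = Sd = Nd = 0.0
    for c1, c2 in alignment.codon_pairs():
        if "-" in c1 or "-" in c2:
            continue
        if any(b not in NUCS for b in c1 + c2):
            continue  # N or other ambiguity
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        path = _pathway_counts(c1, c2)
        if path is None:
            continue
        s1 = SYN_SITES[c1]
        s2 = SYN_SITES[c2]
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        Sd += path[0]
        Nd += path[1]
    if S <= 0:
        raise ValueError("no synonymous sites in alignment")
    pS = Sd / S
    pN = Nd / N
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    flags: set[str] = set()
    if math.isnan(dS) or math.isnan(dN):
        flags.add("saturated")
    if not math.isnan(dS) and dS == 0.0:
        flags.add("ds_zero")
    omega = float("nan")
    if "saturated" not in flags and dS > 0:
        omega = dN / dS
    return RateEstimate(pair_id, S, N, Sd, Nd, pS, pN, dS, dN, omega, flags)


# ---------------------------------------------------------------------------
# protein alignment and back-translation


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def align_proteins(p1: str, p2: str) -> tuple[str, str, float]:
    """Global Needleman-Wunsch alignment (BLOSUM62, gap open 10, extend 0.5).

    Returns the two gapped strings and the alignment score; of score-tied
    optima, the first alignment in the aligner's deterministic enumeration
    order is returned.
    """
    if not p1 or not p2:
        raise ValueError("empty protein sequence")
    alignments = _ALIGNER.align(p1.upper(), p2.upper())
    best = alignments[0]
    a1, a2 = str(best[0]), str(best[1])
    return a1, a2, float(best.score)


def backtranslate(
    aligned_p1: str, aligned_p2: str, cds1: str, cds2: str
) -> CodonAlignment:
    """Expand a gapped protein alignment to a codon alignment (PAL2NAL-style).

    Each CDS must translate (standard code, trailing stop allowed and
    trimmed) to its degapped protein; otherwise the pair is rejected.
    """

    def codons_for(prot_gapped: str, cds: str) -> list[str]:
        prot = prot_gapped.replace("-", "")
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError("CDS length not a multiple of 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        if len(codons) != len(prot):
            raise ValueError("CDS/protein length mismatch")
        for cod, aa in zip(codons, prot):
            trans = CODON_AA.get(cod, "X") if all(b in NUCS for b in cod) else "X"
            if aa != "X" and trans != "X" and trans != aa:
                raise ValueError(f"CDS codon {cod} does not encode {aa}")
        return codons

    cod1 = codons_for(aligned_p1, cds1)
    cod2 = codons_for(aligned_p2, cds2)
    out1: list[str] = []
    out2: list[str] = []
    i1 = i2 = 0
    for a, b in zip(aligned_p1, aligned_p2):
        if a == "-":
            out1.append("---")
        else:
            out1.append(cod1[i1])
            i1 += 1
        if b == "-":
            out2.append("---")
        else:
            out2.append(cod2[i2])
            i2 += 1
    return CodonAlignment("".join(out1), "".join(out2))


def pair_rates(cds1: str, cds2: str, pair_id: str = "") -> RateEstimate:
    """Protein-guided codon alignment followed by NG86 for one CDS pair."""
    p1 = translate_cds(cds1)
    p2 = translate_cds(cds2)
    a1, a2, _ = align_proteins(p1, p2)
    return ng86(backtranslate(a1, a2, cds1, cds2), pair_id=pair_id)


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (standard code); trailing stop trimmed,
    ambiguous codons -> X."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        cod = cds[i : i + 3]
        if any(b not in NUCS for b in cod):
            aas.append("X")
            continue
        aa = CODON_AA[cod]
        if aa == "*":
            if i == len(cds) - 3:
                break
            raise ValueError(f"internal stop codon at nt {i}")
        aas.append(aa)
    return "".join(aas)


def filter_rates(
    estimates: Sequence[RateEstimate],
    ds_outlier_mult: float = 2.0,
    ds_zero_eps: float = 1e-4,
) -> tuple[list[RateEstimate], list[tuple[str, str]]]:
    """Apply the divergence quality filters in one pass.

    Excludes (a) pairs with dS above ``ds_outlier_mult`` times the mean dS of
    the incoming set (suspect alignments), (b) pairs whose dS is effectively
    zero while dN > 0 (spurious, inflated omega), and (c) saturated
    estimates. Returns (kept, [(pair_id, reason), ...]).
    """
    if not estimates:
        raise ValueError("empty estimate list")
    finite_ds = [e.dS for e in estimates if not math.isnan(e.dS)]
    mean_ds = float(np.mean(finite_ds)) if finite_ds else float("nan")
    kept: list[RateEstimate] = []
    excluded: list[tuple[str, str]] = []
    for e in estimates:
        if "saturated" in e.flags:
            excluded.append((e.pair_id, "saturated"))
            continue
        if e.dS < ds_zero_eps and e.dN > 0:
            e.flags.add("ds_zero")
            excluded.append((e.pair_id, "ds_zero"))
            continue
        if not math.isnan(mean_ds) and e.dS > ds_outlier_mult * mean_ds:
            e.flags.add("ds_outlier")
            excluded.append((e.pair_id, "ds_outlier"))
            continue
        kept.append(e)
    return kept, excluded
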