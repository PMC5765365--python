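"""Independent brute-force oracles used by the test suite.

Everything here is written naively and separately from the package
implementations: explicit loops, full enumeration, no shared helpers.
"""

from __future__ import annotations

import itertools
import math
from math import comb

BASES = "ACGT"

_CODON_TABLE = {}


def _build_codon_table():
    # independent table built from the standard-code amino acid string,
    # NCBI transl_table=1, TTT first ordering
    aa = (
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    )
    order = "TCAG"
    i = 0
    for b1 in order:
        for b2 in order:
            for b3 in order:
                _CODON_TABLE[b1 + b2 + b3] = aa[i]
                i += 1


_build_codon_table()


def codon_aa(codon: str) -> str:
    return _CODON_TABLE[codon]


def ng86_oracle(seq1: str, seq2: str):
    """Naive NG86: explicit per-position site counting and full pathway
    enumeration. Returns (S, N, Sd, Nd, pS, pN, dS, dN)."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if "-" in c1 + c2 or any(b not in BASES for b in c1 + c2):
            continue
        if codon_aa(c1) == "*" or codon_aa(c2) == "*":
            continue
        # site counts: fraction of the 3 possible changes per position that
        # are synonymous (changes to stops are nonsynonymous)
        s_pair = []
        for c in (c1, c2):
            s = 0.0
            for pos in range(3):
                for b in BASES:
                    if b == c[pos]:
                        continue
                    mut = c[:pos] + b + c[pos + 1 :]
                    if codon_aa(mut) == codon_aa(c):
                        s += 1.0 / 3.0
            s_pair.append(s)
        # pathways
        diffs = [p for p in range(3) if c1[p] != c2[p]]
        syn_paths, non_paths, n_ok = 0.0, 0.0, 0
        for order in itertools.permutations(diffs):
            cur = c1
            sd = nd = 0
            blocked = False
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if codon_aa(nxt) == "*":
                    blocked = True
                    break
                if codon_aa(nxt) == codon_aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if not blocked:
                syn_paths += sd
                non_paths += nd
                n_ok += 1
        if diffs and n_ok == 0:
            continue  # all pathways pass through stops: codon skipped
        S += (s_pair[0] + s_pair[1]) / 2.0
        N += 3.0 - (s_pair[0] + s_pair[1]) / 2.0
        if diffs:
            Sd += syn_paths / n_ok
            Nd += non_paths / n_ok
    pS = Sd / S
    pN = Nd / N

    def jc(p):
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    return S, N, Sd, Nd, pS, pN, jc(pS), jc(pN)


def align_score_oracle(p1: str, p2: str, matrix, gap_open=10.0, gap_extend=0.5):
    """Exhaustive global alignment score with affine gaps, for tiny inputs.

    Enumerates every alignment as a monotone path of (match, insert, delete)
    moves and scores gap runs as -(open + (len-1)*extend).
    """
    best = [-math.inf]

    def rec(i, j, score, prev):
        if i == len(p1) and j == len(p2):
            best[0] = max(best[0], score)
            return
        if i < len(p1) and j < len(p2):
            rec(i + 1, j + 1, score + matrix[p1[i], p2[j]], "m")
        if i < len(p1):
            pen = gap_extend if prev == "d" else gap_open
            rec(i + 1, j, score - pen, "d")
        if j < len(p2):
            pen = gap_extend if prev == "i" else gap_open
            rec(i, j + 1, score - pen, "i")

    rec(0, 0, 0.0, "m")
    return best[0]


def bh_oracle(pvals, alpha=0.05):
    """Brute-force BH step-up: rejects the k smallest p where k is the
    largest index with p(k) <= k*alpha/m; q-values by the direct definition
    q(i) = min over j>=i of m*p(j)/j on the sorted scale."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * alpha / m:
            k = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        reject[idx] = rank <= k
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * pvals[idx] / rank)
        q[idx] = running
    return q, reject


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def window_pi_oracle(records, n_haplotypes, contig_lengths, window=500):
    """All-pairs haplotype-difference windowed diversity.

    ``records`` as produced by foamrates.simulate.simulate_variants:
    (contig, pos, ref, alt, ["0/1", ...]).
    """
    pi = {}
    for contig, length in contig_lengths.items():
        nwin = (length + window - 1) // window
        for w in range(nwin):
            pi[(contig, w)] = 0.0
    pairs_total = n_haplotypes * (n_haplotypes - 1) // 2
    for contig, pos, ref, alt, gts in records:
        haps = []
        for gt in gts:
            haps.extend(int(x) for x in gt.replace("|", "/").split("/"))
        diff = 0
        for i in range(len(haps)):
            for j in range(i + 1, len(haps)):
                if haps[i] != haps[j]:
                    diff += 1
        pi[(contig, (pos - 1) // window)] += diff / pairs_total
    return {k: v / window for k, v in pi.items()}


def six_frame_orfs_oracle(seq, min_codons=30):
    """All stop-terminated ORFs >= min_codons over 6 frames, as
    (protein, frame). Runs reaching the sequence end without a stop are not
    complete ORFs."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(seq))
    out = []
    for frame, s in [(1, seq), (2, seq[1:]), (3, seq[2:]), (-1, rc), (-2, rc[1:]), (-3, rc[2:])]:
        codons = [s[i : i + 3] for i in range(0, len(s) - 2, 3)]
        run = []
        for c in codons:
            is_stop = all(b in BASES for b in c) and codon_aa(c) == "*"
            if is_stop:
                if len(run) >= min_codons:
                    prot = "".join(
                        codon_aa(x) if all(b in BASES for b in x) else "X" for x in run
                    )
                    out.append((prot, frame))
                run = []
            else:
                run.append(c)
    return out
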