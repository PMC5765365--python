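# Methods

This note describes what each stage computes and the conventions chosen
where a method admits variants. All estimators are tested against
independent brute-force oracles in `tests/` (see `tests/oracles.py`).

## Pairwise divergence (dN/dS)

**Codon alignment.** Coding sequences are translated (a single trailing stop
codon is trimmed; internal stops are rejected), the proteins are aligned
globally with BLOSUM62 (gap open 10, extend 0.5, Needleman–Wunsch), and the
protein alignment is back-translated onto the original codons, so gaps only
ever appear in whole-codon units.

**NG86 estimator.** For each aligned codon the number of synonymous sites is
the per-position fraction of the three possible single-base changes that
preserve the amino acid (denominator 3 per position; changes to stop codons
count as nonsynonymous); a codon therefore contributes S ∈ [0, 3] synonymous
and 3 − S nonsynonymous sites, and a pair contributes the average of its two
codons' counts. Observed synonymous/nonsynonymous differences at multi-hit
codons are averaged over all orderings of the single-base steps, excluding
orderings that pass through a stop codon (a codon pair whose every pathway
passes through a stop is skipped entirely). Columns containing a gap or an
ambiguous base are skipped. Proportions pS = Sd/S and pN = Nd/N are corrected
for multiple hits with the Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3);
p ≥ 3/4 is reported as saturated (d undefined). ω = dN/dS; it is undefined
when dS = 0 or the pair is saturated. The implementation agrees with an
independent pathway-enumeration oracle to 1e−10 and with Biopython's NG86 to
1e−9 on random alignments.

**dS quality filters.** Applied to a batch of estimates: (i) saturated pairs;
(ii) dS greater than twice the batch mean dS, with the mean computed once on
the unfiltered batch (a single pass, so the threshold does not ratchet);
(iii) dS below 1e−4 with dN > 0, which produces unstable, effectively
infinite ω.

## Expression

**Filtering.** Genes are kept when CPM ≥ 1 (raw library sizes) in at least 6
samples, boundaries inclusive.

**Normalization.** Trimmed mean of M-values: reference sample is the one
whose upper-quartile CPM is closest to the mean upper-quartile; M (log2
proportion ratio) is trimmed 30% each side, A (mean log2 abundance) 5% each
side; the remaining M are averaged with inverse asymptotic-variance weights;
factors are rescaled to geometric mean 1. TMM assumes DE is mostly balanced
between directions; strongly one-directional DE leaves a small residual bias
that no trimmed-mean method removes.

**Differential expression.** Per-gene negative-binomial GLMs with a log link
and log(library size × TMM factor) offsets. Dispersions are method-of-moments
(Pearson) estimates with fitted group means, shrunk halfway toward a binned
mean–dispersion trend. Each contrast is a likelihood-ratio test of a
two-group mean model against a single-mean model, referred to χ²(1); BH
q-values are computed per contrast. This is a deliberate simplification of
Cox–Reid adjusted-profile-likelihood machinery; its null calibration
(type-I ≈ 5–6% at p < 0.05) and power (sensitivity ≥ 0.995, empirical FDR
≈ 0.05–0.08 at q < 0.05 on planted |log2FC| = 2, φ = 0.1, 6 vs 6) are
verified on synthetic truth. Genes with all-zero counts in a contrast get
p = 1 and log2FC = 0.

**Groupings.** Scheme A labels tissue-enriched genes (the enrichment lists
are an input) Induced when significantly up in the breeding condition of
their tissue (FG: LD vs SD *or* SD+T vs SD; testis: LD vs SD) at
log2FC > 1 and q < 0.05, strict inequalities; genes up in the breeding
condition of both tissues are removed entirely. Scheme B assigns each gene
its least-inclusive designation: FP > FG_Enriched > FG_Expressed > Other.

## Foam proteins

A protein is confidently detected with ≥ 2 distinct peptide sequences at
confidence ≥ 0.99 (inclusive). The high-confidence foam-protein set is the
intersection of detected proteins with genes significantly up in **both** FG
breeding contrasts.

## Orthology and gene ages

**RBH.** From two directional 12-column similarity-hit tables, each query's
best subject is the highest bitscore (ties broken by lower e-value, then
lexicographic subject id) among hits with e-value ≤ 1e−6; (q, s) is an
ortholog pair iff each is the other's best hit. The output is one-to-one and
symmetric.

**Orthogroups.** A graph over (taxon, gene) nodes contains an edge for every
between-taxa RBH pair, plus within-taxon edges whose bitscore exceeds the
gene's best between-taxa bitscore (recent paralogs). Orthogroups are
connected components. Each focal-taxon gene is dated by the highest-ranked
origin class among taxa in its group, on the fixed order Aves < Vertebrate <
Animal < Eukaryote < Bacteria+Archaea (so a group containing only the focal
species, chicken and mouse is dated Vertebrate).

**ORFs.** `translate_longest_orf` searches all six reading frames for the
longest run of non-stop codons *terminated by a stop codon*; runs truncated
by the sequence end are not complete ORFs. Ties break by frame order
+1, +2, +3, −1, −2, −3.

## Polymorphism

For a biallelic SNP with allele counts (a, b) over the n haplotypes called at
that site, site diversity is π = 2ab / (n(n−1)). Windows tile each contig as
[1, 500], [501, 1000], … and window π is the sum of site π divided by the
full window length (monomorphic and uncalled positions contribute zero).
Non-biallelic records are skipped and counted. Gene π is the unweighted mean
over all windows overlapping the gene's (BED, 0-based half-open) span.
Group comparisons use sequential (Type I) two-way ANOVA of π on tissue,
induction status and their interaction, and Tukey HSD across scheme B labels.

## Group statistics

Group mean ω gets a percentile bootstrap CI (default 10,000 resamples);
coverage under a null simulation is 0.92–0.97 at the 95% level.
Non-overlap of CIs is reported as a descriptive flag, not a formal test.
Ortholog fractions are compared with all pairwise two-sided Fisher exact
tests, BH-corrected; categories not significantly different share a letter
in a compact-letter display built by insert-and-absorb (start from one group
holding every label, split groups containing a significant pair, drop
subset groups). A 2×2 table with a zero margin is reported as p = 1 with a
flag.

## Synthetic study generator

Every gene is assigned one of eight classes (foam protein, FG-induced,
FG-not-induced, testis-induced, testis-not-induced, induced-in-both,
FG-expressed, other) by largest-remainder exact counts. The class determines
expression (which tissues, induced or flat at log2FC = 2), foam-protein
membership, ortholog presence probability, planted ω, gene-age distribution
and θ. Counts are negative-binomial (φ = 0.1) over a 30-sample design (FG in
LD/SD/SD+T, testis in LD/SD, 6 males each; testes regress under SD+T and are
not sampled). The codon-pair simulator defines ω operationally the same way
NG86 measures it: uniform per-site proposals, synonymous changes accepted
always, nonsynonymous with probability min(1, ω), stop-creating proposals
rejected, run until the accepted synonymous count reaches target_dS × S₀.
Variants segregate per site with probability θ·aₙ with derived-allele counts
from the neutral 1/i spectrum, which makes expected per-site π equal θ.
All randomness derives from one integer seed via spawned generator streams;
identical configs give byte-identical output files.
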