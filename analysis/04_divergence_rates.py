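#!/usr/bin/env python
"""Stage 4: reciprocal-best-hit ortholog pairs, protein-guided codon
alignment, NG86 pairwise dN/dS and the dS quality filters. Writes
ortholog_pairs.tsv, rates.tsv, rate_exclusions.tsv, chrom_by_gene.tsv."""

import argparse
from pathlib import Path

from foamrates.pipeline import stage_rates


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    rates = stage_rates(args.results / "inputs", args.results / "analysis")
    print(f"{len(rates)} rate estimates kept")
    print(rates[["dS", "dN", "omega"]].describe().to_string())


if __name__ == "__main__":
    main()
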