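#!/usr/bin/env python
"""Stage 6: nucleotide diversity in fixed windows from the VCF and mean pi
per gene span. Writes pi_windows.tsv and gene_pi.tsv."""

import argparse
from pathlib import Path

from foamrates.pipeline import stage_pi


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--window", type=int, default=500)
    args = ap.parse_args()

    gene_pi = stage_pi(
        args.results / "inputs", args.results / "analysis", window=args.window
    )
    print(f"mean gene pi = {gene_pi['pi'].mean():.6f} over {len(gene_pi)} genes")


if __name__ == "__main__":
    main()
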