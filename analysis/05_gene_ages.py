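#!/usr/bin/env python
"""Stage 5: cluster genes across taxa into orthogroups and date each focal
gene by the most distantly related taxon in its group
(Aves < Vertebrate < Animal < Eukaryote < Bacteria+Archaea).
Writes origins.tsv."""

import argparse
from pathlib import Path

from foamrates.pipeline import stage_ages


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    origins = stage_ages(args.results / "inputs", args.results / "analysis")
    print(origins["origin"].value_counts().to_string())


if __name__ == "__main__":
    main()
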