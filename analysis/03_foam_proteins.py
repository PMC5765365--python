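#!/usr/bin/env python
"""Stage 3: call high-confidence foam proteins (>=2 distinct peptides at
confidence >=0.99, intersected with genes up in both foam-gland breeding
contrasts) and build the least-inclusive grouping (scheme B). Needs stage 2
outputs. Writes fp_called.txt, categories_scheme_b.tsv, categories.tsv."""

import argparse
from pathlib import Path

from foamrates.pipeline import stage_proteome


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--lfc-min", type=float, default=1.0)
    ap.add_argument("--q-max", type=float, default=0.05)
    args = ap.parse_args()

    scheme_b = stage_proteome(
        args.results / "inputs", args.results / "analysis",
        lfc_min=args.lfc_min, q_max=args.q_max,
    )
    print(scheme_b["label"].value_counts().to_string())


if __name__ == "__main__":
    main()
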