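#!/usr/bin/env python
"""Stage 2: CPM filter, TMM normalization, the three treatment contrasts
(FG LD vs SD, FG SD+T vs SD, testis LD vs SD) and the tissue-by-induction
grouping (scheme A). Writes de_results.tsv and categories_scheme_a.tsv."""

import argparse
from pathlib import Path

from foamrates.pipeline import stage_expression


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--lfc-min", type=float, default=1.0)
    ap.add_argument("--q-max", type=float, default=0.05)
    args = ap.parse_args()

    scheme_a = stage_expression(
        args.results / "inputs", args.results / "analysis",
        lfc_min=args.lfc_min, q_max=args.q_max,
    )
    print(scheme_a["label"].value_counts().to_string())


if __name__ == "__main__":
    main()
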