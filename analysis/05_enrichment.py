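#!/usr/bin/env python
"""Annotation-set enrichment of the aggregation fractions.

Chi-square membership tests of each annotation set in the increased and
baseline fractions against the NIA background; the planted set should be
strongly enriched among increased proteins.
"""

import argparse
from pathlib import Path

import pandas as pd

from aggregome.enrichment import enrichment_report
from aggregome.fractions import FractionLabels
from aggregome.io import read_gene_sets


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data/planted"))
    parser.add_argument("--fractions", type=Path, default=Path("results/fractions_planted.tsv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    labels = FractionLabels(labels=pd.read_csv(args.fractions, sep="\t", index_col=0)["label"])
    sets = read_gene_sets(args.datadir / "annotations.gmt")
    report = enrichment_report(
        {name: labels.ids(name) for name in ("increased", "baseline") if labels.ids(name)},
        {name: sets.members(name) for name in sets},
        labels.ids("nia"),
    )
    out = args.outdir / "enrichment_planted.tsv"
    report.to_csv(out, sep="\t", index=False)
    for row in report.itertuples(index=False):
        print(
            f"{row.fraction} x {row.set}: {row.a}/{row.a + row.b} in set vs "
            f"{row.c}/{row.c + row.d} of background, OR {row.odds_ratio:.2f}, "
            f"chi2 {row.statistic:.1f}, p {row.p:.3g}"
        )
    print(f"  -> {out}")


if __name__ == "__main__":
    main()
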