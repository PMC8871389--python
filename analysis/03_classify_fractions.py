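#!/usr/bin/env python
"""Partition the planted proteome into aggregation fractions.

Assigns increased / decreased / baseline / other_aggregate / NIA labels
from the differential results plus WCL detection, and reports the pairwise
overlaps between the truth-defined and call-defined protein sets.
"""

import argparse
from pathlib import Path

import pandas as pd

from aggregome.fractions import classify_fractions, overlap_report
from aggregome.io import FRACTION_WCL, filter_contaminants_reverse, read_protein_groups, read_sample_design


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data/planted"))
    parser.add_argument("--differential", type=Path, default=Path("results/differential_planted.tsv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    design = read_sample_design(args.datadir / "design.tsv")
    table = filter_contaminants_reverse(
        read_protein_groups(args.datadir / "proteinGroups.tsv", design)
    )
    results = pd.read_csv(args.differential, sep="\t", index_col=0)
    wcl_cols = design.labels_for(fraction=FRACTION_WCL)
    wcl_ids = frozenset(table.intensities.index[table.intensities[wcl_cols].notna().any(axis=1)])

    labels = classify_fractions(results, wcl_ids)
    out = args.outdir / "fractions_planted.tsv"
    labels.labels.to_frame().to_csv(out, sep="\t")
    print("fraction sizes:", labels.counts())

    truth = pd.read_csv(args.datadir / "truth.tsv", sep="\t", index_col=0)
    gainers = set(truth.index[truth.aggregates_treated & ~truth.aggregates_control])
    baseline_true = set(truth.index[truth.aggregates_control])
    report = overlap_report(
        {
            "called_increased": labels.ids("increased"),
            "true_gainers": gainers,
            "called_baseline": labels.ids("baseline"),
            "true_constitutive": baseline_true,
        }
    )
    report_path = args.outdir / "fraction_overlaps.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    inc_vs_truth = report[(report.set_a == "called_increased") & (report.set_b == "true_gainers")]
    print(
        "called increased vs true gainers: "
        f"{int(inc_vs_truth.intersection.iloc[0])} shared of {int(inc_vs_truth.size_a.iloc[0])} called"
    )
    print(f"  -> {out}, {report_path}")


if __name__ == "__main__":
    main()
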