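"""Summarize the measured cohort by SEUROP fatness score.

Per score group: n, mean ± se of carcass weight, cutting fat, mean gray
level and fat area, with one-way ANOVA p-values and Tukey HSD compact
letters; plus the group-size-weighted overall means.  Writes
results/group_summary.csv and prints the table.
"""

import argparse
from pathlib import Path

import pandas as pd

from fatgrade import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", type=Path, default=Path("scratch/analysis/run"))
    ap.add_argument("--out", type=Path, default=Path("results/group_summary.csv"))
    args = ap.parse_args()

    cohort = pd.read_csv(args.run / "cohort.csv")
    meas = pd.read_csv(args.run / "measurements.csv")
    table = cohort.merge(meas[["animal_id", "mean_gray", "fat_area_pct"]], on="animal_id")

    summary, anova = pipeline.summarize_by_score(table)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(args.out, index=False, float_format="%.4f")

    counts = summary.attrs["group_sizes"]
    print("group summary (mean ± se; letters: Tukey HSD at alpha = 0.05)")
    header = "variable".ljust(22) + "".join(f"{s} (n={counts[s]})".rjust(16) for s in sorted(counts))
    print(header + "overall".rjust(14) + "p".rjust(10))
    for var in pipeline.SUMMARY_VARIABLES:
        mean = summary.query("variable == @var and statistic == 'mean'").iloc[0]
        se = summary.query("variable == @var and statistic == 'se'").iloc[0]
        res = anova.get(var)
        cells = ""
        for s in sorted(counts):
            letter = res.letters[s] if res and res.letters else ""
            cells += f"{mean[s]:8.1f}±{se[s]:4.1f} {letter:2s}"
        p = f"{res.p_value:.3f}" if res else "--"
        print(var.ljust(22) + cells + f"{mean['overall']:10.1f}±{se['overall']:3.1f}" + p.rjust(10))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
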