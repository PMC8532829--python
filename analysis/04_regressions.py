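"""Fit the cutting-fat prediction models and compare their accuracy.

Three simple regressions of cutting fat (%) on: the visual SEUROP score, the
carcass mean gray level, and the image-analysis carcass fat area; plus three
stepwise multiple regressions over {mean gray, carcass weight, fat area}
with interactions and (optionally) log/square transforms.  Writes
results/models.csv and a scatter plot of the fat-area model.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fatgrade import pipeline, stats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", type=Path, default=Path("scratch/analysis/run"))
    ap.add_argument("--out", type=Path, default=Path("results/models.csv"))
    ap.add_argument("--plot", type=Path, default=Path("results/fat_area_regression.png"))
    args = ap.parse_args()

    cohort = pd.read_csv(args.run / "cohort.csv")
    meas = pd.read_csv(args.run / "measurements.csv")
    table = cohort.merge(meas[["animal_id", "mean_gray", "fat_area_pct"]], on="animal_id")

    models = pipeline.fit_variants(table)
    rows = [m.summary_row(name) for name, m in models.items()]
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False, float_format="%.6f")

    print("cutting-fat prediction models (synthetic cohort):")
    for name, m in models.items():
        terms = " + ".join(m.terms) if m.terms else "(intercept only)"
        print(f"  {name:22s} R^2 = {m.r2:.2f}  RMSE = {m.rmse:.2f} %   [{terms}]")
    best = max(models, key=lambda k: models[k].r2)
    print(f"most accurate: {best} (R^2 = {models[best].r2:.2f})")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fit = models["fat_area"]
        x = table["fat_area_pct"]
        xs = np.linspace(x.min(), x.max(), 50)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(x, table["cutting_fat_pct"], s=18, c="k")
        ax.plot(xs, fit.intercept + fit.coef[1] * xs, "r-")
        ax.set_xlabel("carcass fat area (%)")
        ax.set_ylabel("cutting fat (%)")
        ax.set_title(f"R² = {fit.r2:.2f}, RMSE = {fit.rmse:.2f} %")
        fig.tight_layout()
        fig.savefig(args.plot, dpi=120)
        print(f"wrote {args.out} and {args.plot}")
    except ImportError:
        print(f"wrote {args.out} (matplotlib unavailable, no plot)")


if __name__ == "__main__":
    main()
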