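#!/usr/bin/env python
"""Cohort figures: Poincaré scatter of the first 10 CLs, group box plots
of the headline features, and the 3-D feature scatter."""

from pathlib import Path

import pandas as pd

from vtcycle.episodes import read_cohort
from vtcycle.plots import feature_boxplots, feature_scatter_3d, poincare_plot

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv", strict=False)
    ft = pd.read_csv(OUT / "features.csv")
    poincare_plot(cohort, OUT / "poincare.png")
    feature_boxplots(ft, OUT / "boxplots.png")
    feature_scatter_3d(ft, OUT / "scatter3d.png")
    print(f"wrote poincare.png, boxplots.png, scatter3d.png under {OUT}")


if __name__ == "__main__":
    main()
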