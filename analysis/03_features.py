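#!/usr/bin/env python
"""Extract the per-episode feature table (first-10-CL variability metrics,
AR(1) stability terms, whole-episode descriptors) from the cohort CSV."""

from pathlib import Path

from vtcycle.episodes import read_cohort
from vtcycle.features import features_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv", strict=False)
    ft = features_table(cohort)
    ft.to_csv(OUT / "features.csv", index=False)
    g = ft.groupby("label")[["sd_cl10", "ar_phi", "tinn10", "episode_sd", "mean_cl10"]].mean()
    print("group means of the headline features:")
    print(g.round(3).to_string())
    print(f"wrote {OUT / 'features.csv'} ({len(ft)} rows)")


if __name__ == "__main__":
    main()
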