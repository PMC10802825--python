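#!/usr/bin/env python
"""Compare every feature between outcome groups (normality-gated t-test /
Mann-Whitney U) and write the two-group descriptor report."""

from pathlib import Path

import pandas as pd

from vtcycle.groupstats import compare_groups, comparison_frame, write_report

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ft = pd.read_csv(OUT / "features.csv")
    rows = compare_groups(ft)
    write_report(rows, OUT / "compare.md")
    comparison_frame(rows).to_csv(OUT / "compare.csv", index=False)
    sig = [r for r in sorted(rows, key=lambda r: r.p_value) if r.p_value < 0.05]
    print(f"{len(sig)} of {len(rows)} features differ at P < 0.05; most significant:")
    for r in sig[:6]:
        print(f"  {r.feature:24s} {r.test_used:12s} P = {r.p_value:.2g}")
    print(f"wrote {OUT / 'compare.md'} and compare.csv")


if __name__ == "__main__":
    main()
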