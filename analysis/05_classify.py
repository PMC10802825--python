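#!/usr/bin/env python
"""Cross-validate the feature-selected random forest that predicts
spontaneous VT termination from the first 10 cycle lengths."""

import json
from pathlib import Path

import pandas as pd

from vtcycle.classify import ClassifierConfig, cross_validate

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    ft = pd.read_csv(OUT / "features.csv")
    res = cross_validate(ft, ClassifierConfig(seed=SEED))
    (OUT / "metrics.json").write_text(json.dumps(res.to_dict(), indent=2, sort_keys=True))
    lo, hi = res.accuracy_ci95
    print(f"10-fold CV, positive class = spontaneous termination (seed {SEED}):")
    print(f"  accuracy    {res.accuracy:.3f} (95% CI {lo:.3f}-{hi:.3f})")
    print(f"  sensitivity {res.sensitivity:.3f}  specificity {res.specificity:.3f}")
    print(f"  PPV         {res.ppv:.3f}  NPV         {res.npv:.3f}")
    print(f"  AUROC       {res.auroc:.3f}")
    print(f"  majority-selected features: {', '.join(res.selected_features)}")
    print(f"wrote {OUT / 'metrics.json'}")


if __name__ == "__main__":
    main()
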