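"""Terminating-vs-sustained comparison of episode features.

Each numeric feature is compared between the two outcome groups with
Student's t-test when both groups look Gaussian (Shapiro-Wilk at
alpha = 0.05 per group) and the Mann-Whitney U test otherwise; rows are
summarised as mean +/- SD or median (IQR) accordingly.  P-values are
two-sided and, by default, uncorrected (one row per feature, mirroring
per-feature clinical reporting); Benjamini-Hochberg adjustment is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

T_TEST = "t_test"
MANN_WHITNEY = "mann_whitney"

#: feature-table columns that are identifiers, not features
NON_FEATURE_COLUMNS = ("episode_id", "patient_id", "label")


@dataclass(frozen=True)
class ComparisonRow:
    feature: str
    summary_terminating: str
    summary_sustained: str
    test_used: str
    p_value: float
    p_adjusted: float | None = None


def _normalish(values: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk gate; degenerate (constant) samples are not normal."""
    if np.ptp(values) == 0:
        return False
    return sps.shapiro(values).pvalue > alpha


def choose_test(values_a, values_b, alpha_norm: float = 0.05) -> str:
    """t-test if both groups pass Shapiro-Wilk at ``alpha_norm``, else Mann-Whitney."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group to choose a test")
    if _normalish(a, alpha_norm) and _normalish(b, alpha_norm):
        return T_TEST
    return MANN_WHITNEY


def _mean_sd(v: np.ndarray) -> str:
    return f"{np.mean(v):.1f} ± {np.std(v, ddof=1):.1f}"


def _median_iqr(v: np.ndarray) -> str:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}–{q3:.1f})"


def _p_value(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # identical constant groups: no evidence of difference
    if test == T_TEST:
        return float(sps.ttest_ind(a, b).pvalue)
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def compare_groups(
    features: pd.DataFrame,
    alpha_norm: float = 0.05,
    adjust: bool = False,
) -> list[ComparisonRow]:
    """One comparison row per numeric feature column.

    ``features`` is the table from :func:`vtcycle.features.features_table`
    (a ``label`` column with both ``terminating`` and ``sustained``
    present is required).  With ``adjust=True`` Benjamini-Hochberg
    adjusted p-values are attached.
    """
    if "label" not in features.columns:
        raise ValueError("feature table must carry a 'label' column")
    term = features[features["label"] == "terminating"]
    sust = features[features["label"] == "sustained"]
    if len(term) == 0 or len(sust) == 0:
        raise ValueError("both terminating and sustained episodes are required")

    rows: list[ComparisonRow] = []
    for col in features.columns:
        if col in NON_FEATURE_COLUMNS:
            continue
        if not pd.api.types.is_numeric_dtype(features[col]):
            continue
        a = term[col].to_numpy(dtype=float)
        b = sust[col].to_numpy(dtype=float)
        test = choose_test(a, b, alpha_norm)
        p = _p_value(a, b, test)
        if test == T_TEST:
            sa, sb = _mean_sd(a), _mean_sd(b)
        else:
            sa, sb = _median_iqr(a), _median_iqr(b)
        rows.append(ComparisonRow(col, sa, sb, test, p))

    if adjust:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        rows = [
            ComparisonRow(r.feature, r.summary_terminating, r.summary_sustained,
                          r.test_used, r.p_value, float(adj[i]))
            for i, r in enumerate(rows)
        ]
    return rows


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in rows])
    if df["p_adjusted"].isna().all():
        df = df.drop(columns=["p_adjusted"])
    return df


def write_report(rows: list[ComparisonRow], path) -> None:
    """Markdown report mirroring a clinical two-group descriptor table."""
    lines = [
        "# Terminating vs. sustained VT episode descriptors",
        "",
        "| Feature | Spontaneously terminating | Sustained | Test | P-value |",
        "| --- | --- | --- | --- | --- |",
    ]
    for r in rows:
        test = "t-test" if r.test_used == T_TEST else "Mann–Whitney U"
        p = f"{r.p_value:.3g}"
        lines.append(
            f"| {r.feature} | {r.summary_terminating} | {r.summary_sustained} "
            f"| {test} | {p} |"
        )
    lines.append("")
    lines.append(
        "Parametric rows are mean ± SD (Student's t-test); "
        "non-parametric rows are median (IQR) (Mann–Whitney U)."
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
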