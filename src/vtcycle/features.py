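"""Per-episode cycle-length variability and morphology features.

Unless noted otherwise the variability features are computed on the
first 10 CLs of the episode (CL1, the PVC-coupled interval, included):
roughly the 3.4 s an ICD has available before a therapy decision.  The
whole-episode descriptors (duration, beat count, overall SD, minimum,
initiation-to-shortest dynamics) use the full series.

Conventions:

- all standard deviations use the sample (n-1) denominator;
- pNN50 uses the n-1 successive differences as denominator;
- Poincaré SD1/SD2 are the sample SDs of the rotated coordinates
  ``(x_{i+1} -/+ x_i)/sqrt(2)``, which are always defined, rather than
  the ``sd2^2 = 2 sdnn^2 - sd1^2`` identity that can go negative on
  10-beat windows;
- TINN is the base width of the least-squares triangle fitted to the
  histogram of the window at the conventional 1/128 s = 7.8125 ms bin
  width (configurable; see :func:`tinn`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
import pandas as pd

from vtcycle.ar import DegenerateFitError, fit_ar1
from vtcycle.episodes import Cohort, Episode, episode_duration_s

logger = logging.getLogger(__name__)

DEFAULT_TINN_BIN_MS = 7.8125  # 1/128 s, the conventional HRV histogram bin
NN_THRESHOLD_MS = 50.0


@dataclass(frozen=True)
class FeatureVector:
    """All per-episode features, one row of the feature table.

    Fields ending in ``10`` are computed on the first 10 CLs; the rest
    describe the whole episode.
    """

    episode_id: str
    mean_cl10: float
    sd_cl10: float
    rmssd10: float
    nn50_10: int
    pnn50_10: float
    tinn10: float
    sd1_10: float
    sd2_10: float
    ar_phi: float
    ar_const: float
    ar_resid_sd: float
    first_cl: float
    min_cl: float
    min_cl10: float
    cl10th: float
    episode_sd: float
    episode_duration_s: float
    n_beats: int
    time_to_min_s: float
    pct_beats_to_min: float
    pct_change_first_to_min: float


FEATURE_FIELDS = [f.name for f in dataclass_fields(FeatureVector)]


def first_segment(e: Episode, n: int = 10) -> np.ndarray:
    """The first ``n`` cycle lengths in order, starting at CL1."""
    if n < 1:
        raise ValueError("window length n must be >= 1")
    if e.n_beats < n:
        raise ValueError(
            f"episode {e.episode_id!r} has {e.n_beats} CLs; first_segment needs >= {n}"
        )
    return e.cl_ms[:n].copy()


def basic_stats(window) -> dict:
    """Mean, sample SD and minimum of a CL window."""
    x = np.asarray(window, dtype=float)
    if len(x) < 2:
        raise ValueError("basic_stats needs at least 2 values (sample SD undefined)")
    return {"mean": float(x.mean()), "sd": float(x.std(ddof=1)), "min": float(x.min())}


def successive_diff_metrics(window, threshold: float = NN_THRESHOLD_MS) -> dict:
    """RMSSD, NN50 and pNN50 of the successive CL differences.

    ``d_i = x_{i+1} - x_i``; ``rmssd = sqrt(mean(d_i^2))``;
    ``nn50 = #{|d_i| > threshold}``; ``pnn50 = 100 * nn50 / (n-1)``.
    """
    x = np.asarray(window, dtype=float)
    if len(x) < 2:
        raise ValueError("successive differences need at least 2 values")
    d = np.diff(x)
    nn50 = int(np.sum(np.abs(d) > threshold))
    return {
        "rmssd": float(np.sqrt(np.mean(d**2))),
        "nn50": nn50,
        "pnn50": 100.0 * nn50 / len(d),
    }


def tinn(window, bin_width: float = DEFAULT_TINN_BIN_MS) -> float:
    """Triangular interpolation of the CL histogram (TINN), in ms.

    A histogram D of the window is built over bins of width
    ``bin_width`` aligned to 0.  With X the centre of the modal bin
    (ties broken toward the lowest bin), a triangle that is zero outside
    ``[N, M]`` and peaks at ``(X, D(X))`` is fitted by brute-force
    search of N and M over the bin-centre grid extended one bin beyond
    the histogram support, minimising the summed squared error between
    D (zero outside its support) and the triangle evaluated at the bin
    centres.  Returns the base width ``M - N``.

    When every value falls in a single bin the triangle degenerates and
    one ``bin_width`` is returned.  Note that with only 10 samples the
    histogram is sparse and the fitted base typically spans most of the
    sample range, so short-window TINN values are considerably larger
    than densely-sampled ones at equal spread.
    """
    x = np.asarray(window, dtype=float)
    if len(x) < 2:
        raise ValueError("tinn needs at least 2 values")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    lo = int(np.floor(x.min() / bin_width))
    hi = int(np.floor(x.max() / bin_width))
    nbins = hi - lo + 1
    if nbins == 1:
        return float(bin_width)
    counts = np.zeros(nbins)
    np.add.at(counts, (np.floor(x / bin_width)).astype(int) - lo, 1.0)
    centers = (lo + np.arange(nbins) + 0.5) * bin_width

    k = int(np.argmax(counts))  # lowest bin wins ties
    X, DX = centers[k], counts[k]

    # candidate feet: bin-centre grid extended one bin on each side
    cand = (lo - 1 + np.arange(nbins + 2) + 0.5) * bin_width
    left_cand = cand[cand < X - 1e-12]
    right_cand = cand[cand > X + 1e-12]

    best_err, best_base = np.inf, float(bin_width)
    for N in left_cand:
        for M in right_cand:
            err = 0.0
            # histogram bins, D compared with the triangle (0 outside [N, M])
            for b, d in zip(centers, counts):
                if N <= b <= X:
                    t = DX * (b - N) / (X - N)
                elif X < b <= M:
                    t = DX * (M - b) / (M - X)
                else:
                    t = 0.0
                err += (d - t) ** 2
            # triangle bins outside the histogram support, where D = 0
            for b in cand:
                if (N <= b <= M) and (b < centers[0] - 1e-12 or b > centers[-1] + 1e-12):
                    if b <= X:
                        t = DX * (b - N) / (X - N)
                    else:
                        t = DX * (M - b) / (M - X)
                    err += t**2
            if err < best_err - 1e-12:
                best_err, best_base = err, float(M - N)
    return best_base


def poincare(window) -> dict:
    """Poincaré SD1/SD2 of the lag-1 scatter, rotated-coordinate form.

    Over the pairs ``(x_i, x_{i+1})``: SD1 is the sample SD of
    ``(x_{i+1} - x_i)/sqrt(2)`` (dispersion perpendicular to the line
    of identity), SD2 the sample SD of ``(x_{i+1} + x_i)/sqrt(2)``
    (dispersion along it).
    """
    x = np.asarray(window, dtype=float)
    if len(x) < 3:
        raise ValueError("poincare needs at least 3 values (>= 2 lag pairs)")
    d = (x[1:] - x[:-1]) / np.sqrt(2.0)
    s = (x[1:] + x[:-1]) / np.sqrt(2.0)
    return {"sd1": float(np.std(d, ddof=1)), "sd2": float(np.std(s, ddof=1))}


def initiation_to_shortest(e: Episode) -> dict:
    """Dynamics of the deceleration from initiation to the shortest CL.

    ``idx`` is the first occurrence of the minimum CL.  Time-to-minimum
    sums the CLs through that beat inclusive (the time at which the
    shortest beat completes); percentage of beats counts it too;
    the percentage change is relative to CL1 and is always >= 0.
    """
    x = e.cl_ms
    idx = int(np.argmin(x))  # first occurrence
    return {
        "time_to_min_s": float(np.sum(x[: idx + 1])) / 1000.0,
        "pct_beats_to_min": 100.0 * (idx + 1) / len(x),
        "pct_change_first_to_min": 100.0 * (x[0] - x[idx]) / x[0],
    }


def episode_sd(e: Episode) -> float:
    """Sample SD of the full CL series: CL variability within the episode."""
    if e.n_beats < 2:
        raise ValueError("episode_sd needs at least 2 beats")
    return float(np.std(e.cl_ms, ddof=1))


def extract_features(
    e: Episode, tinn_bin_width: float = DEFAULT_TINN_BIN_MS
) -> FeatureVector:
    """Compute the full feature vector for one analysis-eligible episode.

    Raises :class:`vtcycle.ar.DegenerateFitError` when the first-10
    window is constant (the AR(1) slope is undefined); cohort-level
    callers drop such episodes with a logged reason.
    """
    e.validate()
    win = first_segment(e, 10)
    stats = basic_stats(win)
    diffs = successive_diff_metrics(win)
    pc = poincare(win)
    ar = fit_ar1(win)
    init = initiation_to_shortest(e)
    return FeatureVector(
        episode_id=e.episode_id,
        mean_cl10=stats["mean"],
        sd_cl10=stats["sd"],
        rmssd10=diffs["rmssd"],
        nn50_10=diffs["nn50"],
        pnn50_10=diffs["pnn50"],
        tinn10=tinn(win, tinn_bin_width),
        sd1_10=pc["sd1"],
        sd2_10=pc["sd2"],
        ar_phi=ar.phi,
        ar_const=ar.c,
        ar_resid_sd=ar.resid_sd,
        first_cl=float(e.cl_ms[0]),
        min_cl=float(e.cl_ms.min()),
        min_cl10=stats["min"],
        cl10th=float(e.cl_ms[9]),
        episode_sd=episode_sd(e),
        episode_duration_s=episode_duration_s(e),
        n_beats=e.n_beats,
        time_to_min_s=init["time_to_min_s"],
        pct_beats_to_min=init["pct_beats_to_min"],
        pct_change_first_to_min=init["pct_change_first_to_min"],
    )


def features_table(
    cohort: Cohort, tinn_bin_width: float = DEFAULT_TINN_BIN_MS
) -> pd.DataFrame:
    """Feature table: one row per episode, FeatureVector columns plus
    ``patient_id`` and ``label`` for downstream grouping.

    Episodes with a degenerate (constant-window) AR fit are excluded
    with a logged reason.
    """
    rows = []
    for e in cohort:
        try:
            fv = extract_features(e, tinn_bin_width=tinn_bin_width)
        except DegenerateFitError as err:
            logger.warning("excluding episode %r: %s", e.episode_id, err)
            continue
        row = {f: getattr(fv, f) for f in FEATURE_FIELDS}
        row["patient_id"] = e.patient_id
        row["label"] = e.label
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_FIELDS + ["patient_id", "label"])
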