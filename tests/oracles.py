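"""Independent straight-line re-implementations used as test oracles.

Deliberately written with plain loops / stdlib statistics, sharing no
code with the package, so agreement is evidence and not tautology.
"""

import math
import statistics


def oracle_basic(window):
    n = len(window)
    mean = sum(window) / n
    sd = statistics.stdev(window)
    return mean, sd, min(window)


def oracle_successive(window, threshold=50.0):
    diffs = [window[i + 1] - window[i] for i in range(len(window) - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    nn = sum(1 for d in diffs if abs(d) > threshold)
    return rmssd, nn, 100.0 * nn / len(diffs)


def oracle_poincare(window):
    d = [(window[i + 1] - window[i]) / math.sqrt(2) for i in range(len(window) - 1)]
    s = [(window[i + 1] + window[i]) / math.sqrt(2) for i in range(len(window) - 1)]
    return statistics.stdev(d), statistics.stdev(s)


def oracle_ar1(window):
    lag = window[:-1]
    lead = window[1:]
    m = len(lag)
    mx = sum(lag) / m
    my = sum(lead) / m
    sxx = sum((x - mx) ** 2 for x in lag)
    sxy = sum((x - mx) * (y - my) for x, y in zip(lag, lead))
    phi = sxy / sxx
    c = my - phi * mx
    ssr = sum((y - (c + phi * x)) ** 2 for x, y in zip(lag, lead))
    resid_sd = math.sqrt(ssr / (m - 2)) if m > 2 else float("nan")
    return phi, c, resid_sd


def oracle_initiation(cl):
    mn = min(cl)
    idx = cl.index(mn) if isinstance(cl, list) else int(list(cl).index(mn))
    time_s = sum(cl[: idx + 1]) / 1000.0
    return time_s, 100.0 * (idx + 1) / len(cl), 100.0 * (cl[0] - mn) / cl[0]


def oracle_tinn(window, w=7.8125):
    """Same definition as the package (modal-peak triangle, least squares,
    feet on the bin-centre grid extended one bin), recomputed independently."""
    lo = math.floor(min(window) / w)
    hi = math.floor(max(window) / w)
    nbins = hi - lo + 1
    if nbins == 1:
        return w
    counts = [0.0] * nbins
    for v in window:
        counts[math.floor(v / w) - lo] += 1.0
    centers = [(lo + i + 0.5) * w for i in range(nbins)]
    peak = counts.index(max(counts))
    X, DX = centers[peak], counts[peak]
    grid = [(lo - 1 + i + 0.5) * w for i in range(nbins + 2)]

    def tri(b, N, M):
        if N <= b <= X:
            return DX * (b - N) / (X - N)
        if X < b <= M:
            return DX * (M - b) / (M - X)
        return 0.0

    best = (float("inf"), w)
    for N in grid:
        if N >= X:
            continue
        for M in grid:
            if M <= X:
                continue
            err = sum((c - tri(b, N, M)) ** 2 for b, c in zip(centers, counts))
            for b in grid:
                if N <= b <= M and not (centers[0] - 1e-12 <= b <= centers[-1] + 1e-12):
                    err += tri(b, N, M) ** 2
            if err < best[0] - 1e-12:
                best = (err, M - N)
    return best[1]
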