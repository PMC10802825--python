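import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_episode, random_windows
from oracles import (
    oracle_basic,
    oracle_initiation,
    oracle_poincare,
    oracle_successive,
    oracle_tinn,
)
from vtcycle.features import (
    FEATURE_FIELDS,
    basic_stats,
    episode_sd,
    extract_features,
    features_table,
    first_segment,
    initiation_to_shortest,
    poincare,
    successive_diff_metrics,
    tinn,
)


class TestWorkedExample:
    """Hand-derived values on the PVC-initiation example window."""

    def test_basic_stats(self, fig1_window):
        s = basic_stats(fig1_window)
        assert s["mean"] == pytest.approx(370.25)
        assert s["sd"] == pytest.approx(6.8980, abs=1e-4)
        assert s["min"] == 360

    def test_successive_diffs(self, fig1_window):
        d = successive_diff_metrics(fig1_window)
        assert d["rmssd"] == pytest.approx(math.sqrt(398 / 3), abs=1e-9)
        assert d["nn50"] == 0 and d["pnn50"] == 0

    def test_poincare(self, fig1_window):
        pc = poincare(fig1_window)
        assert pc["sd1"] == pytest.approx(math.sqrt(99.5), abs=1e-9)
        # hand value: sample SD of (748, 735, 733)/sqrt(2)
        assert pc["sd2"] == pytest.approx(5.7591, abs=1e-3)

    def test_initiation_to_shortest(self, fig1_window):
        e = make_episode(fig1_window)
        out = initiation_to_shortest(e)
        assert out["time_to_min_s"] == pytest.approx(1.108)
        assert out["pct_beats_to_min"] == pytest.approx(75.0)
        assert out["pct_change_first_to_min"] == pytest.approx(100 * 13 / 373, abs=1e-3)


def test_first_segment_contract(eleven_beat_episode, fig1_window):
    seg = first_segment(eleven_beat_episode, 10)
    assert np.array_equal(seg, eleven_beat_episode.cl_ms[:10])
    e4 = make_episode(fig1_window)
    assert np.array_equal(first_segment(e4, 4), fig1_window)
    with pytest.raises(ValueError):
        first_segment(e4, 10)
    with pytest.raises(ValueError):
        first_segment(e4, 0)


@pytest.mark.parametrize(
    "func,min_len",
    [(basic_stats, 2), (successive_diff_metrics, 2), (tinn, 2), (poincare, 3)],
)
def test_short_windows_rejected(func, min_len):
    with pytest.raises(ValueError):
        func([300.0] * (min_len - 1))


def test_constant_window_degenerate_values():
    const = [300.0] * 10
    assert basic_stats(const)["sd"] == 0
    d = successive_diff_metrics(const)
    assert (d["rmssd"], d["nn50"], d["pnn50"]) == (0, 0, 0)
    pc = poincare(const)
    assert pc["sd1"] == 0 and pc["sd2"] == 0
    assert tinn(const) == pytest.approx(7.8125)  # single-bin degenerate


def test_symmetric_alternation():
    d = successive_diff_metrics([300.0, 360.0, 300.0])
    assert d["nn50"] == 2 and d["pnn50"] == 100 and d["rmssd"] == 60
    alt = [300.0, 400.0] * 5
    pc = poincare(alt)
    # perpendicular spread ~ |±100|/sqrt(2); along-identity spread ~ 0
    assert pc["sd1"] == pytest.approx(np.std(np.array([100.0, -100.0] * 4 + [100.0]) / np.sqrt(2), ddof=1))
    assert pc["sd2"] == pytest.approx(0, abs=1e-9)


def test_tinn_recovers_exact_triangle():
    # histogram counts 1,2,3,2,1 on adjacent bins -> perfect triangle whose
    # feet sit one bin beyond the outer occupied bins: base = 6 bins
    w = 7.8125
    centers = [(40 + k + 0.5) * w for k in range(5)]
    window = (
        [centers[0]] + [centers[1]] * 2 + [centers[2]] * 3 + [centers[3]] * 2 + [centers[4]]
    )
    assert tinn(window, w) == pytest.approx(6 * w)
    assert oracle_tinn(window, w) == pytest.approx(6 * w)


def test_tinn_bounds_on_random_windows():
    rng = np.random.default_rng(11)
    w = 7.8125
    for win in random_windows(200, rng, min_len=5, max_len=10):
        t = tinn(win, w)
        assert t >= w
        assert t <= (win.max() - win.min()) + 3 * w  # feet extend <= 1 bin past support


def test_episode_sd_matches_window_sd_when_series_is_window(fig1_window):
    e = make_episode(fig1_window)
    assert episode_sd(e) == pytest.approx(basic_stats(fig1_window)["sd"])
    assert episode_sd(make_episode([300.0] * 12)) == 0


def test_monotone_decreasing_min_at_last_beat():
    cl = list(np.linspace(380, 300, 12))
    out = initiation_to_shortest(make_episode(cl))
    assert out["pct_beats_to_min"] == 100.0
    assert out["time_to_min_s"] == pytest.approx(sum(cl) / 1000)


def test_min_at_first_beat():
    cl = [300.0] + list(np.linspace(320, 360, 11))
    out = initiation_to_shortest(make_episode(cl))
    assert out["time_to_min_s"] == pytest.approx(0.3)
    assert out["pct_change_first_to_min"] == 0.0


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(150, 900), min_size=3, max_size=12), st.randoms(use_true_random=False))
def test_basic_stats_permutation_invariant(values, rnd):
    perm = list(values)
    rnd.shuffle(perm)
    a, b = basic_stats(values), basic_stats(perm)
    assert a["mean"] == pytest.approx(b["mean"])
    assert a["sd"] == pytest.approx(b["sd"], abs=1e-9)
    assert a["min"] == b["min"]


def test_oracle_equivalence_random_windows():
    """Every formula agrees with an independent re-implementation to 1e-9."""
    rng = np.random.default_rng(1234)
    for win in random_windows(300, rng):
        w = list(map(float, win))
        s = basic_stats(w)
        om, osd, omin = oracle_basic(w)
        assert s["mean"] == pytest.approx(om, abs=1e-9)
        assert s["sd"] == pytest.approx(osd, abs=1e-9)
        d = successive_diff_metrics(w)
        orm, onn, opn = oracle_successive(w)
        assert d["rmssd"] == pytest.approx(orm, abs=1e-9)
        assert d["nn50"] == onn and d["pnn50"] == pytest.approx(opn, abs=1e-9)
        if len(w) >= 3:
            pc = poincare(w)
            osd1, osd2 = oracle_poincare(w)
            assert pc["sd1"] == pytest.approx(osd1, abs=1e-9)
            assert pc["sd2"] == pytest.approx(osd2, abs=1e-9)
        e = make_episode(w)
        init = initiation_to_shortest(e)
        ot, ob, oc = oracle_initiation(w)
        assert init["time_to_min_s"] == pytest.approx(ot, abs=1e-9)
        assert init["pct_beats_to_min"] == pytest.approx(ob, abs=1e-9)
        assert init["pct_change_first_to_min"] == pytest.approx(oc, abs=1e-9)


def test_extract_features_deterministic_and_finite(eleven_beat_episode):
    fv1 = extract_features(eleven_beat_episode)
    fv2 = extract_features(eleven_beat_episode)
    assert fv1 == fv2
    vals = dataclasses.asdict(fv1)
    for name in FEATURE_FIELDS:
        if name == "episode_id":
            continue
        assert np.isfinite(vals[name]), name
    assert fv1.cl10th == eleven_beat_episode.cl_ms[9]
    assert fv1.min_cl <= eleven_beat_episode.cl_ms.min()
    assert 0 < fv1.pct_beats_to_min <= 100
    assert fv1.pct_change_first_to_min >= 0
    assert fv1.nn50_10 <= 9


def test_features_invariant_to_relabeling(eleven_beat_episode):
    import copy

    other = copy.deepcopy(eleven_beat_episode)
    other.label = "sustained"
    other.episode_id = "X99"
    a = dataclasses.asdict(extract_features(eleven_beat_episode))
    b = dataclasses.asdict(extract_features(other))
    a.pop("episode_id"), b.pop("episode_id")
    assert a == b


def test_features_table_excludes_degenerate_ar(two_episode_cohort, caplog):
    from vtcycle.episodes import Cohort

    flat = make_episode([300.0] * 15, "FLAT", "P03", "sustained")
    cohort = Cohort(two_episode_cohort.episodes + [flat], "t")
    with caplog.at_level("WARNING"):
        ft = features_table(cohort)
    assert set(ft["episode_id"]) == {"A1", "A2"}
    assert "FLAT" in caplog.text
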