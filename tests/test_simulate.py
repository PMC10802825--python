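import numpy as np
import pytest
from dataclasses import replace

from vtcycle.ar import fit_ar1_batch
from vtcycle.simulate import (
    CalibrationError,
    CohortSpec,
    calibrate_innovation_scale,
    default_params,
    generate_cohort,
    generate_episode,
    simulate_windows,
)


def noise_free(params, drop=0.0):
    return replace(params, drop_pct_mean=drop, drop_pct_sd=0.0, phi_sd=0.0,
                   first_cl_sd=0.0, eps_sd_log_mean=-np.inf, eps_sd_log_sd=0.0)


def test_default_params_carry_published_statistics():
    p = default_params()
    assert p["terminating"].first_cl_mean == 357.9
    assert p["sustained"].first_cl_mean == 329.8
    assert p["terminating"].n_beats_mean == 16 and p["terminating"].n_beats_sd == 5
    assert p["sustained"].n_beats_mean == 36 and p["sustained"].n_beats_sd == 14
    assert p["terminating"].drop_pct_mean == 11.0
    assert p["sustained"].drop_pct_mean == 6.0
    for gp in p.values():
        assert gp.provenance  # every default documents its source


def test_noise_free_flat_episode_is_constant():
    p = noise_free(default_params()["terminating"])
    e = generate_episode(p, np.random.default_rng(0))
    assert np.allclose(e.cl_ms, 357.9)


def test_noise_free_decelerating_trend_monotone_to_plateau():
    p = replace(noise_free(default_params()["terminating"], drop=10.0), tau_s=0.2)
    e = generate_episode(p, np.random.default_rng(0))
    diffs = np.diff(e.cl_ms)
    assert np.all(diffs <= 1e-9)  # non-increasing approach to plateau
    assert np.argmin(e.cl_ms) == e.n_beats - 1
    assert e.cl_ms[-1] == pytest.approx(357.9 * 0.9, rel=1e-3)


def test_generate_episode_reproducible():
    p = default_params()["sustained"]
    e1 = generate_episode(p, np.random.default_rng(123))
    e2 = generate_episode(p, np.random.default_rng(123))
    assert np.array_equal(e1.cl_ms, e2.cl_ms)


def test_generate_cohort_counts_and_validity():
    cohort = generate_cohort(CohortSpec(seed=5))
    assert len(cohort) == 69
    labels = cohort.labels()
    assert labels.count("terminating") == 36
    assert labels.count("sustained") == 33
    cohort.validate()  # lengths >= 11, positive CLs, unique ids
    assert all(e.n_beats >= 11 for e in cohort)
    assert "seed=5" in cohort.provenance


def test_patient_structure_default_and_single():
    cohort = generate_cohort(CohortSpec(seed=1))
    term_pat = {e.patient_id for e in cohort if e.label == "terminating"}
    sust_pat = {e.patient_id for e in cohort if e.label == "sustained"}
    assert len(term_pat | sust_pat) == 27
    assert len(term_pat) == 19 and len(sust_pat) == 12
    assert len(term_pat & sust_pat) == 4  # patients contributing both outcomes

    single = generate_cohort(CohortSpec(seed=1, n_patients=1))
    assert {e.patient_id for e in single} == {"P01"}


def test_seeds_differ_counts_match():
    a = generate_cohort(CohortSpec(seed=1))
    b = generate_cohort(CohortSpec(seed=2))
    assert len(a) == len(b) == 69
    assert not np.array_equal(a.episodes[0].cl_ms, b.episodes[0].cl_ms)


def test_monotone_response_of_sd10_to_innovation_scale():
    base = default_params()["sustained"]
    means = []
    for log_mean in (1.0, 1.7, 2.4):
        p = replace(base, eps_sd_log_mean=log_mean)
        w = simulate_windows(p, 4000, np.random.default_rng(3))
        means.append(w.std(axis=1, ddof=1).mean())
    assert means[0] < means[1] < means[2]


def test_calibration_white_noise_identity():
    """phi target 0 on a flat trend: compensated phi ~ +0.1 (Kendall) and
    innovation SD ~ the target window SD."""
    base = replace(default_params()["sustained"], drop_pct_mean=0.0, drop_pct_sd=0.0,
                   phi_sd=0.0, eps_sd_log_sd=0.0)
    p, report = calibrate_innovation_scale(base, target_sd10=15.0, target_phi_hat=0.0,
                                           reps=20_000, seed=4)
    # Kendall's first-order bias -(1+3 phi)/10 predicts ~+0.13 compensation;
    # the exact Monte Carlo root at n=10 sits slightly higher, near +0.15
    assert 0.08 <= p.phi_mean <= 0.22
    assert np.exp(p.eps_sd_log_mean) == pytest.approx(15.0, rel=0.08)
    assert report["iterations"] <= 50


def test_calibration_deterministic_for_fixed_seed():
    base = default_params()["terminating"]
    p1, r1 = calibrate_innovation_scale(base, 20.1, 0.39, reps=5000, seed=11)
    p2, r2 = calibrate_innovation_scale(base, 20.1, 0.39, reps=5000, seed=11)
    assert p1.phi_mean == p2.phi_mean
    assert p1.eps_sd_log_mean == p2.eps_sd_log_mean
    assert r1 == r2


def test_calibration_impossible_target_raises():
    # an absurdly small SD target under a strong fixed trend cannot be met
    base = replace(default_params()["terminating"], drop_pct_mean=30.0, drop_pct_sd=15.0)
    with pytest.raises(CalibrationError):
        calibrate_innovation_scale(base, target_sd10=1.0, target_phi_hat=0.39,
                                   reps=2000, seed=0)


def test_calibration_closes_loop_on_defaults():
    """Shipped defaults reproduce their own calibration targets."""
    p = default_params()
    for label, (sd_t, phi_t) in {"terminating": (20.1, 0.39),
                                 "sustained": (11.5, 0.14)}.items():
        w = simulate_windows(p[label], 20_000, np.random.default_rng(21))
        assert w.std(axis=1, ddof=1).mean() == pytest.approx(sd_t, abs=0.5)
        assert np.nanmean(fit_ar1_batch(w)) == pytest.approx(phi_t, abs=0.03)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        CohortSpec(n_terminating=0)
    bad = replace(default_params()["terminating"], tau_s=-1.0)
    with pytest.raises(ValueError):
        generate_episode(bad, np.random.default_rng(0))
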