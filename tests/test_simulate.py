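"""Generative model: mixture sampling, lognormal RTs, contamination."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

import cuewheel as cw
from cuewheel.simulate import (
    GenerativeParams,
    default_params,
    sample_colour_response,
    sample_rt,
    simulate_subject,
)
from cuewheel._angles import angular_error


def vm_mass_within(kappa, half_width_rad):
    """Quadrature oracle: von Mises(0, kappa) mass in +-half_width."""
    f = lambda x: np.exp(kappa * np.cos(x)) / (2 * np.pi * special.i0(kappa))
    val, _ = integrate.quad(f, -half_width_rad, half_width_rad)
    return val


def test_degenerate_concentration_reproduces_target(rng):
    resp = sample_colour_response(np.full(200, 123.0), rho=1.0, kappa=1e6, rng=rng)
    err = angular_error(123.0, resp)
    assert np.max(np.abs(err)) < 0.5


def test_pure_guessing_is_uniform(rng):
    target = rng.uniform(0, 360, 50_000)
    resp = sample_colour_response(target, rho=0.0, kappa=9.08, rng=rng)
    err = angular_error(target, resp)
    # goodness of fit against the closed-form uniform CDF on [-180, 180)
    p = stats.kstest(err, stats.uniform(loc=-180, scale=360).cdf).pvalue
    assert p > 0.01


def test_mixture_mass_within_30_degrees_matches_quadrature(rng):
    n = 50_000
    rho, kappa = 0.5, 9.08
    target = rng.uniform(0, 360, n)
    resp = sample_colour_response(target, rho, kappa, rng)
    err = angular_error(target, resp)
    frac = np.mean(np.abs(err) <= 30.0)
    expected = rho * vm_mass_within(kappa, np.deg2rad(30)) + (1 - rho) * (60 / 360)
    mc_sd = np.sqrt(expected * (1 - expected) / n)
    assert abs(frac - expected) < 4 * mc_sd


def test_mixture_histogram_matches_density(rng):
    """chi-square of 1e5 simulated errors against rho*VM + (1-rho)*U."""
    n = 100_000
    rho, kappa = 0.7, 5.0
    target = np.zeros(n)
    err = np.deg2rad(angular_error(target, sample_colour_response(target, rho, kappa, rng)))
    edges = np.linspace(-np.pi, np.pi, 37)
    obs, _ = np.histogram(err, bins=edges)
    # bin masses by direct quadrature of the mixture density
    f = lambda x: rho * np.exp(kappa * np.cos(x)) / (2 * np.pi * special.i0(kappa)) + (1 - rho) / (2 * np.pi)
    probs = np.array([integrate.quad(f, lo, hi)[0] for lo, hi in zip(edges[:-1], edges[1:])])
    p = stats.chisquare(obs, n * probs / probs.sum()).pvalue
    assert p > 0.001


def test_circular_shift_invariance(rng):
    target = rng.uniform(0, 360, 2000)
    r1 = sample_colour_response(target, 0.5, 8.0, np.random.default_rng(9))
    r2 = sample_colour_response((target + 90) % 360, 0.5, 8.0, np.random.default_rng(9))
    np.testing.assert_allclose(
        angular_error(target, r1), angular_error((target + 90) % 360, r2), atol=1e-9
    )


def test_invalid_mixture_parameters_rejected(rng):
    with pytest.raises(ValueError):
        sample_colour_response(0.0, rho=1.2, kappa=1.0, rng=rng)
    with pytest.raises(ValueError):
        sample_colour_response(0.0, rho=0.5, kappa=-1.0, rng=rng)


class TestSampleRT:
    def test_zero_noise_is_exact(self, rng):
        p = default_params("E1")
        p = cw.simulate.replace(p, rt_log_sd_within=0.0,
                                rt_log_mean=float(np.log(360.0)),
                                rt_effects={"neutral": 0.0})
        assert sample_rt("neutral", p, 0.0, rng) == pytest.approx(360.0)

    def test_median_is_exp_location(self, rng):
        p = default_params("E1")
        draws = sample_rt("valid", p, 0.0, rng, size=100_000)
        loc = p.rt_log_mean + p.rt_effects["valid"]
        med = np.median(draws)
        # MC error of the lognormal sample median
        se = np.exp(loc) * p.rt_log_sd_within * 1.2533 / np.sqrt(100_000)
        assert abs(med - np.exp(loc)) < 4 * se

    def test_effect_shifts_median_by_exp_ratio(self, rng):
        p = default_params("E1")
        p = cw.simulate.replace(p, rt_effects={"a": 0.0, "b": -0.06})
        ra = sample_rt("a", p, 0.0, rng, size=100_000)
        rb = sample_rt("b", p, 0.0, rng, size=100_000)
        assert np.median(rb) / np.median(ra) == pytest.approx(np.exp(-0.06), rel=5e-3)

    def test_unknown_condition(self, rng):
        with pytest.raises(KeyError):
            sample_rt("nope", default_params("E1"), 0.0, rng)


class TestSimulateSubject:
    def test_zero_contamination_all_hits(self, rng):
        sched = cw.build_session("E1", 1, practice=False, seed=0)
        p = cw.simulate.replace(default_params("E1"), miss_rate=0.0,
                                false_alarm_rate=0.0, pre_target_rate=0.0)
        out = simulate_subject(sched, p, rng)
        tgt = out[out.target_present]
        assert (tgt.outcome == "hit").all()
        assert (out.loc[~out.target_present, "outcome"] == "correct_rejection").all()

    def test_outcome_domains(self, small_e1_dataset):
        df = small_e1_dataset.trials
        assert set(df.loc[df.target_present, "outcome"]) <= {"hit", "miss", "pre_target"}
        assert set(df.loc[~df.target_present, "outcome"]) <= {"false_alarm", "correct_rejection"}

    def test_pre_target_rt_in_minus_soa_zero(self, rng):
        sched = cw.build_session("E1", 2, practice=False, seed=1)
        p = cw.simulate.replace(default_params("E1"), pre_target_rate=0.5)
        out = simulate_subject(sched, p, rng)
        pre = out[out.outcome == "pre_target"]
        assert len(pre) > 0
        assert ((pre.rt_ms >= -pre.soa_ms) & (pre.rt_ms < 0)).all()

    def test_determinism(self):
        d1 = cw.simulate_experiment(3, "E2", seed=77, n_blocks=1)
        d2 = cw.simulate_experiment(3, "E2", seed=77, n_blocks=1)
        pd.testing.assert_frame_equal(d1.trials, d2.trials)

    def test_miss_fraction_binomial(self):
        """Pooled miss rate across many target trials near the set rate."""
        ds = cw.simulate_experiment(25, "E1", seed=5, n_blocks=2, practice=False)
        tgt = ds.trials[ds.trials.target_present]
        n = len(tgt)
        rate = ds.truth.miss_rate
        sd = np.sqrt(rate * (1 - rate) / n)
        assert abs((tgt.outcome == "miss").mean() - rate) < 4 * sd


class TestSimulateExperiment:
    def test_zero_subject_spread_shares_population(self):
        p = cw.simulate.replace(
            default_params("E1"), subject_sds={"rt": 0.0, "rho_logit": 0.0, "log_kappa": 0.0}
        )
        ds = cw.simulate_experiment(3, "E1", params=p, seed=2, n_blocks=1)
        assert np.allclose(ds.subject_offsets[["rt", "rho_logit", "log_kappa"]].to_numpy(), 0.0)

    def test_cohort_row_counts(self):
        ds = cw.simulate_experiment(2, "E1", seed=1, n_blocks=7, practice=True)
        assert len(ds.trials) == 2 * (420 + 30)
        ds2 = cw.simulate_experiment(2, "E2", seed=1, n_blocks=8, practice=True)
        assert len(ds2.trials) == 2 * (480 + 30)

    def test_true_effects_match_defaults(self):
        te = default_params("E1").true_effects()
        assert te["rt_ms valid - invalid"] == pytest.approx(-21.70, abs=1e-9)
        assert te["rho valid - invalid"] == pytest.approx(0.008, abs=1e-12)
        assert te["kappa valid - invalid"] == pytest.approx(0.45, abs=1e-12)
        te2 = default_params("E2").true_effects()
        assert te2["rt_ms valid - invalid@800"] == pytest.approx(34.94, abs=1e-9)
        assert te2["kappa neutral - spatial@100"] == pytest.approx(1.26, abs=1e-3)

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            GenerativeParams(experiment="E1", rt_log_mean=5.9, miss_rate=1.5)
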