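"""Bayesian fitting machinery: dataset assembly, likelihood correctness,
diagnostics, identifiability handling, information-gain behavior."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enadecay.ddpcr import apply_no_rt_subtraction
from enadecay.errors import ConfigurationError, InvalidComparisonError, InvalidInputError
from enadecay.fit import (
    MCMCConfig,
    PriorConfig,
    build_dataset,
    compare_models_loo,
    convergence_diagnostics,
    fit_decay_model,
    prior_posterior_overlap,
    summarize_decay,
)
from enadecay.models import BiphasicParams
from enadecay.simulate import DEFAULT_DESIGN, TruthParams, generate_fixture

from conftest import FAST_MCMC, single_marker_truth


class TestBuildDataset:
    def test_well_counting_per_group(self, default_dataset):
        # 3 carboys x 9 timepoints x 2 reps per monoplex marker-component
        for g in default_dataset.monoplex_groups:
            assert len(g.W) == 54
        assert len(default_dataset.duplex_group.U) == 54
        assert default_dataset.carboys == (1, 2, 3)

    def test_no_rt_rows_rejected(self, default_bundle):
        with pytest.raises(ConfigurationError, match="No-RT"):
            build_dataset(default_bundle["monoplex"])

    def test_control_carboy_positivity_warns(self, default_bundle):
        mono, _ = apply_no_rt_subtraction(default_bundle["monoplex"])
        mono = mono.copy()
        idx = mono.index[(mono["carboy"] == 4)][0]
        mono.loc[idx, "droplets_positive"] = 3
        ds = build_dataset(mono, default_bundle["duplex"])
        assert any("control carboy" in w for w in ds.validation_warnings)

    def test_baseline_excluded_by_default_included_on_request(self, default_bundle):
        mono, _ = apply_no_rt_subtraction(default_bundle["monoplex"])
        ds_no = build_dataset(mono, None)
        ds_yes = build_dataset(mono, None, include_baseline=True)
        for g_no, g_yes in zip(ds_no.monoplex_groups, ds_yes.monoplex_groups):
            assert len(g_yes.W) == len(g_no.W) + 6  # 3 carboys x 2 reps baseline rows
            assert (g_no.t >= 0).all()
            assert (g_yes.t < 0).any()


class TestLikelihood:
    def test_pointwise_binomial_matches_direct_evaluation(self, recovery_fit):
        _, draws = recovery_fit
        g = draws.groups["Cytb_eDNA"]
        gm = g.model
        rng = np.random.default_rng(0)
        flat = g.draws.reshape(-1, g.draws.shape[-1])
        theta = flat[rng.choice(len(flat), size=5)]
        ll = gm.log_likelihood(theta, pointwise=True)
        conc = gm._concentrations(theta, gm.group.t, gm.group.carboy_idx)["Cytb_eDNA"]
        mu = conc * gm.group.factor[None, :]
        p = -np.expm1(-mu)
        direct = stats.binom.logpmf(gm.group.W[None, :], gm.group.U[None, :], p)
        np.testing.assert_allclose(ll, direct, rtol=1e-10, atol=1e-10)


class TestConvergenceDiagnostics:
    def _fake_draws(self, arrs):
        class _G:
            param_names = [f"p{i}" for i in range(arrs.shape[2])]
            draws = arrs

        class _D:
            n_chains = arrs.shape[0]
            groups = {"g": _G()}

        return _D()

    def test_identical_iid_chains_pass(self):
        rng = np.random.default_rng(1)
        d = self._fake_draws(rng.normal(size=(4, 2000, 2)))
        diag = convergence_diagnostics(d, ess_threshold=500)
        assert (diag["rhat"] < 1.005).all()
        assert diag.attrs["all_ok"]

    def test_disjoint_chain_means_fail(self):
        rng = np.random.default_rng(2)
        arrs = rng.normal(size=(4, 500, 1))
        arrs[0] += 10.0
        diag = convergence_diagnostics(self._fake_draws(arrs))
        assert (diag["rhat"] > 1.005).all()
        assert not diag.attrs["all_ok"]

    def test_single_chain_undefined(self):
        rng = np.random.default_rng(3)
        with pytest.raises(InvalidInputError, match="2 chains"):
            convergence_diagnostics(self._fake_draws(rng.normal(size=(1, 500, 1))))


class TestFitting:
    def test_posterior_recovers_generating_rates(self, recovery_fit):
        truth, draws = recovery_fit
        p = truth.components["Cytb_eDNA"]
        for pname, true_val in (("lambda1", p.lambda1), ("lambda2", p.lambda2), ("t_x", p.t_x)):
            samples = draws.shape_param("Cytb_eDNA", pname)
            lo, hi = np.quantile(samples, [0.025, 0.975])
            assert lo <= true_val <= hi, f"{pname}: [{lo:.4f}, {hi:.4f}] misses {true_val}"

    def test_fit_is_reproducible_under_fixed_seed(self):
        truth = single_marker_truth()
        bundle = generate_fixture(3, truth=truth)
        ds = build_dataset(bundle["monoplex"], None)
        cfg = MCMCConfig(n_chains=2, warmup=200, draws=200, thin=2)
        d1 = fit_decay_model(ds, "biphasic", mcmc=cfg, seed=9)
        d2 = fit_decay_model(ds, "biphasic", mcmc=cfg, seed=9)
        np.testing.assert_array_equal(
            d1.groups["Cytb_eDNA"].draws, d2.groups["Cytb_eDNA"].draws
        )

    def test_single_detection_component_reduced_to_na(self, default_dataset):
        cfg = MCMCConfig(n_chains=2, warmup=200, draws=200, thin=2)
        draws = fit_decay_model(default_dataset, "biphasic", mcmc=cfg, seed=5)
        assert "Cytb_emRNA" in draws.na_components
        summary = summarize_decay(draws).set_index(["marker", "component"])
        row = summary.loc[("Cytb", "emRNA")]
        assert row["model"] == "single_exponential"
        assert np.isnan(row["t_x_median"]) and np.isnan(row["lambda2_mean"])

    def test_transition_time_identifiability_diagnostic(self, recovery_fit):
        # lambda1 = lambda2 truth: the t_x posterior stays diffuse, close to
        # its uniform prior; with genuinely biphasic truth it concentrates.
        # (At this droplet depth even noise-level rate differences tilt t_x
        # somewhat, so the degenerate overlap is well below 1 but far above
        # the identified case.)
        truth = single_marker_truth(lambda1=0.1, lambda2=0.1, t_x=30.0)
        bundle = generate_fixture(5, truth=truth)
        ds = build_dataset(bundle["monoplex"], None)
        draws = fit_decay_model(ds, "biphasic", mcmc=FAST_MCMC, seed=5)
        overlap_degenerate = prior_posterior_overlap(draws, "Cytb_eDNA", "t_x")
        _, identified = recovery_fit
        overlap_identified = prior_posterior_overlap(identified, "Cytb_eDNA", "t_x")
        assert overlap_degenerate > 0.3
        assert overlap_degenerate > 3 * overlap_identified

    def test_quadrupled_information_shrinks_posterior(self):
        truth = single_marker_truth()
        sd = {}
        for label, reps, droplets in (("base", 2, 20_000), ("rich", 8, 80_000)):
            design = dataclasses.replace(
                DEFAULT_DESIGN, tech_reps=reps, droplets_per_well=droplets
            )
            bundle = generate_fixture(11, truth=truth, design=design)
            ds = build_dataset(bundle["monoplex"], None)
            draws = fit_decay_model(ds, "biphasic", mcmc=FAST_MCMC, seed=11)
            sd[label] = draws.shape_param("Cytb_eDNA", "lambda1").std()
        assert sd["rich"] < sd["base"]

    def test_duplex_bridge_rate_recovered_with_free_rates_near_zero(self):
        truth = TruthParams(
            components={
                "16S_eDNA": BiphasicParams(1.0, 0.165, 0.028, 33.0),
                "Dloop_eDNA": BiphasicParams(1.0, 0.166, 0.021, 36.0),
                "Bridge_eDNA": BiphasicParams(5e4, 0.190, 0.044, 28.0),
            },
            carboy_sd=0.0,
        )
        bundle = generate_fixture(13, truth=truth)
        ds = build_dataset(bundle["monoplex"], bundle["duplex"])
        cfg = MCMCConfig(n_chains=2, warmup=2000, draws=1000, thin=4)
        draws = fit_decay_model(ds, "biphasic", mcmc=cfg, seed=13)
        lam = draws.shape_param("Bridge_eDNA", "lambda1")
        lo, hi = np.quantile(lam, [0.025, 0.975])
        assert lo <= 0.190 <= hi


class TestModelComparison:
    def test_mismatched_well_sets_rejected(self):
        t = single_marker_truth()
        cfg = MCMCConfig(n_chains=2, warmup=150, draws=150, thin=2)
        b1 = generate_fixture(21, truth=t)
        b2 = generate_fixture(
            21, truth=t, design=dataclasses.replace(DEFAULT_DESIGN, tech_reps=1)
        )
        d1 = fit_decay_model(build_dataset(b1["monoplex"], None), "biphasic", mcmc=cfg, seed=1)
        d2 = fit_decay_model(build_dataset(b2["monoplex"], None), "single_exponential", mcmc=cfg, seed=1)
        with pytest.raises(InvalidComparisonError):
            compare_models_loo([("biphasic", d1), ("single_exponential", d2)])

    def test_identical_fits_have_zero_loo_difference(self):
        t = single_marker_truth()
        b = generate_fixture(22, truth=t)
        ds = build_dataset(b["monoplex"], None)
        cfg = MCMCConfig(n_chains=2, warmup=150, draws=150, thin=2)
        d = fit_decay_model(ds, "biphasic", mcmc=cfg, seed=2)
        table = compare_models_loo([("a", d), ("b", d)])
        assert table["elpd_diff"].abs().max() == pytest.approx(0.0, abs=1e-9)
        assert table["dse"].max() == pytest.approx(0.0, abs=1e-9)
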