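"""Synthetic mesocosm generator: determinism, structure, statistical fidelity."""

import dataclasses
import math

import numpy as np
import pytest

from enadecay.ddpcr import VolumeChain
from enadecay.models import BiphasicParams, biphasic_concentration
from enadecay.simulate import (
    DEFAULT_DESIGN,
    DEFAULT_TRUTH,
    ExperimentDesign,
    TruthParams,
    generate_fixture,
    simulate_droplet_counts,
    simulate_true_concentrations,
)


class TestTrueConcentrations:
    def test_zero_carboy_sd_gives_identical_trajectories(self):
        truth = dataclasses.replace(DEFAULT_TRUTH, carboy_sd=0.0)
        design = dataclasses.replace(DEFAULT_DESIGN, filtration_jitter_h=0.0)
        conc = simulate_true_concentrations(truth, design, seed=3)
        sub = conc[(conc["component_key"] == "Cytb_eDNA") & (conc["carboy"] <= 3)]
        pivot = sub.pivot(index="time_nominal_h", columns="carboy", values="concentration_true")
        assert (pivot.nunique(axis=1) == 1).all()

    def test_equal_rates_trace_single_exponential(self):
        truth = TruthParams(
            components={"Cytb_eDNA": BiphasicParams(1e6, 0.15, 0.15, 36.0)},
            carboy_sd=0.0,
        )
        design = dataclasses.replace(DEFAULT_DESIGN, filtration_jitter_h=0.0)
        conc = simulate_true_concentrations(truth, design, seed=0)
        sub = conc[(conc["carboy"] == 1) & (conc["time_nominal_h"] >= 0)]
        np.testing.assert_allclose(
            sub["concentration_true"],
            1e6 * np.exp(-0.15 * sub["time_actual_h"]),
            rtol=1e-12,
        )

    def test_default_truth_decay_ratio_closed_form(self):
        # C(48)/C(0) = exp(-0.15*36) * exp(-0.03*12) for the recovery truth
        p = BiphasicParams(1e6, 0.15, 0.03, 36.0)
        ratio = biphasic_concentration(p, 48.0) / p.c0
        assert ratio == pytest.approx(math.exp(-0.15 * 36) * math.exp(-0.03 * 12), rel=1e-12)
        assert ratio == pytest.approx(0.00315, rel=0.01)

    def test_control_carboy_is_identically_zero(self):
        conc = simulate_true_concentrations(DEFAULT_TRUTH, DEFAULT_DESIGN, seed=1)
        assert (conc.loc[conc["carboy"] == 4, "concentration_true"] == 0).all()

    def test_baseline_rows_tagged_with_negative_time(self):
        conc = simulate_true_concentrations(DEFAULT_TRUTH, DEFAULT_DESIGN, seed=1)
        base = conc[conc["is_baseline"]]
        assert (base["time_nominal_h"] == -3.0).all()
        # pre-transport concentrations exceed the chamber-start values
        for key, params in DEFAULT_TRUTH.components.items():
            sub = conc[(conc["component_key"] == key) & (conc["carboy"] == 1)]
            c_base = sub.loc[sub["is_baseline"], "concentration_true"].iloc[0]
            c_zero = sub.loc[sub["time_nominal_h"] == 0.0, "concentration_true"].iloc[0]
            assert c_base > c_zero


class TestDropletCounts:
    def test_zero_concentration_gives_zero_positives(self, default_bundle):
        mono = default_bundle["monoplex"]
        ctrl = mono[mono["carboy"] == 4]
        assert (ctrl.loc[ctrl["component"] != "NoRT", "droplets_positive"] == 0).all()
        dup = default_bundle["duplex"]
        dctrl = dup[dup["carboy"] == 4]
        assert (dctrl[["n_both", "n_a_only", "n_b_only"]].to_numpy() == 0).all()

    def test_observed_positive_fraction_matches_poisson_occupancy(self):
        truth = TruthParams(
            components={"Cytb_eDNA": BiphasicParams(3e5, 0.1, 0.02, 40.0)}, carboy_sd=0.0
        )
        design = dataclasses.replace(
            DEFAULT_DESIGN, droplets_per_well=200_000, filtration_jitter_h=0.0
        )
        conc = simulate_true_concentrations(truth, design, seed=2)
        mono, _ = simulate_droplet_counts(conc, truth, design, seed=2)
        w0 = mono[
            (mono["time_nominal_h"] == 0.0)
            & (mono["carboy"] == 1)
            & (mono["pore_size_um"] == 5.0)
        ]
        chain = VolumeChain()
        mu = 3e5 * 0.96 / chain.copies_per_litre_per_droplet_copy
        p = 1 - math.exp(-mu)
        U = design.droplets_per_well
        se = math.sqrt(p * (1 - p) / U)
        for w in w0["droplets_positive"]:
            assert abs(w / U - p) < 4 * se

    def test_linked_only_duplex_truth_has_no_single_positives(self):
        truth = TruthParams(
            components={
                "16S_eDNA": BiphasicParams(1e-6, 0.1, 0.01, 30.0),
                "Dloop_eDNA": BiphasicParams(1e-6, 0.1, 0.01, 30.0),
                "Bridge_eDNA": BiphasicParams(1e5, 0.1, 0.01, 30.0),
            },
            carboy_sd=0.0,
        )
        conc = simulate_true_concentrations(truth, DEFAULT_DESIGN, seed=4)
        _, dup = simulate_droplet_counts(conc, truth, DEFAULT_DESIGN, seed=4)
        live = dup[dup["carboy"] != 4]
        assert (live[["n_a_only", "n_b_only"]].to_numpy() == 0).all()
        assert (live.loc[live["time_nominal_h"] <= 8, "n_both"] > 0).all()


class TestFixtureBundle:
    def test_fixture_is_deterministic_per_seed(self, tmp_path):
        p1 = generate_fixture(1, tmp_path / "a")["paths"]
        p2 = generate_fixture(1, tmp_path / "b")["paths"]
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()
        p3 = generate_fixture(2, tmp_path / "c")["paths"]
        assert p1["wells"].read_bytes() != p3["wells"].read_bytes()

    def test_row_counts_match_design(self, default_bundle):
        mono, dup = default_bundle["monoplex"], default_bundle["duplex"]
        n_samples = 4 * 10 * 2  # carboys (3 + control) x (9 timepoints + baseline) x reps
        # monoplex: 3 assays + 2 No-RT controls per sample, plus 2 extra
        # screening pore sizes per carboy at the first timepoint
        assert len(mono) == n_samples * 5 + 4 * 2
        assert len(dup) == n_samples

    def test_bridge_fraction_declines_when_bridge_decays_faster(self, default_bundle):
        dup = default_bundle["duplex"]
        live = dup[(dup["carboy"] != 4) & (dup["time_nominal_h"] >= 0)]
        from enadecay.duplex import DuplexDropletRecord, estimate_linked_closed_form

        frac = {}
        for t in (0.0, 12.0):
            lam = []
            for _, r in live[live["time_nominal_h"] == t].iterrows():
                rec = DuplexDropletRecord(
                    r.sample_id, r.carboy, r.time_nominal_h, r.time_actual_h, r.tech_rep,
                    r.n_both, r.n_a_only, r.n_b_only, r.n_neither, r.droplets_total,
                )
                est = estimate_linked_closed_form(rec)
                lam.append(est.lambda_linked / max(est.lambda_a_free, 1e-12))
            frac[t] = np.mean(lam)
        assert frac[12.0] < frac[0.0]
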