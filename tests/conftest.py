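"""Shared fixtures: synthetic datasets and fitted posteriors reused across tests.

The full-experiment fit at production sampler settings is expensive, so it is
computed once per session and shared by the diagnostics, summary and clock
tests. Small single-marker datasets cover the fast unit-level fitting checks.
"""

from __future__ import annotations

import pytest

from enadecay.ddpcr import apply_no_rt_subtraction
from enadecay.fit import MCMCConfig, build_dataset, fit_decay_model
from enadecay.models import BiphasicParams
from enadecay.simulate import TruthParams, generate_fixture

#: fast sampler settings for unit-level fits (single-marker posteriors mix quickly)
FAST_MCMC = MCMCConfig(n_chains=2, warmup=600, draws=600, thin=3)


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic mesocosm (all six marker-components), seed 1."""
    return generate_fixture(1)


@pytest.fixture(scope="session")
def default_dataset(default_bundle):
    mono_adj, _ = apply_no_rt_subtraction(default_bundle["monoplex"])
    return build_dataset(mono_adj, default_bundle["duplex"])


@pytest.fixture(scope="session")
def production_fit(default_dataset):
    """Biphasic fit of the default fixture at production sampler settings
    (4 chains, 5000 warmup steps, 10,000 retained draws per chain)."""
    return fit_decay_model(default_dataset, "biphasic", mcmc=MCMCConfig.production_scale(), seed=1)


def single_marker_truth(
    c0=1.0e6, lambda1=0.15, lambda2=0.03, t_x=36.0, **kwargs
) -> TruthParams:
    return TruthParams(
        components={"Cytb_eDNA": BiphasicParams(c0, lambda1, lambda2, t_x)}, **kwargs
    )


@pytest.fixture(scope="session")
def recovery_fit():
    """Fit of a single-marker dataset generated at known biphasic truth."""
    truth = single_marker_truth()
    bundle = generate_fixture(1, truth=truth)
    ds = build_dataset(bundle["monoplex"], None)
    draws = fit_decay_model(
        ds, "biphasic", mcmc=MCMCConfig(n_chains=2, warmup=800, draws=1000, thin=3), seed=1
    )
    return truth, draws
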