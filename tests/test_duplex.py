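"""Duplex-droplet linkage: category probabilities, closed-form inversion,
subtraction heuristic, and their sampling behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enadecay.duplex import (
    DuplexDropletRecord,
    bridge_length_bounds,
    category_probabilities,
    estimate_linked_closed_form,
    expected_double_positives,
    invert_category_fractions,
)
from enadecay.errors import InvalidInputError, SaturatedAssayError


def simulate_droplets(lam_a, lam_b, lam_l, n_droplets, rng):
    """Brute-force droplet simulation: independent Poisson loads per class;
    linked molecules deposit both targets in the same droplet."""
    linked = rng.poisson(lam_l, n_droplets)
    a_pos = (rng.poisson(lam_a, n_droplets) + linked) > 0
    b_pos = (rng.poisson(lam_b, n_droplets) + linked) > 0
    return a_pos, b_pos


def record_from_counts(n_both, n_a, n_b, n_neither):
    U = n_both + n_a + n_b + n_neither
    return DuplexDropletRecord("w", 1, 0.0, 0.0, 1, n_both, n_a, n_b, n_neither, U)


class TestCategoryProbabilities:
    def test_empty_reaction(self):
        assert category_probabilities(0, 0, 0) == (0.0, 0.0, 0.0, 1.0)

    def test_fully_linked_pool(self):
        p = category_probabilities(0.0, 0.0, 0.7)
        assert p.p_a_only == p.p_b_only == 0.0
        assert p.p_both == pytest.approx(1 - math.exp(-0.7))

    def test_matches_brute_force_droplet_simulation(self):
        lam_a, lam_b, lam_l = 0.5, 0.3, 0.2
        p = category_probabilities(lam_a, lam_b, lam_l)
        assert p.p_neither == pytest.approx(math.exp(-1.0), rel=1e-12)
        rng = np.random.default_rng(11)
        n = 1_000_000
        a_pos, b_pos = simulate_droplets(lam_a, lam_b, lam_l, n, rng)
        for prob, obs in [
            (p.p_both, (a_pos & b_pos).mean()),
            (p.p_a_only, (a_pos & ~b_pos).mean()),
            (p.p_b_only, (~a_pos & b_pos).mean()),
            (p.p_neither, (~a_pos & ~b_pos).mean()),
        ]:
            se = math.sqrt(prob * (1 - prob) / n)
            assert abs(obs - prob) < 4 * se

    def test_negative_load_rejected(self):
        with pytest.raises(InvalidInputError):
            category_probabilities(-0.1, 0.0, 0.0)

    @given(
        lam=st.tuples(st.floats(0, 3), st.floats(0, 3), st.floats(0.001, 3)),
        eps=st.floats(0.01, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_linked_load_monotonicity(self, lam, eps):
        la, lb, ll = lam
        p0 = category_probabilities(la, lb, ll)
        p1 = category_probabilities(la, lb, ll + eps)
        assert p1.p_both > p0.p_both
        assert p1.p_neither < p0.p_neither


class TestClosedFormInversion:
    def test_exact_independence_gives_zero_linkage(self):
        rec = record_from_counts(n_both=2500, n_a=2500, n_b=2500, n_neither=2500)
        est = estimate_linked_closed_form(rec)
        assert est.lambda_linked == pytest.approx(0.0, abs=1e-12)

    def test_fully_linked_half_occupancy(self):
        rec = record_from_counts(n_both=5000, n_a=0, n_b=0, n_neither=5000)
        est = estimate_linked_closed_form(rec)
        assert est.lambda_linked == pytest.approx(math.log(2), rel=1e-12)
        assert est.lambda_a_free == est.lambda_b_free == 0.0

    @given(
        la=st.floats(0, 3),
        lb=st.floats(0, 3),
        ll=st.floats(0, 3),
    )
    @settings(max_examples=150, deadline=None)
    def test_inverts_exact_probabilities(self, la, lb, ll):
        # category probabilities -> negative fractions -> exact inversion
        p = category_probabilities(la, lb, ll)
        qA = p.p_b_only + p.p_neither
        qB = p.p_a_only + p.p_neither
        est_a, est_b, est_l = invert_category_fractions(qA, qB, p.p_neither)
        assert est_l == pytest.approx(ll, abs=1e-12, rel=1e-9)
        assert est_a == pytest.approx(la, abs=1e-12, rel=1e-9)
        assert est_b == pytest.approx(lb, abs=1e-12, rel=1e-9)

    def test_saturated_assay_raises(self):
        with pytest.raises(SaturatedAssayError):
            estimate_linked_closed_form(record_from_counts(10_000, 0, 0, 0))

    def test_estimator_consistency_over_wells(self):
        # mean closed-form estimate over 200 wells of 20,000 droplets is
        # within 2% of the generating linked load
        rng = np.random.default_rng(5)
        for ll in (0.01, 0.1, 0.5):
            p = category_probabilities(0.2, 0.15, ll)
            ests = []
            for _ in range(200):
                counts = rng.multinomial(20_000, list(p))
                rec = record_from_counts(*counts)
                ests.append(estimate_linked_closed_form(rec).lambda_linked)
            assert np.mean(ests) == pytest.approx(ll, rel=0.02)


class TestSubtractionHeuristic:
    def test_independence_gives_zero_excess(self):
        rec = record_from_counts(2500, 2500, 2500, 2500)
        expected, excess = expected_double_positives(rec)
        assert expected == pytest.approx(2500)
        assert excess == 0.0

    def test_low_occupancy_agreement_with_closed_form(self):
        # evaluated on exact category probabilities, the subtraction estimate
        # agrees with the closed form within 15% when droplets are sparse
        p = category_probabilities(0.05, 0.03, 0.02)
        U = 10_000_000
        rec = record_from_counts(
            round(p.p_both * U), round(p.p_a_only * U), round(p.p_b_only * U), round(p.p_neither * U)
        )
        est = estimate_linked_closed_form(rec)
        assert est.lambda_linked_subtraction == pytest.approx(est.lambda_linked, rel=0.15)

    def test_high_occupancy_underestimates(self):
        # documented bias: at (0.5, 0.3, 0.2) the subtraction path gives ~0.067
        p = category_probabilities(0.5, 0.3, 0.2)
        U = 10_000_000
        rec = record_from_counts(
            round(p.p_both * U), round(p.p_a_only * U), round(p.p_b_only * U), round(p.p_neither * U)
        )
        est = estimate_linked_closed_form(rec)
        assert est.lambda_linked == pytest.approx(0.2, abs=1e-6)
        assert est.lambda_linked_subtraction == pytest.approx(0.067, abs=0.005)
        assert est.lambda_linked_subtraction < 0.5 * est.lambda_linked


class TestAssayMetadata:
    def test_bridge_length_bounds(self):
        lo, hi = bridge_length_bounds()
        assert (lo, hi) == (2746, 16_390)
        assert lo < hi
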