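"""Duplex-droplet linkage quantification of intact ("Bridge") mtDNA.

A duplex ddPCR assay targets two mitochondrial loci (16S and D-loop) in the
same droplets. Because mtDNA is circular, molecules that are still relatively
intact — at least 2746 bp, the shortest span between the two amplicons —
carry both targets and always produce double-positive droplets. Fragmented
molecules carry one target each and co-occur in a droplet only by chance.
Modelling the droplet loads of free-16S, free-D-loop and linked (Bridge)
molecules as independent Poisson processes with means (λa, λb, λL) gives
closed-form four-category probabilities, which this module inverts exactly;
the count-subtraction heuristic (observed double positives minus the
number expected under independence) is retained alongside for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InvalidInputError, SaturatedAssayError

__all__ = [
    "DuplexDropletRecord",
    "LinkageEstimate",
    "CategoryProbs",
    "category_probabilities",
    "invert_category_fractions",
    "estimate_linked_closed_form",
    "expected_double_positives",
    "bridge_length_bounds",
]

#: Minimum and maximum span (bp) of a molecule linking the two amplicons:
#: the shortest 16S–D-loop distance and the full mitogenome length.
BRIDGE_MIN_BP = 2746
BRIDGE_MAX_BP = 16390


@dataclass(frozen=True)
class DuplexDropletRecord:
    """Four-category droplet counts from one duplex well (A = 16S, B = D-loop)."""

    sample_id: str
    carboy: int
    time_nominal_h: float
    time_actual_h: float
    tech_rep: int
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    droplets_total: int

    def __post_init__(self) -> None:
        counts = (self.n_both, self.n_a_only, self.n_b_only, self.n_neither)
        if any(c < 0 for c in counts):
            raise InvalidInputError(f"{self.sample_id}: negative category count")
        if sum(counts) != self.droplets_total:
            raise InvalidInputError(
                f"{self.sample_id}: category counts sum to {sum(counts)}, "
                f"expected droplets_total={self.droplets_total}"
            )
        if self.droplets_total <= 0:
            raise InvalidInputError(f"{self.sample_id}: droplets_total must be > 0")


@dataclass(frozen=True)
class LinkageEstimate:
    """Per-droplet Poisson means for free and linked molecule classes."""

    lambda_a_free: float
    lambda_b_free: float
    lambda_linked: float
    expected_doubles_independent: float
    excess_doubles: float
    lambda_linked_subtraction: float
    floored: tuple[str, ...] = ()


class CategoryProbs(NamedTuple):
    p_both: float
    p_a_only: float
    p_b_only: float
    p_neither: float


def category_probabilities(
    lambda_a: float, lambda_b: float, lambda_linked: float
) -> CategoryProbs:
    """Exact four-category droplet probabilities under independent Poisson loads.

    A droplet is A-negative iff it holds no free-A and no linked molecule
    (probability ``exp(-(λa+λL))``), and similarly for B; the double-negative
    probability is ``exp(-(λa+λb+λL))``. ``p_both`` takes the remainder so the
    four probabilities sum to one exactly.
    """
    for name, lam in (("lambda_a", lambda_a), ("lambda_b", lambda_b), ("lambda_linked", lambda_linked)):
        if not (np.isfinite(lam) and lam >= 0):
            raise InvalidInputError(f"{name} must be finite and >= 0, got {lam}")
    p_neither = math.exp(-(lambda_a + lambda_b + lambda_linked))
    p_a_only = math.exp(-(lambda_b + lambda_linked)) - p_neither
    p_b_only = math.exp(-(lambda_a + lambda_linked)) - p_neither
    p_both = 1.0 - p_neither - p_a_only - p_b_only
    return CategoryProbs(p_both, p_a_only, p_b_only, p_neither)


def invert_category_fractions(qA: float, qB: float, q00: float) -> tuple[float, float, float]:
    """Exact inversion of negative-category fractions to Poisson loads.

    ``qA``/``qB`` are the A-/B-negative droplet fractions and ``q00`` the
    double-negative fraction. Returns (λa_free, λb_free, λL), unfloored.
    """
    if qA <= 0 or qB <= 0 or q00 <= 0:
        raise SaturatedAssayError("a required negative category fraction is zero")
    lam_linked = math.log(q00) - math.log(qA) - math.log(qB)
    return (-math.log(qA) - lam_linked, -math.log(qB) - lam_linked, lam_linked)


def estimate_linked_closed_form(rec: DuplexDropletRecord) -> LinkageEstimate:
    """Invert the observed category fractions for (λa_free, λb_free, λL).

    With ``qA`` the A-negative fraction, ``qB`` the B-negative fraction and
    ``q00`` the double-negative fraction, the Poisson model gives

        λL = ln q00 − ln qA − ln qB
        λa_free = −ln qA − λL,   λb_free = −ln qB − λL.

    Sampling noise can drive any of these slightly negative; physical
    concentrations cannot be, so negative estimates are floored at zero and
    flagged. The subtraction-heuristic estimate (excess double positives / U)
    is reported alongside.
    """
    U = rec.droplets_total
    qA = (rec.n_b_only + rec.n_neither) / U
    qB = (rec.n_a_only + rec.n_neither) / U
    q00 = rec.n_neither / U
    try:
        lam_a, lam_b, lam_linked = invert_category_fractions(qA, qB, q00)
    except SaturatedAssayError:
        raise SaturatedAssayError(
            f"{rec.sample_id}: a required negative category is empty; "
            "the well is saturated and unquantifiable"
        ) from None
    floored = []
    if lam_linked < 0:
        floored.append("lambda_linked")
        lam_linked = 0.0
    if lam_a < 0:
        floored.append("lambda_a_free")
        lam_a = 0.0
    if lam_b < 0:
        floored.append("lambda_b_free")
        lam_b = 0.0
    expected, excess = expected_double_positives(rec)
    return LinkageEstimate(
        lambda_a_free=lam_a,
        lambda_b_free=lam_b,
        lambda_linked=lam_linked,
        expected_doubles_independent=expected,
        excess_doubles=excess,
        lambda_linked_subtraction=excess / U,
        floored=tuple(floored),
    )


def expected_double_positives(rec: DuplexDropletRecord) -> tuple[float, float]:
    """Double positives expected from chance co-occupancy alone, and the excess.

    Under independence of the two markers the double-positive count would be
    ``U · (1 − qA) · (1 − qB)``; the observed excess over this is attributed to
    physically linked molecules. The implied per-droplet linked load
    ``excess / U`` underestimates λL at high occupancy (a documented bias of
    the heuristic) but agrees with the closed form when droplets are sparse.
    """
    U = rec.droplets_total
    qA = (rec.n_b_only + rec.n_neither) / U
    qB = (rec.n_a_only + rec.n_neither) / U
    expected = U * (1.0 - qA) * (1.0 - qB)
    excess = max(rec.n_both - expected, 0.0)
    return expected, excess


def bridge_length_bounds() -> tuple[int, int]:
    """Assay metadata: (minimum, maximum) bridging-fragment length in bp."""
    return (BRIDGE_MIN_BP, BRIDGE_MAX_BP)
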