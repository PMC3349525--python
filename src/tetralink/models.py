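"""Phenotype-class and gamete-class probability models.

Two inheritance models for a coupling-phase F2 seed-fluorescence design
with a green marker (proximal to the centromere) and a red marker
(distal) on the same chromosome:

* **Disomic** (diploids and allotetraploids with strict bivalent
  pairing): the four seed-phenotype frequencies depend on the
  recombination fraction ``r`` alone.
* **Tetrasomic** (autotetraploids): segregation among four homologues
  allows double reduction — sister-chromatid segments entering the same
  gamete — quantified by the coefficient ``alpha`` at the green marker.
  Phenotype frequencies are built from the four gamete classes (both
  markers / green only / red only / neither) by random union of gametes.

Seed phenotype classes are indexed 1..4 throughout: yellow (both
markers), green, red, grey (neither).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "R_MAX_DISOMIC",
    "R_MAX_TETRASOMIC",
    "ALPHA_MAX",
    "BETA_MAX",
    "DisomicParams",
    "TetrasomicParams",
    "GameteClassDistribution",
    "PhenotypeDistribution",
    "BetaPrediction",
    "disomic_phenotype_probs",
    "tetrasomic_gamete_probs",
    "phenotype_from_gametes",
    "tetrasomic_phenotype_probs",
    "green_marginal_probs",
    "predict_double_reduction_red",
]

#: Theoretical upper bound of the recombination fraction under disomic
#: inheritance (diploids and allotetraploids).
R_MAX_DISOMIC = 0.5
#: Theoretical upper bound of the recombination fraction under
#: tetrasomic inheritance (autotetraploids).
R_MAX_TETRASOMIC = 0.75
#: Theoretical maximum of the coefficient of double reduction.
ALPHA_MAX = 0.25
#: Printed maximum for the predicted double-reduction coefficient at the
#: second locus; predictions above it are flagged, not rejected.
BETA_MAX = 0.25


def _check_unit_interval(name: str, value: float, upper: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not (0.0 <= value <= upper):
        raise ValueError(f"{name} must lie in [0, {upper}], got {value!r}")
    return value


class GameteClassDistribution(NamedTuple):
    """Probabilities that a gamete carries both / green-only / red-only /
    neither marker allele."""

    g1: float
    g2: float
    g3: float
    g4: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


class PhenotypeDistribution(NamedTuple):
    """Probabilities of the yellow / green / red / grey seed classes."""

    f1: float
    f2: float
    f3: float
    f4: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


@dataclass(frozen=True)
class DisomicParams:
    """Recombination fraction under disomic inheritance, r ∈ [0, 1/2]."""

    r: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", _check_unit_interval("r", self.r, R_MAX_DISOMIC))


@dataclass(frozen=True)
class TetrasomicParams:
    """Double-reduction coefficient at the green marker, alpha ∈ [0, 1/4],
    and recombination fraction r ∈ [0, 3/4], under tetrasomic inheritance."""

    alpha: float
    r: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "alpha", _check_unit_interval("alpha", self.alpha, ALPHA_MAX)
        )
        object.__setattr__(
            self, "r", _check_unit_interval("r", self.r, R_MAX_TETRASOMIC)
        )


@dataclass(frozen=True)
class BetaPrediction:
    """Predicted double-reduction coefficient at the red (distal) marker.

    ``exceeds_bound`` flags a prediction above the theoretical maximum
    1/4; the value is still reported since beta is a derived prediction,
    not a fitted parameter.
    """

    beta: float
    exceeds_bound: bool = False


def disomic_phenotype_probs(r: float) -> PhenotypeDistribution:
    """Seed-phenotype distribution of the coupling-phase F2 under disomic
    inheritance.

    f1 = 3(1-r)^2/4 + r(1-r) + r^2/2 (yellow), f2 = f3 = r(2-r)/4
    (green, red), f4 = (1-r)^2/4 (grey).  At r = 0 this is the 3:1
    two-class ratio; at r = 1/2 the 9:3:3:1 dihybrid ratio.
    """
    r = _check_unit_interval("r", r, R_MAX_DISOMIC)
    f1 = 3.0 * (1.0 - r) ** 2 / 4.0 + r * (1.0 - r) + r * r / 2.0
    f2 = r * (2.0 - r) / 4.0
    f4 = (1.0 - r) ** 2 / 4.0
    return PhenotypeDistribution(f1, f2, f2, f4)


def tetrasomic_gamete_probs(alpha: float, r: float) -> GameteClassDistribution:
    """Gamete-class distribution produced by a tetrasomic duplex-marker
    parent with double reduction ``alpha`` at the green marker.

    The four classes are gametes carrying {green and red}, {green only},
    {red only}, {neither}.  The polynomials sum to one identically in
    (alpha, r).
    """
    alpha = _check_unit_interval("alpha", alpha, ALPHA_MAX)
    r = _check_unit_interval("r", r, R_MAX_TETRASOMIC)
    u = (1.0 - r) ** 2
    v = r * (1.0 - r)
    w = r * r
    g1 = (2.0 - alpha) * u / 4.0 + v / 2.0 + (1.0 - alpha) * w / 6.0
    g2 = (1.0 - alpha) * v / 3.0 + (10.0 - alpha) * w / 36.0
    g3 = v / 2.0 + (8.0 + alpha) * w / 36.0
    g4 = (2.0 + alpha) * (u / 4.0 + v / 3.0 + w / 6.0)
    g = GameteClassDistribution(g1, g2, g3, g4)
    if min(g) < 0.0:
        raise ValueError(
            f"negative gamete-class probability at alpha={alpha}, r={r}: {g}"
        )
    return g


def phenotype_from_gametes(g: GameteClassDistribution) -> PhenotypeDistribution:
    """Seed-phenotype distribution from random union of two gametes drawn
    from ``g``.

    A seed shows a marker iff at least one gamete carries it:
    f1 = g1(2-g1) + 2 g2 g3, f2 = g2(g2+2 g4), f3 = g3(g3+2 g4),
    f4 = g4^2.  Preserves normalisation: sum f = 1 whenever sum g = 1.
    """
    g1, g2, g3, g4 = g
    if min(g) < 0.0 or abs(g1 + g2 + g3 + g4 - 1.0) > 1e-9:
        raise ValueError(f"gamete distribution must be nonnegative and sum to 1: {g}")
    f1 = g1 * (2.0 - g1) + 2.0 * g2 * g3
    f2 = g2 * (g2 + 2.0 * g4)
    f3 = g3 * (g3 + 2.0 * g4)
    f4 = g4 * g4
    return PhenotypeDistribution(f1, f2, f3, f4)


def tetrasomic_phenotype_probs(alpha: float, r: float) -> PhenotypeDistribution:
    """Seed-phenotype distribution under tetrasomic inheritance: the
    gamete-class distribution pushed through random gamete union."""
    return phenotype_from_gametes(tetrasomic_gamete_probs(alpha, r))


def green_marginal_probs(alpha: float) -> tuple[float, float]:
    """Marginal probabilities (p_g, p_0) that an autotetraploid F2 seed
    carries / does not carry the green marker.

    Obtained by setting r = 0 in the tetrasomic phenotype probabilities:
    p_g = (12 - 4a - a^2)/16, p_0 = (2 + a)^2/16.  The green-marker
    margin depends on alpha only, which is what makes the two-step
    estimation of (alpha, r) possible.
    """
    alpha = _check_unit_interval("alpha", alpha, ALPHA_MAX)
    pg = (12.0 - 4.0 * alpha - alpha * alpha) / 16.0
    p0 = (2.0 + alpha) ** 2 / 16.0
    return pg, p0


def predict_double_reduction_red(alpha: float, r: float) -> BetaPrediction:
    """Predict the double-reduction coefficient at the red marker from the
    green-marker coefficient and the recombination fraction:

        beta = [alpha (3 - 4r)^2 + 2r (3 - 2r)] / 9
    """
    alpha = _check_unit_interval("alpha", alpha, ALPHA_MAX)
    r = _check_unit_interval("r", r, R_MAX_TETRASOMIC)
    beta = (alpha * (3.0 - 4.0 * r) ** 2 + 2.0 * r * (3.0 - 2.0 * r)) / 9.0
    return BetaPrediction(beta=beta, exceeds_bound=beta > BETA_MAX)
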