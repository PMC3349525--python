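"""Maximum-likelihood estimation of recombination frequency and double
reduction from four-class phenotype counts.

The data for one F2 population are the multinomial counts
(n1, n2, n3, n4) of yellow / green / red / grey seeds.  All
log-likelihoods are proportional: the multinomial coefficient is
omitted, so reported values are Sum_i n_i ln f_i in natural log.

Disomic model: one parameter r, estimated from the exact roots of the
polynomial score equation.  Tetrasomic model: two-step procedure —
alpha from the closed-form green-marker marginal (which depends on
alpha alone), then r by maximising the four-class likelihood with
alpha held fixed.  Standard errors come from the observed Fisher
information, the negative second derivative of the log-likelihood at
the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .models import (
    ALPHA_MAX,
    R_MAX_DISOMIC,
    R_MAX_TETRASOMIC,
    BetaPrediction,
    PhenotypeDistribution,
    disomic_phenotype_probs,
    green_marginal_probs,
    predict_double_reduction_red,
    tetrasomic_phenotype_probs,
)

__all__ = [
    "PhenotypeCounts",
    "Estimate",
    "FitResult",
    "LikelihoodRatio",
    "log_likelihood",
    "observed_information_se",
    "mle_disomic",
    "mle_alpha_marginal",
    "mle_r_tetrasomic",
    "fit_population",
    "likelihood_ratio",
    "moment_estimate",
]

ModelLabel = Literal["disomic", "tetrasomic"]


@dataclass(frozen=True)
class PhenotypeCounts:
    """Observed counts of the four seed-phenotype classes.

    n1 yellow (both markers), n2 green only, n3 red only, n4 grey.
    """

    n1: int
    n2: int
    n3: int
    n4: int

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3", "n4"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n < 1:
            raise ValueError("total count must be at least 1")

    @property
    def n(self) -> int:
        """Total population size."""
        return self.n1 + self.n2 + self.n3 + self.n4

    @property
    def ng(self) -> int:
        """Individuals carrying the green marker (yellow + green)."""
        return self.n1 + self.n2

    @property
    def n0(self) -> int:
        """Individuals not carrying the green marker (red + grey)."""
        return self.n3 + self.n4

    def as_array(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.n3, self.n4], dtype=float)

    def scaled(self, k: int) -> "PhenotypeCounts":
        return PhenotypeCounts(self.n1 * k, self.n2 * k, self.n3 * k, self.n4 * k)


@dataclass(frozen=True)
class Estimate:
    """A scalar MLE with Wald standard error and solver diagnostics.

    ``se`` is ``None`` when the estimate sits on the parameter boundary
    or the observed information is not positive — it is never
    extrapolated.  ``loglik`` is the proportional log-likelihood at the
    estimate.
    """

    value: float
    se: Optional[float]
    loglik: float
    n_roots_in_domain: int = 1
    at_boundary: bool = False


@dataclass(frozen=True)
class FitResult:
    """Full per-population fit: model label, recombination estimate, and
    (tetrasomic only) double-reduction estimate/prediction, plus the
    proportion-based comparison estimator."""

    model: ModelLabel
    counts: PhenotypeCounts
    r: Estimate
    alpha: Optional[Estimate] = None
    beta: Optional[BetaPrediction] = None
    moment_r: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        def est(e: Optional[Estimate]):
            if e is None:
                return None
            return {
                "value": e.value,
                "se": e.se,
                "loglik": e.loglik,
                "n_roots_in_domain": e.n_roots_in_domain,
                "at_boundary": e.at_boundary,
            }

        return {
            "model": self.model,
            "counts": [self.counts.n1, self.counts.n2, self.counts.n3, self.counts.n4],
            "r": est(self.r),
            "alpha": est(self.alpha),
            "beta": None
            if self.beta is None
            else {"value": self.beta.beta, "exceeds_bound": self.beta.exceeds_bound},
            "moment_r": self.moment_r,
        }


class LikelihoodRatio(NamedTuple):
    ratio: float
    log_ratio: float


def log_likelihood(counts: PhenotypeCounts, f: PhenotypeDistribution | Sequence[float]) -> float:
    """Proportional multinomial log-likelihood Sum n_i ln f_i.

    Classes with zero count contribute nothing whatever their
    probability; a class with positive count and zero probability makes
    the parameter point impossible and returns ``-inf``.
    """
    total = 0.0
    for ni, fi in zip(counts.as_array(), f):
        if ni > 0.0:
            if fi <= 0.0:
                return -math.inf
            total += ni * math.log(fi)
    return total


def observed_information_se(
    loglik_fn: Callable[[float], float], theta_hat: float, step: float = 1e-5
) -> float:
    """Wald standard error sqrt(-1 / L''(theta_hat)) from the observed
    Fisher information.

    The second derivative is a Richardson-extrapolated central
    difference (steps ``step`` and ``2*step``), accurate enough to
    resolve four decimals of the SEs arising here.  Raises if the
    curvature is not negative (theta_hat not an interior maximum).
    """
    theta_hat = float(theta_hat)

    def d2(h: float) -> float:
        return (loglik_fn(theta_hat + h) - 2.0 * loglik_fn(theta_hat) + loglik_fn(theta_hat - h)) / (h * h)

    curv = (4.0 * d2(step) - d2(2.0 * step)) / 3.0
    if not curv < 0.0:
        raise ValueError(
            f"observed information not positive at {theta_hat} (L''={curv}); "
            "not a local maximum"
        )
    return math.sqrt(-1.0 / curv)


def _disomic_score_roots(counts: PhenotypeCounts) -> list[float]:
    """Interior stationary points of the disomic log-likelihood.

    Clearing denominators in dL/dr = 0 yields (1-r) times a quartic in
    r; the quartic's real roots inside (0, 1/2) are returned.
    """
    n1, m, n4 = counts.n1, counts.n2 + counts.n3, counts.n4
    n = n1 + m + n4
    coeffs = [
        n,
        -4.0 * n,
        8.0 * m + 5.0 * n1 + 7.0 * n4,
        -(8.0 * m + 2.0 * n1 + 6.0 * n4),
        3.0 * m,
    ]
    roots = np.roots(coeffs)
    out = []
    for z in roots:
        if abs(z.imag) < 1e-9 and 0.0 < z.real < R_MAX_DISOMIC:
            out.append(float(z.real))
    return sorted(out)


def _argmax_with_endpoints(
    loglik: Callable[[float], float],
    interior_roots: Sequence[float],
    lo: float,
    hi: float,
) -> tuple[float, bool]:
    """Pick the likelihood argmax over interior stationary points and the
    two domain endpoints; returns (argmax, at_boundary)."""
    candidates = [(float(x), False) for x in interior_roots]
    candidates += [(lo, True), (hi, True)]
    best, boundary = max(candidates, key=lambda c: loglik(c[0]))
    return best, boundary


def mle_disomic(counts: PhenotypeCounts) -> Estimate:
    """MLE of the recombination fraction under the disomic model.

    Exact polynomial score-equation roots, compared with the domain
    endpoints by log-likelihood.  SE from the observed information at
    interior estimates; undefined (None) on the boundary.
    """
    if counts.n < 2:
        raise ValueError("need at least 2 individuals to estimate r")
    ll = lambda r: log_likelihood(counts, disomic_phenotype_probs(r))
    roots = _disomic_score_roots(counts)
    r_hat, at_boundary = _argmax_with_endpoints(ll, roots, 0.0, R_MAX_DISOMIC)
    se = None if at_boundary else observed_information_se(ll, r_hat)
    return Estimate(
        value=r_hat,
        se=se,
        loglik=ll(r_hat),
        n_roots_in_domain=len(roots),
        at_boundary=at_boundary,
    )


def mle_alpha_marginal(counts: PhenotypeCounts) -> Estimate:
    """MLE of the double-reduction coefficient alpha from the green-marker
    margin (n_g vs n_0) of an autotetraploid population.

    The score equation of L(alpha) = n_g ln p_g + n_0 ln p_0 reduces to
    a quadratic whose admissible root is the exact moment inversion
    alpha = 4 sqrt(n_0/n) - 2; it is clamped to [0, 1/4] with the
    boundary flagged.  The reported loglik is the two-class marginal
    log-likelihood.
    """
    ng, n0 = counts.ng, counts.n0
    if ng <= 0 or n0 <= 0:
        raise ValueError("marginal alpha estimation needs ng > 0 and n0 > 0")

    def ll(a: float) -> float:
        pg, p0 = green_marginal_probs(a)
        return ng * math.log(pg) + n0 * math.log(p0)

    a_raw = 4.0 * math.sqrt(n0 / (ng + n0)) - 2.0
    if a_raw <= 0.0:
        return Estimate(
            0.0, None, ll(0.0), n_roots_in_domain=int(a_raw == 0.0), at_boundary=True
        )
    if a_raw > ALPHA_MAX:
        return Estimate(ALPHA_MAX, None, ll(ALPHA_MAX), n_roots_in_domain=0, at_boundary=True)
    se = observed_information_se(ll, a_raw)
    return Estimate(a_raw, se, ll(a_raw), n_roots_in_domain=1, at_boundary=False)


def _tetrasomic_score(counts: PhenotypeCounts, alpha: float, r: float) -> float:
    """Analytic dL/dr of the four-class tetrasomic log-likelihood at fixed
    alpha, via the chain rule through the gamete-class polynomials."""
    a = alpha
    u = (1.0 - r) ** 2
    v = r * (1.0 - r)
    w = r * r
    g1 = (2.0 - a) * u / 4.0 + v / 2.0 + (1.0 - a) * w / 6.0
    g2 = (1.0 - a) * v / 3.0 + (10.0 - a) * w / 36.0
    g3 = v / 2.0 + (8.0 + a) * w / 36.0
    g4 = (2.0 + a) * (u / 4.0 + v / 3.0 + w / 6.0)
    du = 2.0 * (r - 1.0)
    dv = 1.0 - 2.0 * r
    dw = 2.0 * r
    d1 = (2.0 - a) * du / 4.0 + dv / 2.0 + (1.0 - a) * dw / 6.0
    d2 = (1.0 - a) * dv / 3.0 + (10.0 - a) * dw / 36.0
    d3 = dv / 2.0 + (8.0 + a) * dw / 36.0
    d4 = (2.0 + a) * (du / 4.0 + dv / 3.0 + dw / 6.0)
    f = (
        g1 * (2.0 - g1) + 2.0 * g2 * g3,
        g2 * (g2 + 2.0 * g4),
        g3 * (g3 + 2.0 * g4),
        g4 * g4,
    )
    df = (
        2.0 * d1 * (1.0 - g1) + 2.0 * (d2 * g3 + g2 * d3),
        2.0 * (d2 * g2 + d2 * g4 + g2 * d4),
        2.0 * (d3 * g3 + d3 * g4 + g3 * d4),
        2.0 * g4 * d4,
    )
    score = 0.0
    for ni, fi, dfi in zip(counts.as_array(), f, df):
        if ni > 0.0:
            score += ni * dfi / fi
    return score


def mle_r_tetrasomic(counts: PhenotypeCounts, alpha_fixed: float) -> Estimate:
    """MLE of the recombination fraction under the tetrasomic model with
    the double-reduction coefficient held fixed.

    Stationary points are located by bracketing sign changes of the
    analytic score on a fine grid and polishing with Brent root-finding
    (tolerance 1e-12 in r); the argmax over stationary points and the
    endpoints {0, 3/4} is returned.  SE from the observed information of
    the conditional (alpha fixed) log-likelihood.
    """
    if not 0.0 <= alpha_fixed <= ALPHA_MAX:
        raise ValueError(f"alpha_fixed must lie in [0, {ALPHA_MAX}]")
    ll = lambda r: log_likelihood(counts, tetrasomic_phenotype_probs(alpha_fixed, r))
    score = lambda r: _tetrasomic_score(counts, alpha_fixed, r)

    eps = 1e-9
    grid = np.linspace(eps, R_MAX_TETRASOMIC - eps, 1501)
    s = np.array([score(r) for r in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if s[i] == 0.0:
            roots.append(float(grid[i]))
        elif s[i] * s[i + 1] < 0.0:
            roots.append(float(brentq(score, grid[i], grid[i + 1], xtol=1e-12)))
    r_hat, at_boundary = _argmax_with_endpoints(ll, roots, 0.0, R_MAX_TETRASOMIC)
    se = None if at_boundary else observed_information_se(ll, r_hat)
    return Estimate(
        value=r_hat,
        se=se,
        loglik=ll(r_hat),
        n_roots_in_domain=len(roots),
        at_boundary=at_boundary,
    )


def moment_estimate(counts: PhenotypeCounts, variant: str = "proportion") -> float:
    """Comparison (moment) estimator of r from the single-colour classes.

    ``"proportion"`` returns (n2+n3)/n, the observed fraction of green
    plus red seeds — the variant that reproduces the earlier report's
    published estimates.  ``"printed_equation"`` solves
    2r - r^2 = 2(n2+n3)/n, i.e. r = 1 - sqrt(1 - 2(n2+n3)/n), the
    literal published description, which yields different values.
    """
    p = (counts.n2 + counts.n3) / counts.n
    if variant == "proportion":
        return p
    if variant == "printed_equation":
        if 2.0 * p > 1.0:
            raise ValueError(f"2(n2+n3)/n = {2 * p:.4f} > 1; moment equation has no real root")
        return 1.0 - math.sqrt(1.0 - 2.0 * p)
    raise ValueError(f"unknown variant {variant!r}")


def likelihood_ratio(
    counts: PhenotypeCounts,
    model: ModelLabel,
    params_a,
    params_b,
) -> LikelihoodRatio:
    """Ratio of likelihoods at two parameter points on the same data,
    exp(L_a - L_b), with the log-ratio reported alongside (the ratio
    itself may overflow for large count vectors).

    For the disomic model each params is a scalar r; for the tetrasomic
    model an (alpha, r) pair.
    """
    if model == "disomic":
        fa = disomic_phenotype_probs(float(params_a))
        fb = disomic_phenotype_probs(float(params_b))
    elif model == "tetrasomic":
        fa = tetrasomic_phenotype_probs(*params_a)
        fb = tetrasomic_phenotype_probs(*params_b)
    else:
        raise ValueError(f"unknown model {model!r}")
    log_ratio = log_likelihood(counts, fa) - log_likelihood(counts, fb)
    ratio = math.exp(log_ratio) if log_ratio < 700.0 else math.inf
    return LikelihoodRatio(ratio=ratio, log_ratio=log_ratio)


def fit_population(counts: PhenotypeCounts, model: ModelLabel) -> FitResult:
    """Fit one F2 population.

    disomic: the score-equation MLE of r.  tetrasomic: the two-step
    procedure — alpha from the green-marker margin, r from the
    four-class likelihood at that alpha, and the predicted
    double-reduction coefficient beta at the red marker.  The
    proportion-based comparison estimate is always attached.
    """
    if model == "disomic":
        r_est = mle_disomic(counts)
        return FitResult(
            model=model, counts=counts, r=r_est, moment_r=moment_estimate(counts)
        )
    if model == "tetrasomic":
        alpha_est = mle_alpha_marginal(counts)
        r_est = mle_r_tetrasomic(counts, alpha_est.value)
        beta = predict_double_reduction_red(alpha_est.value, r_est.value)
        return FitResult(
            model=model,
            counts=counts,
            r=r_est,
            alpha=alpha_est,
            beta=beta,
            moment_r=moment_estimate(counts),
        )
    raise ValueError(f"unknown model {model!r}; expected 'disomic' or 'tetrasomic'")
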