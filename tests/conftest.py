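import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from tetralink.inference import PhenotypeCounts
from tetralink.models import R_MAX_DISOMIC, R_MAX_TETRASOMIC


@pytest.fixture
def diploid_counts() -> PhenotypeCounts:
    return PhenotypeCounts(2805, 322, 333, 791)


@pytest.fixture
def allotetraploid_counts() -> PhenotypeCounts:
    return PhenotypeCounts(1484, 275, 298, 320)


@pytest.fixture
def autotetraploid_counts() -> PhenotypeCounts:
    return PhenotypeCounts(12707, 1868, 2216, 3098)


def _grid_ll(counts: PhenotypeCounts, f_stack: np.ndarray) -> np.ndarray:
    """Vectorised proportional log-likelihood over a stack of phenotype
    distributions (shape (4, m)); impossible points get -inf."""
    n = counts.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.log(f_stack)
    logf[:, :][np.isneginf(logf) & (n[:, None] == 0)] = 0.0
    ll = (n[:, None] * np.where(n[:, None] > 0, logf, 0.0)).sum(axis=0)
    ll[np.any((f_stack <= 0) & (n[:, None] > 0), axis=0)] = -np.inf
    return ll


def disomic_f_grid(r: np.ndarray) -> np.ndarray:
    f1 = (3.0 - 2.0 * r + r * r) / 4.0
    f2 = r * (2.0 - r) / 4.0
    f4 = (1.0 - r) ** 2 / 4.0
    return np.stack([f1, f2, f2, f4])


def tetrasomic_f_grid(alpha: float, r: np.ndarray) -> np.ndarray:
    a = alpha
    u = (1.0 - r) ** 2
    v = r * (1.0 - r)
    w = r * r
    g1 = (2.0 - a) * u / 4.0 + v / 2.0 + (1.0 - a) * w / 6.0
    g2 = (1.0 - a) * v / 3.0 + (10.0 - a) * w / 36.0
    g3 = v / 2.0 + (8.0 + a) * w / 36.0
    g4 = (2.0 + a) * (u / 4.0 + v / 3.0 + w / 6.0)
    return np.stack(
        [g1 * (2.0 - g1) + 2.0 * g2 * g3, g2 * (g2 + 2.0 * g4), g3 * (g3 + 2.0 * g4), g4 * g4]
    )


def grid_search_mle(
    counts: PhenotypeCounts, model: str, alpha: float | None = None, step: float = 1e-5
) -> float:
    """Independent brute-force oracle: dense grid over the parameter
    domain followed by bounded local refinement of the log-likelihood."""
    if model == "disomic":
        hi = R_MAX_DISOMIC
        f_of = disomic_f_grid
    else:
        hi = R_MAX_TETRASOMIC
        f_of = lambda r: tetrasomic_f_grid(alpha, r)
    grid = np.arange(0.0, hi + step / 2, step)
    ll = _grid_ll(counts, f_of(grid))
    best = float(grid[int(np.argmax(ll))])
    lo_b, hi_b = max(0.0, best - 2 * step), min(hi, best + 2 * step)

    def neg(r: float) -> float:
        return -float(_grid_ll(counts, f_of(np.array([r])))[0])

    res = minimize_scalar(neg, bounds=(lo_b, hi_b), method="bounded", options={"xatol": 1e-12})
    return float(res.x) if -res.fun >= ll.max() else best
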