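"""Multinomial simulation of phenotype counts and parameter-recovery
experiments.

Sampling is at the phenotype-class level the likelihood models: each
replicate is one multinomial draw of size n over the four seed classes
under the chosen inheritance model.  No meiosis-level mechanism
(pairing configurations, interference) is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .inference import Estimate, FitResult, PhenotypeCounts, fit_population
from .models import (
    DisomicParams,
    PhenotypeDistribution,
    TetrasomicParams,
    disomic_phenotype_probs,
    tetrasomic_phenotype_probs,
)

__all__ = [
    "SimulationConfig",
    "ParameterRecovery",
    "RecoverySummary",
    "model_distribution",
    "simulate_counts",
    "run_recovery",
]

Params = Union[DisomicParams, TetrasomicParams]

#: z quantile for nominal 95% Wald intervals.
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation scenario: inheritance model, true parameters,
    population size, replicate count and master seed."""

    model: str
    params: Params
    n: int
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model == "disomic":
            if not isinstance(self.params, DisomicParams):
                raise TypeError("disomic model requires DisomicParams")
        elif self.model == "tetrasomic":
            if not isinstance(self.params, TetrasomicParams):
                raise TypeError("tetrasomic model requires TetrasomicParams")
        else:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n < 1 or self.replicates < 1:
            raise ValueError("n and replicates must be positive")


def model_distribution(config: SimulationConfig) -> PhenotypeDistribution:
    """Phenotype-class distribution implied by the scenario's model and
    parameters."""
    if config.model == "disomic":
        return disomic_phenotype_probs(config.params.r)
    return tetrasomic_phenotype_probs(config.params.alpha, config.params.r)


def simulate_counts(config: SimulationConfig) -> list[PhenotypeCounts]:
    """Draw one multinomial count vector per replicate.

    Each replicate uses its own counter-based substream seeded by
    (config.seed, replicate index), so results are reproducible and
    independent of execution order.
    """
    f = np.asarray(model_distribution(config), dtype=float)
    out = []
    for i in range(config.replicates):
        rng = np.random.default_rng([config.seed, i])
        n1, n2, n3, n4 = rng.multinomial(config.n, f)
        out.append(PhenotypeCounts(int(n1), int(n2), int(n3), int(n4)))
    return out


@dataclass(frozen=True)
class ParameterRecovery:
    """Recovery statistics for one parameter across replicates."""

    name: str
    truth: float
    mean_estimate: float
    bias: float
    empirical_sd: float
    mean_se: Optional[float]
    coverage95: Optional[float]


@dataclass(frozen=True)
class RecoverySummary:
    """Aggregate of a parameter-recovery experiment.

    ``boundary_rate`` is the fraction of replicates whose fit hit a
    parameter boundary; ``n_failed`` counts replicates whose fit raised
    and were excluded from the moments.
    """

    config: SimulationConfig
    parameters: tuple[ParameterRecovery, ...]
    boundary_rate: float
    n_failed: int

    def parameter(self, name: str) -> ParameterRecovery:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)


def _recover_one(name: str, truth: float, estimates: list[Estimate]) -> ParameterRecovery:
    values = np.array([e.value for e in estimates])
    ses = [e.se for e in estimates if e.se is not None]
    covered = [
        abs(e.value - truth) <= _Z95 * e.se for e in estimates if e.se is not None
    ]
    return ParameterRecovery(
        name=name,
        truth=truth,
        mean_estimate=float(values.mean()),
        bias=float(values.mean() - truth),
        empirical_sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        mean_se=float(np.mean(ses)) if ses else None,
        coverage95=float(np.mean(covered)) if covered else None,
    )


def run_recovery(config: SimulationConfig) -> RecoverySummary:
    """Simulate, refit each replicate, and summarise bias, spread, SE
    calibration and 95% Wald coverage per parameter."""
    fits: list[FitResult] = []
    n_failed = 0
    for counts in simulate_counts(config):
        try:
            fits.append(fit_population(counts, config.model))
        except (ValueError, ArithmeticError):
            n_failed += 1
    if not fits:
        raise RuntimeError("all replicates failed to fit")

    params = []
    params.append(_recover_one("r", config.params.r, [f.r for f in fits]))
    boundary_hits = [f.r.at_boundary for f in fits]
    if config.model == "tetrasomic":
        params.append(
            _recover_one("alpha", config.params.alpha, [f.alpha for f in fits])
        )
        boundary_hits = [
            br or f.alpha.at_boundary for br, f in zip(boundary_hits, fits)
        ]
    return RecoverySummary(
        config=config,
        parameters=tuple(params),
        boundary_rate=float(np.mean(boundary_hits)),
        n_failed=n_failed,
    )
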