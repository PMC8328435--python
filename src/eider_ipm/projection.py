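"""Stage-structured demographic core for a prebreeding-census female model.

The life cycle has four stages: 1-year-olds (``n1``), non-breeding
2-year-olds (``n2``), breeding 2-year-olds (``n3``), and breeders aged 3+
(``n4``).  Recruitment is delayed: a 2-year-old breeds with propensity
``alpha``; all 3+ females breed.  Only breeders are observable on the
breeding grounds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StageVector",
    "DemographicRates",
    "AbundanceSeries",
    "build_projection_matrix",
    "project_deterministic",
    "project_stochastic",
    "total_females",
    "breeding_abundance",
    "lambda_series",
    "geometric_mean_growth",
]


@dataclass(frozen=True)
class StageVector:
    """Latent female abundances in the four life-cycle stages for one year."""

    year: int
    n1: float
    n2: float
    n3: float
    n4: float

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3", "n4"):
            if getattr(self, name) < 0:
                raise ValueError(f"stage abundance {name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.n3, self.n4], dtype=float)


@dataclass(frozen=True)
class DemographicRates:
    """Annual demographic rates acting on the interval t -> t+1.

    phi_j : first-year survival (30 days old to age 1)
    phi_a : survival of females aged 1+ (all share one rate)
    alpha : breeding propensity of 2-year-old females
    fec   : ducklings (both sexes) surviving to 30 days per breeding female
    """

    phi_j: float
    phi_a: float
    alpha: float
    fec: float

    def __post_init__(self) -> None:
        for name in ("phi_j", "phi_a", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fec < 0:
            raise ValueError(f"fec={self.fec} must be non-negative")


@dataclass(frozen=True)
class AbundanceSeries:
    """Per-year total female (Ntot) and breeding (Nbpop) abundances."""

    years: np.ndarray
    ntot: np.ndarray
    nbpop: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.years) == len(self.ntot) == len(self.nbpop)):
            raise ValueError("years, ntot, nbpop must have equal length")
        if np.any(np.asarray(self.ntot) < 0) or np.any(np.asarray(self.nbpop) < 0):
            raise ValueError("abundances must be non-negative")


def build_projection_matrix(rates: DemographicRates) -> np.ndarray:
    """Projection matrix A for the four-stage prebreeding-census model.

    Recruitment enters row 1 from the two breeding stages as
    (fec/2)*phi_j (female-only accounting, equal sex ratio at 30 days);
    1-year-olds transition to non-breeding or breeding 2-year-olds with
    phi_a*(1-alpha) and phi_a*alpha; stages 2-4 survive into 4 with phi_a.
    """
    a = np.zeros((4, 4))
    a[0, 2] = a[0, 3] = 0.5 * rates.fec * rates.phi_j
    a[1, 0] = rates.phi_a * (1.0 - rates.alpha)
    a[2, 0] = rates.phi_a * rates.alpha
    a[3, 1] = a[3, 2] = a[3, 3] = rates.phi_a
    return a


def project_deterministic(sv: StageVector, rates: DemographicRates) -> StageVector:
    """One deterministic projection step (expected-value state equations)."""
    n = build_projection_matrix(rates) @ sv.as_array()
    return StageVector(sv.year + 1, *n)


def project_stochastic(
    sv: StageVector, rates: DemographicRates, rng: np.random.Generator
) -> StageVector:
    """One demographically stochastic projection step.

    Recruitment is Poisson; transitions of 1-year-olds are trinomial
    (survive & skip breeding / survive & breed / die); survival of stages
    2-4 is binomial.  The expectation equals :func:`project_deterministic`.
    """
    stages = sv.as_array()
    if not np.allclose(stages, np.round(stages)):
        raise ValueError("stochastic projection requires integer-valued stages")
    n1, n2, n3, n4 = (int(round(v)) for v in stages)

    recruits = rng.poisson(0.5 * rates.fec * rates.phi_j * (n3 + n4))
    p_nb = rates.phi_a * (1.0 - rates.alpha)
    p_b = rates.phi_a * rates.alpha
    nb, b, _dead = rng.multinomial(n1, [p_nb, p_b, 1.0 - p_nb - p_b])
    adults = rng.binomial(n2 + n3 + n4, rates.phi_a)
    return StageVector(sv.year + 1, float(recruits), float(nb), float(b), float(adults))


def total_females(sv: StageVector) -> float:
    """Total female abundance Ntot = n1 + n2 + n3 + n4."""
    return sv.n1 + sv.n2 + sv.n3 + sv.n4


def breeding_abundance(sv: StageVector) -> float:
    """Breeding abundance (males + females) Nbpop = (n3 + n4) * 2."""
    return 2.0 * (sv.n3 + sv.n4)


def lambda_series(n: np.ndarray) -> np.ndarray:
    """Per-interval growth rates lambda_t = N_{t+1} / N_t."""
    n = np.asarray(n, dtype=float)
    if n.size < 2:
        raise ValueError("need at least two abundances")
    if np.any(n <= 0):
        raise ValueError("abundances must be positive for growth rates")
    return n[1:] / n[:-1]


def geometric_mean_growth(lambdas: np.ndarray) -> float:
    """Geometric mean of per-interval growth rates."""
    lam = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if np.any(lam <= 0):
        raise ValueError("growth rates must be positive")
    return float(np.exp(np.mean(np.log(lam))))
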