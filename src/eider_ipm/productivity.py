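"""Productivity components: nest success, clutch size at hatch, fecundity.

Nest success (probability that a nest hatches at least one egg) is binomial
per year with a logit-scale annual random effect; clutch size at hatch is
Poisson around a single time-constant mean; duckling survival to 30 days is
a known constant (0.67).  Fecundity per breeding female is the product
``fec_t = ns_t * cs * ds``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "NestYear",
    "DUCKLING_SURVIVAL",
    "read_nest_data",
    "nest_success_loglik",
    "clutch_loglik",
    "fecundity",
]

#: survival of ducklings from hatch to 30 days, supplied as data
DUCKLING_SURVIVAL = 0.67


@dataclass(frozen=True)
class NestYear:
    """One breeding season's nest records."""

    year: int
    n_nests: int
    n_success: int
    clutch_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.n_success <= self.n_nests:
            raise ValueError(
                f"year {self.year}: n_success must lie in [0, n_nests]"
            )
        if any(c < 0 for c in self.clutch_sizes):
            raise ValueError(f"year {self.year}: clutch sizes must be non-negative")


def read_nest_data(path_or_df) -> list[NestYear]:
    """Read the nest CSV: year, n_nests, n_success, clutch_sizes.

    ``clutch_sizes`` holds semicolon-separated clutch-at-hatch counts for the
    successful nests (may be empty).
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    required = {"year", "n_nests", "n_success"}
    if not required.issubset(df.columns):
        raise ValueError(f"nest CSV must have columns {sorted(required)}")
    out = []
    for i, row in df.iterrows():
        raw = row.get("clutch_sizes", "")
        if pd.isna(raw) or str(raw).strip() == "":
            clutches: tuple[int, ...] = ()
        else:
            try:
                clutches = tuple(int(tok) for tok in str(raw).split(";"))
            except ValueError as exc:
                raise ValueError(f"line {i + 2}: bad clutch_sizes field") from exc
        try:
            out.append(
                NestYear(
                    year=int(row["year"]),
                    n_nests=int(row["n_nests"]),
                    n_success=int(row["n_success"]),
                    clutch_sizes=clutches,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {i + 2}: {exc}") from exc
    return out


def nest_success_loglik(data: list[NestYear], ns: np.ndarray) -> float:
    """Binomial log-likelihood of annual nest-success counts.

    ``ns[t]`` is the success probability for ``data[t]``'s year.
    """
    ns = np.asarray(ns, dtype=float)
    if ns.size != len(data):
        raise ValueError("ns must supply one probability per nest year")
    total = 0.0
    for d, prob in zip(data, ns):
        total += stats.binom.logpmf(d.n_success, d.n_nests, prob)
    return float(total)


def clutch_loglik(data: list[NestYear], cs: float) -> float:
    """Poisson log-likelihood of all observed clutch-at-hatch counts."""
    if cs <= 0:
        raise ValueError("mean clutch size must be positive")
    counts = np.array([c for d in data for c in d.clutch_sizes], dtype=float)
    if counts.size == 0:
        return 0.0
    return float(np.sum(counts * np.log(cs) - cs - special.gammaln(counts + 1.0)))


def fecundity(ns, cs: float, ds: float = DUCKLING_SURVIVAL):
    """Expected 30-day ducklings (both sexes) per breeding female."""
    return np.asarray(ns, dtype=float) * cs * ds if np.ndim(ns) else float(ns) * cs * ds
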