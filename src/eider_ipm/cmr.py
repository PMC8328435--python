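"""Capture-recapture structures for females marked as ducklings or breeders.

Capture histories are reduced to m-arrays (release occasion x occasion of
first recapture) and evaluated under the multinomial formulation of a
multistate Cormack-Jolly-Seber model with unobservable states: 1-year-olds
and non-breeding 2-year-olds never appear on the breeding grounds, so a
duckling-marked bird cannot be recaptured one year after release, and its
first-recapture cell probabilities route through the latent recruit states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CaptureHistory",
    "MArray",
    "MArraySet",
    "read_capture_histories",
    "build_marray",
    "build_marrays",
    "adult_cell_probabilities",
    "duckling_cell_probabilities",
    "cmr_loglik",
]

COHORTS = ("duckling", "adult")


@dataclass(frozen=True)
class CaptureHistory:
    """One female's detection record from first marking onward.

    ``detections`` is a 0/1 array aligned with ``years`` (all study years);
    entries before ``first_year`` are zero by construction.
    """

    id: str
    cohort: str
    first_year: int
    years: np.ndarray
    detections: np.ndarray

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        years = np.asarray(self.years)
        det = np.asarray(self.detections)
        if years.shape != det.shape:
            raise ValueError("years and detections must align")
        if self.first_year not in years:
            raise ValueError(f"first_year {self.first_year} outside study years")
        f = int(np.searchsorted(years, self.first_year))
        if det[f] != 1:
            raise ValueError(f"{self.id}: no detection recorded at first_year")
        if np.any(det[:f] != 0):
            raise ValueError(f"{self.id}: detection before first_year")
        if self.cohort == "duckling" and f + 1 < det.size and det[f + 1] == 1:
            raise ValueError(
                f"{self.id}: duckling-marked bird detected one year after "
                "release; 1-year-olds are unobservable"
            )

    @property
    def first_index(self) -> int:
        return int(np.searchsorted(self.years, self.first_year))


@dataclass
class MArray:
    """Release counts and first-recapture counts for one marking cohort.

    ``m[t, j]`` counts animals released at occasion ``t`` (0-based) and first
    recaptured at occasion ``j > t``; ``never[t]`` counts those never seen
    again.  Rows exist for occasions ``0 .. n_occasions-2``.
    """

    releases: np.ndarray
    m: np.ndarray
    never: np.ndarray

    @property
    def n_occasions(self) -> int:
        return self.m.shape[1]

    def validate(self) -> None:
        if np.any(self.m < 0) or np.any(self.never < 0):
            raise ValueError("m-array counts must be non-negative")
        if not np.array_equal(self.m.sum(axis=1) + self.never, self.releases):
            raise ValueError("m-array rows must sum to release counts")


@dataclass
class MArraySet:
    duckling: MArray
    adult: MArray

    def validate(self) -> None:
        self.duckling.validate()
        self.adult.validate()


def read_capture_histories(path_or_df) -> list[CaptureHistory]:
    """Read and validate the capture-history CSV.

    Schema: ``id``, ``cohort`` in {duckling, adult}, ``first_year``, then one
    0/1 column per study year (column names are the years).  Raises
    ``ValueError`` with the offending line number on schema violations.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    required = {"id", "cohort", "first_year"}
    if not required.issubset(df.columns):
        raise ValueError(f"capture-history CSV must have columns {sorted(required)}")
    year_cols = [c for c in df.columns if c not in required]
    try:
        years = np.array(sorted(int(c) for c in year_cols))
    except ValueError as exc:
        raise ValueError(f"non-year column in capture-history CSV: {exc}") from exc
    if df.empty:
        logger.warning("capture-history file contains no records")
        return []
    histories = []
    for i, row in df.iterrows():
        det = np.array([int(row[str(y)]) for y in years])
        if np.any((det != 0) & (det != 1)):
            raise ValueError(f"line {i + 2}: detections must be 0/1")
        try:
            histories.append(
                CaptureHistory(
                    id=str(row["id"]),
                    cohort=str(row["cohort"]),
                    first_year=int(row["first_year"]),
                    years=years,
                    detections=det,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {i + 2}: {exc}") from exc
    return histories


def _empty_marray(n_occ: int) -> MArray:
    return MArray(
        releases=np.zeros(n_occ - 1, dtype=int),
        m=np.zeros((n_occ - 1, n_occ), dtype=int),
        never=np.zeros(n_occ - 1, dtype=int),
    )


def build_marrays(histories: list[CaptureHistory], n_occasions: int | None = None) -> MArraySet:
    """Tabulate histories into duckling and adult m-arrays.

    A duckling-marked bird contributes its initial release to the duckling
    array; once first recaptured it has recruited, and every subsequent
    release goes into the adult array.  Releases at the final occasion carry
    no information and are dropped (standard CJS conditioning).
    """
    if n_occasions is None:
        if not histories:
            raise ValueError("cannot infer occasion count from empty history list")
        n_occasions = histories[0].years.size
    duck = _empty_marray(n_occasions)
    adult = _empty_marray(n_occasions)

    for h in histories:
        det_occ = np.flatnonzero(h.detections)
        if h.cohort == "duckling":
            t0 = det_occ[0]
            if t0 < n_occasions - 1:
                duck.releases[t0] += 1
                if det_occ.size > 1:
                    duck.m[t0, det_occ[1]] += 1
                else:
                    duck.never[t0] += 1
            adult_occ = det_occ[1:]  # re-releases after recruitment
        else:
            adult_occ = det_occ
        for a, b in zip(adult_occ[:-1], adult_occ[1:]):
            adult.releases[a] += 1
            adult.m[a, b] += 1
        if adult_occ.size and adult_occ[-1] < n_occasions - 1:
            last = adult_occ[-1]
            adult.releases[last] += 1
            adult.never[last] += 1

    out = MArraySet(duckling=duck, adult=adult)
    out.validate()
    return out


def build_marray(histories: list[CaptureHistory], cohort: str, n_occasions: int | None = None) -> MArray:
    """The m-array component for one cohort (see :func:`build_marrays`)."""
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    ms = build_marrays(histories, n_occasions)
    return getattr(ms, cohort)


def adult_cell_probabilities(phi_a: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First-recapture cell probabilities for adult-marked releases.

    ``phi_a[k]`` is survival over interval k -> k+1; ``p[k]`` is recapture
    probability at occasion k+1 (both length ``n_occasions - 1``).  Returns
    ``(cells, never)`` with ``cells[t, j]`` the probability of release at t,
    first recapture at j, and ``never`` the complement per row.
    """
    phi_a = np.asarray(phi_a, dtype=float)
    p = np.asarray(p, dtype=float)
    if phi_a.shape != p.shape:
        raise ValueError("phi_a and p must have equal length")
    n_int = phi_a.size
    n_occ = n_int + 1
    cells = np.zeros((n_int, n_occ))
    for t in range(n_int):
        alive_undet = 1.0  # P(alive, not yet recaptured) just after release
        for j in range(t + 1, n_occ):
            cells[t, j] = alive_undet * phi_a[j - 1] * p[j - 1]
            alive_undet *= phi_a[j - 1] * (1.0 - p[j - 1])
    never = 1.0 - cells.sum(axis=1)
    return cells, never


def duckling_cell_probabilities(
    phi_j: np.ndarray, phi_a: np.ndarray, alpha: float, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First-recapture cell probabilities for duckling-marked releases.

    A duckling released at occasion t survives its first year with
    ``phi_j[t]`` (unobservable at t+1), then with ``phi_a[t+1]`` reaches age
    2 at t+2 where it breeds (and is detectable) with propensity ``alpha``.
    Non-breeding 2-year-olds are unobservable and breed with certainty at
    age 3; thereafter dynamics are the adult ones.
    """
    phi_j = np.asarray(phi_j, dtype=float)
    phi_a = np.asarray(phi_a, dtype=float)
    p = np.asarray(p, dtype=float)
    if not (phi_j.shape == phi_a.shape == p.shape):
        raise ValueError("phi_j, phi_a, p must have equal length")
    n_int = phi_j.size
    n_occ = n_int + 1
    cells = np.zeros((n_int, n_occ))
    for t in range(n_int):
        if t + 2 >= n_occ:
            continue  # first recapture impossible inside the study
        # reach age 2 (occasion t+2): detected only if breeding
        reach2 = phi_j[t] * phi_a[t + 1]
        cells[t, t + 2] = reach2 * alpha * p[t + 1]
        # undetected at age 2 (skipped breeding, or bred unseen); all breed
        # from age 3 on
        alive_undet = reach2 * (1.0 - alpha * p[t + 1])
        for j in range(t + 3, n_occ):
            cells[t, j] = alive_undet * phi_a[j - 1] * p[j - 1]
            alive_undet *= phi_a[j - 1] * (1.0 - p[j - 1])
    never = 1.0 - cells.sum(axis=1)
    return cells, never


def cmr_loglik(marray: MArray, cells: np.ndarray, never: np.ndarray) -> float:
    """Multinomial log-likelihood of one cohort's m-array.

    Computed as the product over individuals of their cell probabilities
    (i.e. the multinomial kernel; the data-constant combinatorial
    coefficient is omitted so the value equals the product of per-history
    likelihoods exactly).  A positive count on a zero-probability cell
    yields ``-inf``.
    """
    m = marray.m
    if cells.shape != m.shape:
        raise ValueError("cell probability matrix does not match m-array shape")
    total = 0.0
    with np.errstate(divide="ignore"):
        logc = np.where(m > 0, np.log(np.where(cells > 0, cells, np.nan)), 0.0)
        lognever = np.where(
            marray.never > 0, np.log(np.where(never > 0, never, np.nan)), 0.0
        )
    if np.any(np.isnan(logc)) or np.any(np.isnan(lognever)):
        logger.warning("positive m-array count on zero-probability cell")
        return float("-inf")
    total = float(np.sum(m * logc) + np.sum(marray.never * lognever))
    return total
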