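"""Shared fixtures: small synthetic bundles and independent CMR oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from eider_ipm.cmr import CaptureHistory
from eider_ipm.synthetic import TruthConfig, SimulatedBundle, simulate_bundle

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def small_bundle() -> SimulatedBundle:
    """A 10-year bundle with reduced sample sizes for fast smoke fits."""
    cfg = TruthConfig(
        t=10,
        duckling_releases=20,
        adult_releases=20,
        nests_per_year=30,
        missing_count_years=(1997,),
        seed=42,
    )
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def default_bundle() -> SimulatedBundle:
    """A bundle at the default (study-scale) configuration."""
    return simulate_bundle(TruthConfig(seed=42))


def make_history(cohort: str, detections: str, years=None) -> CaptureHistory:
    """Build a history from a compact 0/1 string like '1011'."""
    det = np.array([int(c) for c in detections])
    years = np.arange(2000, 2000 + det.size) if years is None else np.asarray(years)
    first = int(years[np.flatnonzero(det)[0]])
    return CaptureHistory(
        id=f"{cohort}-{detections}", cohort=cohort, first_year=first,
        years=years, detections=det,
    )


def forward_history_loglik(
    history: CaptureHistory, phi_j, phi_a, alpha, p
) -> float:
    """Exact per-history log-likelihood by forward summation over the
    discrete latent state space (duckling, 1-year-old, non-breeding
    2-year-old, breeder, dead), conditional on the initial release.

    Independent of the m-array code path: detection at occasion k uses
    ``p[k-1]``, survival over interval k -> k+1 uses ``phi_a[k]`` (or
    ``phi_j[k]`` for a duckling's first interval).
    """
    det = history.detections
    t_occ = det.size
    first = history.first_index
    # joint probability of the data so far and each latent state
    # states: 0=newly marked duckling, 1=age1, 2=nb2, 3=breeder, 4=dead
    prob = np.zeros(5)
    prob[0 if history.cohort == "duckling" else 3] = 1.0
    for occ in range(first + 1, t_occ):
        k = occ - 1  # interval index occ-1 -> occ
        new = np.zeros(5)
        # transitions
        new[4] = prob[4]
        if prob[0] > 0:  # duckling's first winter
            new[1] += prob[0] * phi_j[k]
            new[4] += prob[0] * (1.0 - phi_j[k])
        if prob[1] > 0:  # age 1 -> age 2, breed with propensity alpha
            new[2] += prob[1] * phi_a[k] * (1.0 - alpha)
            new[3] += prob[1] * phi_a[k] * alpha
            new[4] += prob[1] * (1.0 - phi_a[k])
        if prob[2] > 0:  # non-breeding 2-year-old recruits at 3
            new[3] += prob[2] * phi_a[k]
            new[4] += prob[2] * (1.0 - phi_a[k])
        if prob[3] > 0:
            new[3] += prob[3] * phi_a[k]
            new[4] += prob[3] * (1.0 - phi_a[k])
        # emission: only breeders can be detected
        if det[occ] == 1:
            like = new[3] * p[occ - 1]
            if like <= 0:
                return -np.inf
            prob = np.zeros(5)
            prob[3] = like
        else:
            new[3] *= 1.0 - p[occ - 1]
            prob = new
    total = prob.sum()
    return float(np.log(total)) if total > 0 else -np.inf


def enumerate_duckling_paths(phi_j, phi_a, alpha, p, release: int, n_occ: int):
    """Exhaustive path enumeration of first-recapture probabilities for a
    duckling released at ``release``: returns (cells, never) for that row.

    Walks every discrete state/detection sequence recursively.
    """
    cells = np.zeros(n_occ)
    never = 0.0

    def arrive(j, state, q):
        """Individual arrives at occasion j in `state`, not yet recaptured."""
        nonlocal never
        if q == 0.0 or state == "dead":
            never += q
            return
        if state == "breeder":
            cells[j] += q * p[j - 1]  # first detection at occasion j
            q = q * (1.0 - p[j - 1])
        if j == n_occ - 1:
            never += q
            return
        k = j  # interval j -> j+1
        if state == "duck":
            arrive(j + 1, "age1", q * phi_j[k])
            arrive(j + 1, "dead", q * (1.0 - phi_j[k]))
        elif state == "age1":
            arrive(j + 1, "nb2", q * phi_a[k] * (1.0 - alpha))
            arrive(j + 1, "breeder", q * phi_a[k] * alpha)
            arrive(j + 1, "dead", q * (1.0 - phi_a[k]))
        else:  # nb2 or undetected breeder: a breeder next year if it survives
            arrive(j + 1, "breeder", q * phi_a[k])
            arrive(j + 1, "dead", q * (1.0 - phi_a[k]))

    # the duckling is alive in its natal year at the release occasion
    arrive(release, "duck", 1.0)
    return cells, never
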