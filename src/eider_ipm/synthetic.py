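"""Synthetic data bundles generated from known parameters.

Emulates the four input streams of the integrated model — aerial count
index, individual capture histories, nest records, and environmental
series — under a fully known parameterization, so every pipeline stage
(readers, m-array builder, likelihoods, sampler) can be exercised and
parameter recovery can be verified end to end.

Winter sea-ice severity is generated as a latent AR(1) process mapped to a
daily concentration curve (smooth seasonal plateau plus autocorrelated
daily noise); the defaults put the per-winter extreme-ice-day counts on
the scale observed for the Bering Sea core wintering area (mean near 70,
spanning roughly 16-101 days).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import (
    AnnualCovariates,
    CovariateCoefficients,
    build_annual_covariates,
    inv_logit,
    linear_predictor_ns,
    linear_predictor_phiA,
    linear_predictor_phiJ,
)
from .cmr import CaptureHistory, build_marrays
from .model import CountData, IPMData
from .productivity import DUCKLING_SURVIVAL, NestYear, fecundity
from .projection import DemographicRates, StageVector, project_deterministic, project_stochastic

__all__ = ["TruthConfig", "SimulatedBundle", "simulate_covariates",
           "simulate_population", "simulate_counts", "simulate_cmr",
           "simulate_nests", "simulate_bundle", "write_bundle"]


def _logit(x: float) -> float:
    return float(np.log(x / (1.0 - x)))


@dataclass
class TruthConfig:
    """Full generative parameterization.

    Rate means are on the probability scale (converted to logit-scale
    intercepts internally); defaults follow the published posterior means
    with duckling survival fixed at 0.67.
    """

    t: int = 23
    start_year: int = 1992
    mean_phi_a: float = 0.878
    mean_phi_j: float = 0.290
    alpha: float = 0.359
    mean_ns: float = 0.778
    cs: float = 4.297
    mean_p: float = 0.6
    ds: float = DUCKLING_SURVIVAL
    sigma_phi_a: float = 0.77
    sigma_phi_j: float = 0.6
    sigma_ns: float = 0.80
    sigma_p: float = 0.5
    betas: CovariateCoefficients = field(
        default_factory=lambda: CovariateCoefficients(
            beta_phiA_lin=-0.132,
            beta_phiA_quad=-0.251,
            beta_phiJ_ao=0.201,
            beta_ns_lin=-0.026,
            beta_ns_quad=-0.455,
            beta_ns_fox=-0.169,
            beta_ns_precip=-0.032,
        )
    )
    n0: tuple[float, float, float, float] = (600.0, 100.0, 50.0, 1200.0)
    sigma_y: float = 250.0
    missing_count_years: tuple[int, ...] = (2011,)
    duckling_releases: int = 30
    adult_releases: int = 30
    nests_per_year: int = 60
    # winter severity generation
    ice_ar1_rho: float = 0.5
    ice_peak_mean: float = 0.975
    ice_peak_sd: float = 0.045
    ice_daily_noise_sd: float = 0.03
    ice_daily_noise_rho: float = 0.8
    stochastic_projection: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t < 3:
            raise ValueError("need at least three study years")
        for name in ("mean_phi_a", "mean_phi_j", "alpha", "mean_ns", "mean_p"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.t)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class SimulatedBundle:
    """All generated streams plus the underlying truth."""

    config: TruthConfig
    daily_ice: pd.DataFrame
    annual_indices: pd.DataFrame
    cov: AnnualCovariates
    rates: dict[str, np.ndarray]
    stages: np.ndarray
    counts: CountData
    histories: list[CaptureHistory]
    nests: list[NestYear]
    ice_days_truth: np.ndarray

    def to_ipm_data(self, use_covariates: bool = True) -> IPMData:
        return IPMData(
            years=self.config.years,
            counts=self.counts,
            marrays=build_marrays(self.histories, self.config.t),
            nests=self.nests,
            cov=self.cov if use_covariates else None,
            ds=self.config.ds,
        )


def _seasonal_profile(n_days: int) -> np.ndarray:
    """Ramp up, mid-winter plateau, ramp down (fractions 25/50/25)."""
    u = np.linspace(0.0, 1.0, n_days)
    f = np.minimum(1.0, np.minimum(u / 0.25, (1.0 - u) / 0.25))
    return f


def simulate_covariates(cfg: TruthConfig, rng: np.random.Generator):
    """Daily winter ice series plus raw annual AO/fox/precip indices.

    Returns (daily_ice DataFrame, annual_indices DataFrame, per-winter
    extreme-ice-day counts as internally booked by the generator).
    """
    frames = []
    internal_counts = np.zeros(cfg.t, dtype=int)
    sev = 0.0
    for i, year in enumerate(cfg.years):
        sev = cfg.ice_ar1_rho * sev + np.sqrt(1.0 - cfg.ice_ar1_rho**2) * rng.standard_normal()
        peak = cfg.ice_peak_mean + cfg.ice_peak_sd * sev
        dates = pd.date_range(f"{year - 1}-11-01", f"{year}-04-30", freq="D")
        profile = _seasonal_profile(len(dates))
        noise = np.empty(len(dates))
        e = rng.standard_normal() * cfg.ice_daily_noise_sd
        for d in range(len(dates)):
            e = cfg.ice_daily_noise_rho * e + np.sqrt(
                1.0 - cfg.ice_daily_noise_rho**2
            ) * rng.standard_normal() * cfg.ice_daily_noise_sd
            noise[d] = e
        conc = np.clip(peak * profile + noise, 0.0, 1.0)
        internal_counts[i] = int(np.sum(conc >= 0.95))
        frames.append(pd.DataFrame({"date": dates, "concentration": conc}))
    daily = pd.concat(frames, ignore_index=True)
    annual = pd.DataFrame(
        {
            "year": cfg.years,
            "ao": rng.standard_normal(cfg.t),
            "fox": rng.standard_normal(cfg.t),
            "precip": rng.standard_normal(cfg.t),
        }
    )
    return daily, annual, internal_counts


def _annual_rates(cfg: TruthConfig, cov: AnnualCovariates, rng: np.random.Generator):
    """Rate series from the truth's linear predictors and random effects."""
    t = cfg.t
    eps_a = rng.normal(0.0, cfg.sigma_phi_a, t - 1)
    eps_j = rng.normal(0.0, cfg.sigma_phi_j, t - 1)
    eps_ns = rng.normal(0.0, cfg.sigma_ns, t)
    eps_p = rng.normal(0.0, cfg.sigma_p, t - 1)
    phi_a = inv_logit(
        linear_predictor_phiA(_logit(cfg.mean_phi_a), eps_a, cov.ice_days[1:], cfg.betas)
    )
    phi_j = inv_logit(
        linear_predictor_phiJ(_logit(cfg.mean_phi_j), eps_j, cov.ao[1:], cfg.betas)
    )
    ns = inv_logit(
        linear_predictor_ns(
            _logit(cfg.mean_ns), eps_ns, cov.ice_days, cov.fox, cov.precip, cfg.betas
        )
    )
    p = inv_logit(_logit(cfg.mean_p) + eps_p)
    fec = fecundity(ns, cfg.cs, cfg.ds)
    return {
        "phi_a": phi_a, "phi_j": phi_j, "ns": ns, "p": p, "fec": fec,
        "eps_phi_a": eps_a, "eps_phi_j": eps_j, "eps_ns": eps_ns, "eps_p": eps_p,
    }


def simulate_population(
    cfg: TruthConfig, cov: AnnualCovariates, rng: np.random.Generator,
    max_redraws: int = 20,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Latent stage trajectory (T x 4) and the annual rates that drove it.

    Uses the demographically stochastic projection by default.  An
    extinct trajectory (any year with no breeders) is flagged and redrawn.
    """
    for _ in range(max_redraws):
        rates = _annual_rates(cfg, cov, rng)
        stages = np.empty((cfg.t, 4))
        sv = StageVector(int(cfg.years[0]), *np.round(cfg.n0))
        stages[0] = sv.as_array()
        for i in range(cfg.t - 1):
            r = DemographicRates(
                phi_j=rates["phi_j"][i],
                phi_a=rates["phi_a"][i],
                alpha=cfg.alpha,
                fec=rates["fec"][i],
            )
            sv = (
                project_stochastic(sv, r, rng)
                if cfg.stochastic_projection
                else project_deterministic(sv, r)
            )
            stages[i + 1] = sv.as_array()
        if np.all(stages[:, 2] + stages[:, 3] > 0):
            return stages, rates
    raise RuntimeError("population went extinct in every redraw attempt")


def simulate_counts(
    stages: np.ndarray, sigma_y, years: np.ndarray, rng: np.random.Generator,
    missing_years: tuple[int, ...] = (),
) -> CountData:
    """Normal survey index around breeding abundance, with missing years."""
    years = np.asarray(years, dtype=int)
    nbpop = 2.0 * (stages[:, 2] + stages[:, 3])
    sig = np.broadcast_to(np.asarray(sigma_y, dtype=float), nbpop.shape).copy()
    y = rng.normal(nbpop, sig)
    y[np.isin(years, missing_years)] = np.nan
    return CountData(years=years, y=y, sigma_y=sig)


def simulate_cmr(
    cfg: TruthConfig, rates: dict[str, np.ndarray], rng: np.random.Generator
) -> list[CaptureHistory]:
    """Individual-based capture histories for both marking cohorts.

    Each released female walks the life cycle under the same annual rates
    as the population process: ducklings survive their first interval with
    phi_j, recruit at age 2 with propensity alpha (age 3 with certainty),
    and breeders are detected with the annual recapture probability.
    """
    t = cfg.t
    phi_a, phi_j, p = rates["phi_a"], rates["phi_j"], rates["p"]
    histories: list[CaptureHistory] = []
    years = cfg.years
    counter = 0

    def walk_adult(first_occ: int, det: np.ndarray) -> None:
        """Detections of a breeder from its first occasion onward."""
        for occ in range(first_occ, t - 1):
            if rng.random() >= phi_a[occ]:
                return  # died during interval occ -> occ+1
            if rng.random() < p[occ]:  # p[occ] is recapture prob at occ+1
                det[occ + 1] = 1

    for rel in range(t - 1):
        for _ in range(cfg.adult_releases):
            det = np.zeros(t, dtype=int)
            det[rel] = 1
            walk_adult(rel, det)
            histories.append(
                CaptureHistory(
                    id=f"a{counter}", cohort="adult", first_year=int(years[rel]),
                    years=years, detections=det,
                )
            )
            counter += 1
        for _ in range(cfg.duckling_releases):
            det = np.zeros(t, dtype=int)
            det[rel] = 1
            alive = rng.random() < phi_j[rel]  # first interval: phi_j
            if alive and rel + 1 < t - 1:
                if rng.random() < phi_a[rel + 1]:  # age 1 -> age 2
                    # age 2 at occasion rel+2: breeds with propensity alpha
                    if rng.random() < cfg.alpha:
                        if rng.random() < p[rel + 1]:
                            det[rel + 2] = 1
                        walk_adult(rel + 2, det)
                    elif rel + 2 < t - 1 and rng.random() < phi_a[rel + 2]:
                        # non-breeding 2-year-old: recruits at age 3
                        if rng.random() < p[rel + 2]:
                            det[rel + 3] = 1
                        walk_adult(rel + 3, det)
            histories.append(
                CaptureHistory(
                    id=f"d{counter}", cohort="duckling", first_year=int(years[rel]),
                    years=years, detections=det,
                )
            )
            counter += 1
    return histories


def simulate_nests(
    cfg: TruthConfig, ns: np.ndarray, rng: np.random.Generator
) -> list[NestYear]:
    """Binomial nest success and Poisson clutches for successful nests."""
    out = []
    for i, year in enumerate(cfg.years):
        n_succ = int(rng.binomial(cfg.nests_per_year, ns[i]))
        clutches = tuple(int(c) for c in rng.poisson(cfg.cs, n_succ))
        out.append(
            NestYear(
                year=int(year), n_nests=cfg.nests_per_year,
                n_success=n_succ, clutch_sizes=clutches,
            )
        )
    return out


def simulate_bundle(cfg: TruthConfig | None = None, seed: int | None = None) -> SimulatedBundle:
    """Generate all four data streams under one truth."""
    cfg = cfg or TruthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    daily, annual, internal = simulate_covariates(cfg, rng)
    cov = build_annual_covariates(daily, annual, cfg.years)
    stages, rates = simulate_population(cfg, cov, rng)
    counts = simulate_counts(
        stages, cfg.sigma_y, cfg.years, rng, cfg.missing_count_years
    )
    histories = simulate_cmr(cfg, rates, rng)
    nests = simulate_nests(cfg, rates["ns"], rng)
    return SimulatedBundle(
        config=cfg, daily_ice=daily, annual_indices=annual, cov=cov,
        rates=rates, stages=stages, counts=counts, histories=histories,
        nests=nests, ice_days_truth=internal,
    )


def write_bundle(bundle: SimulatedBundle, directory, force: bool = False) -> dict[str, Path]:
    """Write the bundle's CSVs plus a truth-metadata JSON.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} is not empty (use force=True)")
    directory.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config

    paths = {}
    counts_df = pd.DataFrame(
        {
            "year": bundle.counts.years,
            "y": bundle.counts.y,
            "sigma_y": bundle.counts.sigma_y,
        }
    )
    paths["counts"] = directory / "counts.csv"
    counts_df.to_csv(paths["counts"], index=False)

    cap_rows = []
    for h in bundle.histories:
        row = {"id": h.id, "cohort": h.cohort, "first_year": h.first_year}
        row.update({str(y): int(d) for y, d in zip(h.years, h.detections)})
        cap_rows.append(row)
    paths["captures"] = directory / "captures.csv"
    pd.DataFrame(cap_rows).to_csv(paths["captures"], index=False)

    nest_df = pd.DataFrame(
        {
            "year": [n.year for n in bundle.nests],
            "n_nests": [n.n_nests for n in bundle.nests],
            "n_success": [n.n_success for n in bundle.nests],
            "clutch_sizes": [";".join(map(str, n.clutch_sizes)) for n in bundle.nests],
        }
    )
    paths["nests"] = directory / "nests.csv"
    nest_df.to_csv(paths["nests"], index=False)

    paths["daily_ice"] = directory / "daily_ice.csv"
    ice = bundle.daily_ice.copy()
    ice["date"] = ice["date"].dt.strftime("%Y-%m-%d")
    ice.to_csv(paths["daily_ice"], index=False)

    paths["annual_covariates"] = directory / "annual_covariates.csv"
    bundle.annual_indices.to_csv(paths["annual_covariates"], index=False)

    truth = {
        "config": cfg.to_jsonable(),
        "rates": {k: np.asarray(v).tolist() for k, v in bundle.rates.items()},
        "stages": bundle.stages.tolist(),
        "ice_days": bundle.ice_days_truth.tolist(),
        "seed": cfg.seed,
    }
    paths["truth"] = directory / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
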