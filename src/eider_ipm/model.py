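"""Joint model: data bundle, priors, parameter layout, and log posterior.

The integrated likelihood is the product of three components sharing
demographic parameters: a Normal state-space likelihood for the aerial
breeding-abundance index, a multinomial m-array likelihood for the
capture-recapture data, and binomial/Poisson likelihoods for nest success
and clutch size.  Annual rates are hierarchical on the logit scale with
optional covariate terms; latent stage abundances follow the deterministic
state equations given the annual rates and the initial stage vector.

This module holds the readable reference implementation; ``_fast`` holds a
numerically identical JIT-compiled path used by the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import cmr as cmr_mod
from . import productivity as prod_mod
from .cmr import MArraySet, adult_cell_probabilities, cmr_loglik, duckling_cell_probabilities
from .covariates import (
    AnnualCovariates,
    CovariateCoefficients,
    inv_logit,
    linear_predictor_ns,
    linear_predictor_phiA,
    linear_predictor_phiJ,
)
from .productivity import DUCKLING_SURVIVAL, NestYear, clutch_loglik, fecundity, nest_success_loglik
from .projection import StageVector, breeding_abundance

__all__ = [
    "PriorSet",
    "CountData",
    "IPMData",
    "ParamLayout",
    "count_loglik",
    "log_prior",
    "log_joint",
    "log_joint_components",
]


@dataclass(frozen=True)
class PriorSet:
    """Prior hyperparameters (Beta priors are on the mean probability scale)."""

    phi_a: tuple[float, float] = (5.5, 1.833)  # mean 0.750
    phi_j: tuple[float, float] = (2.5, 5.833)  # mean 0.300
    alpha: tuple[float, float] = (2.5, 5.833)  # mean 0.300
    p: tuple[float, float] = (5.056, 5.056)  # mean 0.500
    ns: tuple[float, float] = (5.922, 3.189)  # mean 0.650
    cs_gamma: tuple[float, float] = (0.1, 0.1)  # shape, rate
    sigma_bounds: tuple[float, float] = (0.001, 5.0)
    beta_sd: float = 10.0
    n0_bounds: tuple[tuple[float, float], ...] = (
        (300.0, 900.0),
        (10.0, 200.0),
        (10.0, 100.0),
        (500.0, 2000.0),
    )

    def beta_mean(self, name: str) -> float:
        a, b = getattr(self, name)
        return a / (a + b)


@dataclass
class CountData:
    """Annual breeding-abundance index with per-year observation SDs.

    Missing survey years carry ``y = nan`` (they drop out of the
    likelihood); ``sigma_y`` is an SD.
    """

    years: np.ndarray
    y: np.ndarray
    sigma_y: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        self.sigma_y = np.asarray(self.sigma_y, dtype=float)
        if not (self.years.size == self.y.size == self.sigma_y.size):
            raise ValueError("count arrays must have equal length")
        obs = ~np.isnan(self.y)
        if np.any(self.sigma_y[obs] <= 0):
            raise ValueError("observation SDs must be positive where y is present")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.y)


@dataclass
class IPMData:
    """Everything the joint likelihood needs, aligned to the study years."""

    years: np.ndarray
    counts: CountData
    marrays: MArraySet
    nests: list[NestYear]
    cov: AnnualCovariates | None = None
    ds: float = DUCKLING_SURVIVAL

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        t = self.years.size
        if t < 3:
            raise ValueError("need at least three study years")
        if not np.array_equal(self.counts.years, self.years):
            raise ValueError("count years must match study years")
        if len(self.nests) != t:
            raise ValueError("need one nest record per study year")
        if [n.year for n in self.nests] != list(self.years):
            raise ValueError("nest years must match study years")
        if self.marrays.adult.n_occasions != t:
            raise ValueError("m-array occasion count must match study years")
        if self.cov is not None and not np.array_equal(self.cov.years, self.years):
            raise ValueError("covariate years must match study years")

    @property
    def n_years(self) -> int:
        return int(self.years.size)


@dataclass(frozen=True)
class ParamLayout:
    """Index map of the flat sampling vector.

    Scalars: logit-mean rates (Beta prior with logit Jacobian), random-effect
    SDs, logit breeding propensity, log mean clutch size, seven covariate
    coefficients, four initial stages.  Vectors: annual logit-scale random
    effects for adult survival, first-year survival (both length T-1), nest
    success (length T), and recapture (length T-1).
    """

    n_years: int

    MU_A, SIG_A, MU_J, SIG_J, L_ALPHA, MU_NS, SIG_NS, MU_P, SIG_P, LOG_CS = range(10)
    BETAS = slice(10, 17)
    N0 = slice(17, 21)

    @property
    def eps_a(self) -> slice:
        return slice(21, 21 + self.n_years - 1)

    @property
    def eps_j(self) -> slice:
        s = self.eps_a.stop
        return slice(s, s + self.n_years - 1)

    @property
    def eps_ns(self) -> slice:
        s = self.eps_j.stop
        return slice(s, s + self.n_years)

    @property
    def eps_p(self) -> slice:
        s = self.eps_ns.stop
        return slice(s, s + self.n_years - 1)

    @property
    def n_params(self) -> int:
        return self.eps_p.stop

    def names(self) -> list[str]:
        base = [
            "mu_phi_a", "sigma_phi_a", "mu_phi_j", "sigma_phi_j", "logit_alpha",
            "mu_ns", "sigma_ns", "mu_p", "sigma_p", "log_cs",
            "beta_phiA_lin", "beta_phiA_quad", "beta_phiJ_ao",
            "beta_ns_lin", "beta_ns_quad", "beta_ns_fox", "beta_ns_precip",
            "n0_1", "n0_2", "n0_3", "n0_4",
        ]
        t = self.n_years
        base += [f"eps_phi_a[{i}]" for i in range(t - 1)]
        base += [f"eps_phi_j[{i}]" for i in range(t - 1)]
        base += [f"eps_ns[{i}]" for i in range(t)]
        base += [f"eps_p[{i}]" for i in range(t - 1)]
        return base


def annual_rates(theta: np.ndarray, data: IPMData, layout: ParamLayout):
    """Annual demographic rate series implied by a parameter vector.

    Covariate alignment: survival over interval t -> t+1 uses the winter
    ending in year t+1; nest success of season t uses the winter ending in
    year t; first-year survival uses the AO of its own winter.
    """
    t = data.n_years
    if data.cov is None:
        ice = ao = fox = precip = np.zeros(t)
    else:
        ice, ao = data.cov.ice_days, data.cov.ao
        fox, precip = data.cov.fox, data.cov.precip
    betas = CovariateCoefficients(*theta[layout.BETAS])
    phi_a = inv_logit(
        linear_predictor_phiA(theta[layout.MU_A], theta[layout.eps_a], ice[1:], betas)
    )
    phi_j = inv_logit(
        linear_predictor_phiJ(theta[layout.MU_J], theta[layout.eps_j], ao[1:], betas)
    )
    ns = inv_logit(
        linear_predictor_ns(
            theta[layout.MU_NS], theta[layout.eps_ns], ice, fox, precip, betas
        )
    )
    p = inv_logit(theta[layout.MU_P] + theta[layout.eps_p])
    alpha = float(inv_logit(theta[layout.L_ALPHA]))
    cs = float(np.exp(theta[layout.LOG_CS]))
    fec = fecundity(ns, cs, data.ds)
    return phi_a, phi_j, ns, p, alpha, cs, fec


def latent_stages(theta: np.ndarray, data: IPMData, layout: ParamLayout) -> np.ndarray:
    """Deterministic latent stage trajectory (T x 4) from rates and n0."""
    phi_a, phi_j, _, _, alpha, _, fec = annual_rates(theta, data, layout)
    t = data.n_years
    n = np.empty((t, 4))
    n[0] = theta[layout.N0]
    for i in range(t - 1):
        n[i + 1, 0] = 0.5 * fec[i] * phi_j[i] * (n[i, 2] + n[i, 3])
        n[i + 1, 1] = phi_a[i] * (1.0 - alpha) * n[i, 0]
        n[i + 1, 2] = phi_a[i] * alpha * n[i, 0]
        n[i + 1, 3] = phi_a[i] * (n[i, 1] + n[i, 2] + n[i, 3])
    return n


def count_loglik(stages, counts: CountData) -> float:
    """Normal log-likelihood of the survey index given latent stages.

    ``stages`` is a list of :class:`StageVector` or a (T, 4) array; missing
    survey years contribute nothing.
    """
    if isinstance(stages, np.ndarray):
        nbpop = 2.0 * (stages[:, 2] + stages[:, 3])
    else:
        nbpop = np.array([breeding_abundance(sv) for sv in stages])
    if nbpop.size != counts.years.size:
        raise ValueError("stages must cover all count years")
    obs = ~counts.missing
    return float(
        np.sum(stats.norm.logpdf(counts.y[obs], nbpop[obs], counts.sigma_y[obs]))
    )


def log_prior(theta: np.ndarray, layout: ParamLayout, priors: PriorSet = PriorSet()) -> float:
    """Log prior density of the flat parameter vector (with Jacobians for
    logit/log-transformed parameters)."""
    lp = 0.0
    for idx, name in ((layout.MU_A, "phi_a"), (layout.MU_J, "phi_j"),
                      (layout.L_ALPHA, "alpha"), (layout.MU_NS, "ns"),
                      (layout.MU_P, "p")):
        a, b = getattr(priors, name)
        m = float(inv_logit(theta[idx]))
        if not 0.0 < m < 1.0:
            return -np.inf
        lp += stats.beta.logpdf(m, a, b) + np.log(m * (1.0 - m))
    shape, rate = priors.cs_gamma
    cs = float(np.exp(theta[layout.LOG_CS]))
    lp += stats.gamma.logpdf(cs, shape, scale=1.0 / rate) + theta[layout.LOG_CS]
    lo, hi = priors.sigma_bounds
    sigmas = theta[[layout.SIG_A, layout.SIG_J, layout.SIG_NS, layout.SIG_P]]
    if np.any((sigmas < lo) | (sigmas > hi)):
        return -np.inf
    lp += -4.0 * np.log(hi - lo)
    lp += float(np.sum(stats.norm.logpdf(theta[layout.BETAS], 0.0, priors.beta_sd)))
    for val, (blo, bhi) in zip(theta[layout.N0], priors.n0_bounds):
        if not blo <= val <= bhi:
            return -np.inf
        lp += -np.log(bhi - blo)
    for eps_slc, sig_idx in ((layout.eps_a, layout.SIG_A), (layout.eps_j, layout.SIG_J),
                             (layout.eps_ns, layout.SIG_NS), (layout.eps_p, layout.SIG_P)):
        lp += float(np.sum(stats.norm.logpdf(theta[eps_slc], 0.0, theta[sig_idx])))
    return float(lp)


def log_joint_components(
    theta: np.ndarray, data: IPMData, layout: ParamLayout, priors: PriorSet = PriorSet()
) -> dict[str, float]:
    """Each additive term of the log posterior, for attribution and testing."""
    out = {"prior": log_prior(theta, layout, priors)}
    if not np.isfinite(out["prior"]):
        out.update(count=0.0, cmr=0.0, nest_success=0.0, clutch=0.0)
        return out
    phi_a, phi_j, ns, p, alpha, cs, _ = annual_rates(theta, data, layout)
    stages = latent_stages(theta, data, layout)
    out["count"] = count_loglik(stages, data.counts)
    ca, na = adult_cell_probabilities(phi_a, p)
    cd, nd = duckling_cell_probabilities(phi_j, phi_a, alpha, p)
    out["cmr"] = cmr_loglik(data.marrays.adult, ca, na) + cmr_loglik(
        data.marrays.duckling, cd, nd
    )
    out["nest_success"] = nest_success_loglik(data.nests, ns)
    out["clutch"] = clutch_loglik(data.nests, cs)
    return out


def log_joint(
    theta: np.ndarray, data: IPMData, layout: ParamLayout, priors: PriorSet = PriorSet()
) -> float:
    """Log posterior kernel: log prior plus the three data log-likelihoods."""
    return float(sum(log_joint_components(theta, data, layout, priors).values()))
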