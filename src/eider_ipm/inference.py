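"""Posterior sampling, convergence diagnostics, goodness of fit, and the
post-model derived statistics (growth rates, demographic-growth
correlations, variance explained by covariates).

The sampler is componentwise adaptive random-walk Metropolis over the
joint posterior (see ``_fast``); the latent stage trajectory is the
deterministic function of initial stages and annual rates, so only rates,
hyperparameters, and the initial stage vector are sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from . import _fast
from .covariates import inv_logit
from .model import IPMData, ParamLayout, PriorSet, log_joint
from .projection import geometric_mean_growth, lambda_series

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "PosteriorDraws",
    "FitReport",
    "fit",
    "rhat",
    "gof_freeman_tukey",
    "gof_chisq_counts",
    "variance_explained",
    "demographic_correlations",
    "posterior_mode",
    "summarize",
]


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings.

    Defaults are scaled down for desk-size runs; ``paper_protocol=True``
    switches to 3 chains x 900,000 iterations with 800,000 warm-up and
    thinning by 25 (12,000 kept draws).
    """

    chains: int = 3
    n_adapt: int = 3000
    n_keep: int = 1000
    thin: int = 2
    seed: int = 0
    use_covariates: bool = True
    paper_protocol: bool = False
    strict: bool = False
    init_step: float = 0.05
    rhat_threshold: float = 1.05

    def resolved(self) -> "FitConfig":
        if self.paper_protocol:
            return FitConfig(
                chains=3, n_adapt=800_000, n_keep=4000, thin=25, seed=self.seed,
                use_covariates=self.use_covariates, paper_protocol=True,
                strict=self.strict, init_step=self.init_step,
                rhat_threshold=self.rhat_threshold,
            )
        return self


class NonConvergenceError(RuntimeError):
    """Raised in strict mode when any R-hat exceeds the threshold."""


@dataclass
class PosteriorDraws:
    """MCMC draws of the flat parameter vector, by chain.

    ``theta`` has shape (chains, draws, n_params); use :meth:`param` for a
    named series and :meth:`derived` for annual rates and latent states.
    """

    theta: np.ndarray
    logpost: np.ndarray
    layout: ParamLayout
    data: IPMData
    config: FitConfig
    sampler_info: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def flat(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1])

    def param(self, name: str) -> np.ndarray:
        """Flattened draws of one named sampling parameter."""
        idx = self.layout.names().index(name)
        return self.flat()[:, idx]

    def derived(self) -> dict[str, np.ndarray]:
        """Per-draw annual rate series, latent stages, and growth rates.

        Returns arrays with a leading draw axis: ``phi_a``/``phi_j``/``p``
        (T-1), ``ns``/``fec`` (T), ``stages`` (T, 4), ``ntot``/``nbpop``
        (T), ``lambda_tot``/``lambda_bpop`` (T-1), scalars ``alpha``,
        ``cs``, ``geom_lambda_tot``, ``geom_lambda_bpop``.
        """
        th = self.flat()
        lay, data = self.layout, self.data
        t = data.n_years
        if data.cov is None:
            ice = ao = fox = precip = np.zeros(t)
        else:
            ice, ao = data.cov.ice_days, data.cov.ao
            fox, precip = data.cov.fox, data.cov.precip
        b = th[:, lay.BETAS]
        eps_a = th[:, lay.eps_a]
        eps_j = th[:, lay.eps_j]
        eps_ns = th[:, lay.eps_ns]
        eps_p = th[:, lay.eps_p]
        phi_a = inv_logit(
            th[:, [lay.MU_A]] + b[:, [0]] * ice[1:] + b[:, [1]] * ice[1:] ** 2 + eps_a
        )
        phi_j = inv_logit(th[:, [lay.MU_J]] + b[:, [2]] * ao[1:] + eps_j)
        ns = inv_logit(
            th[:, [lay.MU_NS]]
            + b[:, [3]] * ice
            + b[:, [4]] * ice**2
            + b[:, [5]] * fox
            + b[:, [6]] * precip
            + eps_ns
        )
        p = inv_logit(th[:, [lay.MU_P]] + eps_p)
        alpha = inv_logit(th[:, lay.L_ALPHA])
        cs = np.exp(th[:, lay.LOG_CS])
        fec = ns * cs[:, None] * data.ds
        ndraw = th.shape[0]
        stages = np.empty((ndraw, t, 4))
        stages[:, 0, :] = th[:, lay.N0]
        for i in range(t - 1):
            s = stages[:, i, :]
            stages[:, i + 1, 0] = 0.5 * fec[:, i] * phi_j[:, i] * (s[:, 2] + s[:, 3])
            stages[:, i + 1, 1] = phi_a[:, i] * (1.0 - alpha) * s[:, 0]
            stages[:, i + 1, 2] = phi_a[:, i] * alpha * s[:, 0]
            stages[:, i + 1, 3] = phi_a[:, i] * (s[:, 1] + s[:, 2] + s[:, 3])
        ntot = stages.sum(axis=2)
        nbpop = 2.0 * (stages[:, :, 2] + stages[:, :, 3])
        lam_tot = ntot[:, 1:] / ntot[:, :-1]
        lam_bpop = nbpop[:, 1:] / nbpop[:, :-1]
        return {
            "phi_a": phi_a, "phi_j": phi_j, "ns": ns, "p": p, "fec": fec,
            "alpha": alpha, "cs": cs, "stages": stages, "ntot": ntot,
            "nbpop": nbpop, "lambda_tot": lam_tot, "lambda_bpop": lam_bpop,
            "geom_lambda_tot": np.exp(np.mean(np.log(lam_tot), axis=1)),
            "geom_lambda_bpop": np.exp(np.mean(np.log(lam_bpop), axis=1)),
        }

    def rhat_all(self) -> dict[str, float]:
        """Gelman-Rubin statistic for every sampled (active) parameter."""
        names = self.layout.names()
        active = self.sampler_info.get("active", np.arange(self.theta.shape[-1]))
        return {names[i]: rhat(self.theta[:, :, i]) for i in active}

    def to_dataframe(self) -> pd.DataFrame:
        names = self.layout.names()
        rows = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.theta[c], columns=names)
            df.insert(0, "draw", np.arange(self.n_draws))
            df.insert(0, "chain", c)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _pack_data(data: IPMData, priors: PriorSet):
    """Primitive arrays for the JIT path."""
    t = data.n_years
    if data.cov is None:
        ice = ao = fox = precip = np.zeros(t)
    else:
        ice = np.asarray(data.cov.ice_days, dtype=float)
        ao = np.asarray(data.cov.ao, dtype=float)
        fox = np.asarray(data.cov.fox, dtype=float)
        precip = np.asarray(data.cov.precip, dtype=float)
    y = np.where(data.counts.missing, 0.0, data.counts.y)
    sig_y = np.where(data.counts.missing, 1.0, data.counts.sigma_y)
    y_obs = (~data.counts.missing).astype(np.bool_)
    ad, dk = data.marrays.adult, data.marrays.duckling
    clutches = np.array(
        [c for ny in data.nests for c in ny.clutch_sizes], dtype=float
    )
    clutch_lgam = float(np.sum(special.gammaln(clutches + 1.0))) if clutches.size else 0.0
    beta_priors = np.array(
        [priors.phi_a, priors.phi_j, priors.alpha, priors.ns, priors.p], dtype=float
    )
    return (
        t, ice, ao, fox, precip, y, sig_y, y_obs,
        ad.releases.astype(np.int64), ad.m.astype(np.int64), ad.never.astype(np.int64),
        dk.releases.astype(np.int64), dk.m.astype(np.int64), dk.never.astype(np.int64),
        np.array([ny.n_nests for ny in data.nests], dtype=np.int64),
        np.array([ny.n_success for ny in data.nests], dtype=np.int64),
        float(clutches.sum()), float(clutches.size), clutch_lgam,
        beta_priors, np.array(priors.cs_gamma, dtype=float),
        np.array(priors.sigma_bounds, dtype=float), float(priors.beta_sd),
        np.array(priors.n0_bounds, dtype=float), float(data.ds),
    )


def fast_log_joint(theta: np.ndarray, data: IPMData, priors: PriorSet = PriorSet()) -> float:
    """JIT-path log posterior (numerically identical to ``model.log_joint``)."""
    return float(_fast.logpost(np.asarray(theta, dtype=float), *_pack_data(data, priors)))


def _initial_theta(
    data: IPMData, layout: ParamLayout, priors: PriorSet, rng: np.random.Generator
) -> np.ndarray:
    """Moderately dispersed, data-informed starting point with finite density."""
    th = np.zeros(layout.n_params)
    th[layout.MU_A] = special.logit(0.85) + 0.3 * rng.standard_normal()
    th[layout.MU_J] = special.logit(0.30) + 0.3 * rng.standard_normal()
    th[layout.L_ALPHA] = special.logit(0.35) + 0.3 * rng.standard_normal()
    succ = sum(ny.n_success for ny in data.nests)
    tot = max(1, sum(ny.n_nests for ny in data.nests))
    th[layout.MU_NS] = special.logit(np.clip(succ / tot, 0.05, 0.95)) + 0.2 * rng.standard_normal()
    th[layout.MU_P] = special.logit(0.5) + 0.3 * rng.standard_normal()
    clutches = [c for ny in data.nests for c in ny.clutch_sizes]
    cs0 = np.mean(clutches) if clutches else 4.0
    th[layout.LOG_CS] = np.log(max(cs0, 0.5)) + 0.1 * rng.standard_normal()
    for idx in (layout.SIG_A, layout.SIG_J, layout.SIG_NS, layout.SIG_P):
        th[idx] = rng.uniform(0.2, 0.8)
    th[layout.BETAS] = 0.0
    for k, (lo, hi) in enumerate(priors.n0_bounds):
        th[layout.N0.start + k] = rng.uniform(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo))
    for slc in (layout.eps_a, layout.eps_j, layout.eps_ns, layout.eps_p):
        th[slc] = 0.05 * rng.standard_normal(slc.stop - slc.start)
    return th


def fit(
    data: IPMData,
    config: FitConfig = FitConfig(),
    priors: PriorSet = PriorSet(),
) -> PosteriorDraws:
    """Sample the joint posterior of the integrated model.

    With ``use_covariates=False`` the seven regression coefficients are
    pinned at zero (the temporal-variation model; it is exactly nested in
    the covariate model).  In strict mode, any R-hat above the threshold
    raises :class:`NonConvergenceError`.
    """
    config = config.resolved()
    layout = ParamLayout(data.n_years)
    packed = _pack_data(data, priors)
    active = np.arange(layout.n_params)
    if not config.use_covariates:
        active = np.setdiff1d(active, np.arange(layout.BETAS.start, layout.BETAS.stop))
    active = active.astype(np.int64)

    rng = np.random.default_rng(config.seed)
    thetas = np.empty((config.chains, config.n_keep, layout.n_params))
    lps = np.empty((config.chains, config.n_keep))
    rates = []
    for c in range(config.chains):
        th0 = _initial_theta(data, layout, priors, rng)
        if not config.use_covariates:
            th0[layout.BETAS] = 0.0
        chain_seed = int(rng.integers(1, 2**31 - 1))
        draws, lp, _, rate = _fast.run_chain(
            th0, active, config.n_adapt, config.n_keep, config.thin,
            chain_seed, config.init_step, *packed,
        )
        thetas[c], lps[c] = draws, lp
        rates.append(float(rate))

    post = PosteriorDraws(
        theta=thetas, logpost=lps, layout=layout, data=data, config=config,
        sampler_info={
            "sampler": "componentwise adaptive random-walk Metropolis (numba)",
            "latent_process": "deterministic state equations, continuous initial stages",
            "acceptance_rates": rates,
            "active": active,
            "seed": config.seed,
        },
    )
    rh = post.rhat_all()
    worst = max(rh.values())
    post.sampler_info["max_rhat"] = worst
    if worst > config.rhat_threshold:
        logger.warning("max R-hat %.3f exceeds %.2f", worst, config.rhat_threshold)
        if config.strict:
            raise NonConvergenceError(
                f"max R-hat {worst:.3f} > {config.rhat_threshold}"
            )
    return post


def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws) for one parameter.  Uses the classic
    between/within-variance formula with the n-1/n correction; values below
    1 arise only from finite-sample noise and are reported as 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("R-hat needs at least two chains")
    m, n = x.shape
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(max(1.0, np.sqrt(var_plus / w)))


def gof_freeman_tukey(
    post: PosteriorDraws, rng: np.random.Generator
) -> tuple[float, np.ndarray, np.ndarray]:
    """Posterior-predictive Freeman-Tukey check of the nest-success model.

    Per draw: D = sum_t (sqrt(successes_t) - sqrt(n_t * ns_t))^2 for the
    observed and a binomial replicate data set; the Bayesian p-value is the
    fraction of draws with D_rep >= D_obs.
    """
    ns = post.derived()["ns"]
    n_nests = np.array([ny.n_nests for ny in post.data.nests])
    n_succ = np.array([ny.n_success for ny in post.data.nests])
    expected = n_nests * ns
    d_obs = np.sum((np.sqrt(n_succ) - np.sqrt(expected)) ** 2, axis=1)
    rep = rng.binomial(n_nests, ns)
    d_rep = np.sum((np.sqrt(rep) - np.sqrt(expected)) ** 2, axis=1)
    return float(np.mean(d_rep >= d_obs)), d_obs, d_rep


def gof_chisq_counts(
    post: PosteriorDraws, rng: np.random.Generator
) -> tuple[float, np.ndarray, np.ndarray]:
    """Posterior-predictive chi-square check of the count model.

    Missing survey years are excluded from both observed and replicate
    discrepancies.
    """
    nbpop = post.derived()["nbpop"]
    counts = post.data.counts
    obs = ~counts.missing
    mu = nbpop[:, obs]
    sig = counts.sigma_y[obs]
    x2_obs = np.sum((counts.y[obs] - mu) ** 2 / sig**2, axis=1)
    rep = rng.normal(mu, sig)
    x2_rep = np.sum((rep - mu) ** 2 / sig**2, axis=1)
    return float(np.mean(x2_rep >= x2_obs)), x2_obs, x2_rep


def variance_explained(sigma2_total: float, sigma2_resid: float) -> float:
    """Proportion of temporal variance explained by covariates:
    V = (sigma2_total - sigma2_resid) / sigma2_total."""
    if sigma2_total <= 0 or sigma2_resid <= 0:
        raise ValueError("variances must be positive")
    v = (sigma2_total - sigma2_resid) / sigma2_total
    if v < 0:
        logger.warning("negative variance explained (%.3f): residual > total", v)
    return float(v)


def posterior_mode(draws: np.ndarray) -> float:
    """KDE argmax (Silverman bandwidth) of a posterior sample."""
    draws = np.asarray(draws, dtype=float)
    if np.ptp(draws) == 0:
        return float(draws[0])
    kde = stats.gaussian_kde(draws, bw_method="silverman")
    grid = np.linspace(draws.min(), draws.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def demographic_correlations(post: PosteriorDraws) -> pd.DataFrame:
    """Posterior correlation of each annual rate with total-female growth.

    For each draw, the Pearson correlation across years between the rate
    series (adult survival, first-year survival, nest success, fecundity)
    and lambda_t of total females; summarized by posterior mode, mean,
    95% CrI, and p(r > 0).  Draws with a degenerate (constant) series are
    skipped and counted.
    """
    der = post.derived()
    lam = der["lambda_tot"]
    if lam.shape[1] < 2 or post.data.n_years < 3:
        raise ValueError("need at least three years for correlations")
    rows = []
    for name in ("phi_a", "phi_j", "ns", "fec"):
        series = der[name][:, : lam.shape[1]]
        sx = series.std(axis=1)
        sy = lam.std(axis=1)
        ok = (sx > 0) & (sy > 0)
        n_skipped = int((~ok).sum())
        if n_skipped:
            logger.info("%s: skipped %d degenerate draws", name, n_skipped)
        xs = series[ok] - series[ok].mean(axis=1, keepdims=True)
        ys = lam[ok] - lam[ok].mean(axis=1, keepdims=True)
        r = np.sum(xs * ys, axis=1) / np.sqrt(
            np.sum(xs**2, axis=1) * np.sum(ys**2, axis=1)
        )
        lo, hi = np.percentile(r, [2.5, 97.5])
        rows.append(
            {
                "rate": name,
                "r_mode": posterior_mode(r),
                "r_mean": float(r.mean()),
                "r_median": float(np.median(r)),
                "cri_lo": float(lo),
                "cri_hi": float(hi),
                "p_r_positive": float(np.mean(r > 0)),
                "n_draws": int(r.size),
                "n_skipped": n_skipped,
            }
        )
    return pd.DataFrame(rows)


ESTIMANDS = {
    "adult_survival": lambda d, p: inv_logit(p.param("mu_phi_a")),
    "juvenile_survival": lambda d, p: inv_logit(p.param("mu_phi_j")),
    "breeding_propensity": lambda d, p: d["alpha"],
    "nest_success": lambda d, p: inv_logit(p.param("mu_ns")),
    "clutch_size": lambda d, p: d["cs"],
    "geometric_lambda_bpop": lambda d, p: d["geom_lambda_bpop"],
    "geometric_lambda_tot": lambda d, p: d["geom_lambda_tot"],
}


@dataclass
class FitReport:
    """Posterior summaries, convergence diagnostics, and sampler metadata."""

    estimates: pd.DataFrame
    rhat: dict[str, float]
    sampler_info: dict

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.to_dict(orient="records"),
            "rhat": self.rhat,
            "sampler_info": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.sampler_info.items()
            },
        }


def summarize(post: PosteriorDraws) -> FitReport:
    """Table-style report: mean/median/mode and 95% CrI per estimand,
    every sampled hyperparameter, and R-hat for all sampled parameters."""
    der = post.derived()
    rows = []

    def add(name: str, draws: np.ndarray) -> None:
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(draws)),
                "median": float(np.median(draws)),
                "mode": posterior_mode(draws),
                "cri_lo": float(lo),
                "cri_hi": float(hi),
            }
        )

    for name, fn in ESTIMANDS.items():
        add(name, fn(der, post))
    flat = post.flat()
    for i, name in enumerate(post.layout.names()):
        if name.startswith("eps_"):
            continue
        add(name, flat[:, i])
    return FitReport(
        estimates=pd.DataFrame(rows),
        rhat=post.rhat_all(),
        sampler_info=dict(post.sampler_info),
    )
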