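"""Environmental covariates: winter sea-ice severity and annual indices.

The wintering period is fixed to November 1 - April 30.  Severity is the
number of "extreme ice days" (daily sea-ice concentration >= 95% over the
core wintering area) in that window; days < 15% cover index extreme low
ice.  Covariates are z-standardized before entering logit-scale linear
predictors: a quadratic in ice days for adult survival and nest success,
the winter Arctic Oscillation for first-year survival, and fox sign and
June-August precipitation for nest success.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnnualCovariates",
    "CovariateCoefficients",
    "read_daily_ice",
    "read_annual_indices",
    "ice_days",
    "low_ice_days",
    "zstandardize",
    "build_annual_covariates",
    "linear_predictor_phiA",
    "linear_predictor_phiJ",
    "linear_predictor_ns",
    "inv_logit",
]

ICE_THRESHOLD_HIGH = 0.95
ICE_THRESHOLD_LOW = 0.15


def inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class CovariateCoefficients:
    """Logit-scale regression coefficients for the demographic rates."""

    beta_phiA_lin: float = 0.0
    beta_phiA_quad: float = 0.0
    beta_phiJ_ao: float = 0.0
    beta_ns_lin: float = 0.0
    beta_ns_quad: float = 0.0
    beta_ns_fox: float = 0.0
    beta_ns_precip: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.beta_phiA_lin,
                self.beta_phiA_quad,
                self.beta_phiJ_ao,
                self.beta_ns_lin,
                self.beta_ns_quad,
                self.beta_ns_fox,
                self.beta_ns_precip,
            ]
        )


@dataclass
class AnnualCovariates:
    """Standardized annual covariates indexed by study year.

    ``ice_days`` for a year refers to the winter ending April 30 of that
    year.  A masked year (supplementary sensitivity refit) is excluded from
    standardization and its standardized value set to 0 (the mean).
    """

    years: np.ndarray
    ice_days_raw: np.ndarray
    ice_days: np.ndarray
    ao: np.ndarray
    fox: np.ndarray
    precip: np.ndarray
    masked_years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.years)
        for name in ("ice_days_raw", "ice_days", "ao", "fox", "precip"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match years")


def read_daily_ice(path_or_df) -> pd.DataFrame:
    """Read the daily-ice CSV (date, concentration in [0, 1])."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    if not {"date", "concentration"}.issubset(df.columns):
        raise ValueError("daily ice CSV must have columns date, concentration")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)
    c = df["concentration"].to_numpy(dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("ice concentrations must lie in [0, 1]")
    if df["date"].duplicated().any():
        raise ValueError("duplicate dates in daily ice series")
    return df


def read_annual_indices(path_or_df) -> pd.DataFrame:
    """Read the annual-index CSV (year, ao, fox, precip; raw units)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    if not {"year", "ao", "fox", "precip"}.issubset(df.columns):
        raise ValueError("annual covariate CSV must have columns year, ao, fox, precip")
    return df.sort_values("year").reset_index(drop=True)


def _winter_window(winter: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    return pd.Timestamp(winter - 1, 11, 1), pd.Timestamp(winter, 4, 30)


def _winter_concentrations(series: pd.DataFrame, winter: int) -> np.ndarray:
    start, end = _winter_window(winter)
    sel = series[(series["date"] >= start) & (series["date"] <= end)]
    expected = pd.date_range(start, end, freq="D")
    if len(sel) != len(expected):
        missing = expected.difference(pd.DatetimeIndex(sel["date"]))
        raise ValueError(
            f"winter {winter}: missing {len(missing)} daily ice values "
            f"(first gaps: {[str(d.date()) for d in missing[:5]]})"
        )
    return sel["concentration"].to_numpy(dtype=float)


def ice_days(series: pd.DataFrame, winter: int, threshold: float = ICE_THRESHOLD_HIGH) -> int:
    """Extreme-ice days (concentration >= threshold) in the Nov 1 - Apr 30
    window of the winter ending in calendar year ``winter``."""
    conc = _winter_concentrations(series, winter)
    return int(np.sum(conc >= threshold))


def low_ice_days(series: pd.DataFrame, winter: int, threshold: float = ICE_THRESHOLD_LOW) -> int:
    """Days with concentration below ``threshold`` in the same window."""
    conc = _winter_concentrations(series, winter)
    return int(np.sum(conc < threshold))


def zstandardize(x, mask=None) -> np.ndarray:
    """(x - mean) / sd over unmasked entries (sample sd, n-1 denominator).

    ``mask`` marks entries to EXCLUDE from the mean/sd; masked entries are
    set to 0 in the output (i.e. the mean).
    """
    x = np.asarray(x, dtype=float)
    keep = np.ones(x.shape, dtype=bool) if mask is None else ~np.asarray(mask, dtype=bool)
    if keep.sum() < 2:
        raise ValueError("need at least two unmasked values to standardize")
    mu = x[keep].mean()
    sd = x[keep].std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant series")
    z = (x - mu) / sd
    z[~keep] = 0.0
    return z


def build_annual_covariates(
    daily_ice: pd.DataFrame,
    annual: pd.DataFrame,
    years: np.ndarray,
    masked_years: tuple[int, ...] = (),
    threshold: float = ICE_THRESHOLD_HIGH,
) -> AnnualCovariates:
    """Assemble standardized covariates for the study years.

    The raw ice-day count for each study year comes from the winter ending
    in that year; AO/fox/precip rows are matched by year.
    """
    years = np.asarray(years, dtype=int)
    annual = annual.set_index("year")
    missing = [y for y in years if y not in annual.index]
    if missing:
        raise ValueError(f"annual covariate CSV lacks years {missing}")
    raw_ice = np.array([ice_days(daily_ice, int(y), threshold) for y in years])
    mask = np.isin(years, masked_years)
    return AnnualCovariates(
        years=years,
        ice_days_raw=raw_ice,
        ice_days=zstandardize(raw_ice, mask),
        ao=zstandardize(annual.loc[years, "ao"].to_numpy(), mask),
        fox=zstandardize(annual.loc[years, "fox"].to_numpy(), mask),
        precip=zstandardize(annual.loc[years, "precip"].to_numpy(), mask),
        masked_years=tuple(masked_years),
    )


def linear_predictor_phiA(mu, eps, ice, betas: CovariateCoefficients):
    """Logit adult survival: mu + b_lin*ice + b_quad*ice^2 + eps."""
    ice = np.asarray(ice, dtype=float)
    return mu + betas.beta_phiA_lin * ice + betas.beta_phiA_quad * ice**2 + eps


def linear_predictor_phiJ(mu, eps, ao, betas: CovariateCoefficients):
    """Logit first-year survival: mu + b_ao*ao + eps."""
    return mu + betas.beta_phiJ_ao * np.asarray(ao, dtype=float) + eps


def linear_predictor_ns(mu, eps, ice, fox, precip, betas: CovariateCoefficients):
    """Logit nest success: quadratic ice plus linear fox and precipitation."""
    ice = np.asarray(ice, dtype=float)
    return (
        mu
        + betas.beta_ns_lin * ice
        + betas.beta_ns_quad * ice**2
        + betas.beta_ns_fox * np.asarray(fox, dtype=float)
        + betas.beta_ns_precip * np.asarray(precip, dtype=float)
        + eps
    )
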