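"""Reading data bundles from disk and assembling the model's data object.

CSV dialects: UTF-8, comma separators, header row required, ISO dates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cmr import build_marrays, read_capture_histories
from .covariates import ICE_THRESHOLD_HIGH, build_annual_covariates, read_annual_indices, read_daily_ice
from .model import CountData, IPMData
from .productivity import read_nest_data

__all__ = ["read_counts", "load_bundle"]


def read_counts(path_or_df) -> CountData:
    """Read the count CSV (year, y, sigma_y); empty/NaN y marks a missing
    survey year."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    if not {"year", "y", "sigma_y"}.issubset(df.columns):
        raise ValueError("count CSV must have columns year, y, sigma_y")
    df = df.sort_values("year").reset_index(drop=True)
    return CountData(
        years=df["year"].to_numpy(dtype=int),
        y=df["y"].to_numpy(dtype=float),
        sigma_y=df["sigma_y"].to_numpy(dtype=float),
    )


def load_bundle(
    directory,
    use_covariates: bool = True,
    masked_years: tuple[int, ...] = (),
    ice_threshold: float = ICE_THRESHOLD_HIGH,
) -> IPMData:
    """Assemble an :class:`IPMData` from a bundle directory.

    Expects counts.csv, captures.csv, nests.csv and (when covariates are
    used) daily_ice.csv and annual_covariates.csv, as written by
    :func:`eider_ipm.synthetic.write_bundle`.
    """
    directory = Path(directory)
    counts = read_counts(directory / "counts.csv")
    histories = read_capture_histories(directory / "captures.csv")
    nests = read_nest_data(directory / "nests.csv")
    years = counts.years
    cov = None
    if use_covariates:
        daily = read_daily_ice(directory / "daily_ice.csv")
        annual = read_annual_indices(directory / "annual_covariates.csv")
        cov = build_annual_covariates(
            daily, annual, years, masked_years=masked_years, threshold=ice_threshold
        )
    return IPMData(
        years=years,
        counts=counts,
        marrays=build_marrays(histories, len(years)),
        nests=nests,
        cov=cov,
    )
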