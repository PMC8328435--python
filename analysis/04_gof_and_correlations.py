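"""Goodness of fit and demographic contributions to population growth.

Refits the covariate model (same seed as 02_fit.py, hence identical
draws), computes posterior-predictive Bayesian p-values for the nest and
count models, and correlates each annual demographic rate with
total-female population growth across the posterior.
"""

import json
from pathlib import Path

import numpy as np

from eider_ipm.inference import (
    FitConfig,
    demographic_correlations,
    fit,
    gof_chisq_counts,
    gof_freeman_tukey,
)
from eider_ipm.io import load_bundle

ROOT = Path(__file__).resolve().parents[1] / "results"
CONFIG = FitConfig(n_adapt=5000, n_keep=1500, thin=2, seed=11)
GOF_SEED = 13


def main() -> None:
    post = fit(load_bundle(ROOT / "bundle"), CONFIG)

    rng = np.random.default_rng(GOF_SEED)
    p_ft, _, _ = gof_freeman_tukey(post, rng)
    p_x2, _, _ = gof_chisq_counts(post, rng)
    print(f"Bayesian p-value, nest success (Freeman-Tukey): {p_ft:.3f}")
    print(f"Bayesian p-value, counts (chi-square):          {p_x2:.3f}")

    corr = demographic_correlations(post)
    print("\ncorrelation of annual rates with total-female growth:")
    for _, row in corr.iterrows():
        print(
            f"  {row['rate']:6s} r_mode {row.r_mode:+.2f} "
            f"({row.cri_lo:+.2f}, {row.cri_hi:+.2f})  p(r>0) {row.p_r_positive:.2f}"
        )

    (ROOT / "gof.json").write_text(
        json.dumps(
            {"freeman_tukey_nest_success": p_ft, "chisq_counts": p_x2}, indent=1
        )
    )
    corr.to_csv(ROOT / "growth_correlations.csv", index=False)
    print(f"\nwritten to {ROOT}/gof.json and {ROOT}/growth_correlations.csv")


if __name__ == "__main__":
    main()
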