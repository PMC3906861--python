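"""Derive the genetic parameters from the fitted models.

Reads the fit state written by 02_fit_models.py and computes, for both
models, the total heritable variance σ²_TBV, the phenotypic variance σ²_P,
T² = σ²_TBV/σ²_P, h², the direct–social genetic correlation, and the
percentage partition of σ²_TBV (direct / covariance / social), with
delta-method standard errors. Writes results/03_derived_parameters.csv.

Run:  python analysis/03_derived_parameters.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from codsge import derive
from codsge.reml import COMPONENTS, ModelFit, VarianceComponents

ROOT = Path(__file__).resolve().parents[1]


def rebuild(model: str, record: dict) -> ModelFit:
    return ModelFit(
        model=model,
        vc=VarianceComponents(**record["vc"]),
        beta=np.zeros(1),
        x_labels=["intercept"],
        loglik=record["loglik"],
        cov=np.asarray(record["cov"]),
        converged=True,
        n_iter=0,
        boundary=record["boundary"],
        n_obs=0,
    )


def main() -> None:
    state = json.loads((ROOT / "results" / "02_fit_state.json").read_text())
    rows = []
    for model in ("conventional", "social"):
        dp = derive(rebuild(model, state[model]), n=21)
        rows.append(
            {
                "model": model,
                "sigma2_TBV": dp.sigma2_TBV, "se_TBV": dp.se_sigma2_TBV,
                "sigma2_P": dp.sigma2_P, "se_P": dp.se_sigma2_P,
                "T2": dp.T2, "se_T2": dp.se_T2,
                "h2": dp.h2, "se_h2": dp.se_h2,
                "r_AS_AD": dp.r_AS_AD, "se_r": dp.se_r_AS_AD,
                "share_direct_pct": dp.shares[0] if dp.shares else np.nan,
                "share_cov_pct": dp.shares[1] if dp.shares else np.nan,
                "share_social_pct": dp.shares[2] if dp.shares else np.nan,
            }
        )
    df = pd.DataFrame(rows).round(4)
    out = ROOT / "results" / "03_derived_parameters.csv"
    df.to_csv(out, index=False)
    print(df.to_string(index=False))
    soc = rows[1]
    print(
        f"\nsocial model: {soc['share_direct_pct']:.1f}% direct, "
        f"{soc['share_cov_pct']:.1f}% covariance, "
        f"{soc['share_social_pct']:.1f}% social share of sigma2_TBV"
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
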