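"""Fit the conventional and social animal models to the simulated dataset.

Reads the CSVs written by 01_simulate_experiment.py, estimates all variance
components by sparse REML for both models, and writes per-model component
tables (estimate, SE, boundary flag) plus the fit state (components and
sampling covariance, for step 03) under results/.

Run:  python analysis/02_fit_models.py
"""

import argparse
import json
from pathlib import Path

from codsge import (
    build_A_inverse,
    build_groups,
    build_matrices,
    fit,
    fit_report,
    lrt,
    read_pedigree,
    read_phenotypes,
)
from codsge.reml import COMPONENTS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "scratch" / "data")
    ap.add_argument("--trait", default="finD1")
    ap.add_argument("--recording", type=int, default=3)
    args = ap.parse_args()

    ped = read_pedigree(args.data / "pedigree.csv")
    table = read_phenotypes(args.data / "phenotypes.csv")
    groups = build_groups(table)
    Ainv = build_A_inverse(ped)
    print(f"{len(table)} fish, pedigree of {len(ped)}, {len(groups.tanks)} tanks")

    state = {}
    fits = {}
    for model in ("conventional", "social"):
        mm = build_matrices(table, groups, ped, args.trait, args.recording, model)
        f = fit(mm, Ainv, model)
        fits[model] = f
        report = fit_report(f, n=21)
        out = ROOT / "results" / f"02_fit_{model}.csv"
        report.to_csv(out, index=False)
        print(f"\n{model} model: logL = {f.loglik:.2f} "
              f"({'converged' if f.converged else 'NOT converged'}, {f.n_iter} iterations)")
        print(report.to_string(index=False))
        state[model] = {
            "loglik": f.loglik,
            "vc": {c: getattr(f.vc, c) for c in COMPONENTS},
            "cov": f.cov.tolist(),
            "boundary": f.boundary,
        }

    test = lrt(fits["conventional"], fits["social"])
    print(f"\nLRT social vs conventional: delta logL = {test.delta_logl:.2f}, "
          f"chi2 = {test.chi2:.2f} (df = {test.df}), p = {test.p:.3g}")
    state["lrt"] = {"delta_logl": test.delta_logl, "chi2": test.chi2,
                    "df": test.df, "p": test.p}
    (ROOT / "results" / "02_fit_state.json").write_text(json.dumps(state, indent=2))


if __name__ == "__main__":
    main()
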