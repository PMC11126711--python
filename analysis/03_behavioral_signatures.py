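#!/usr/bin/env python
"""Model-agnostic behavioral battery on the simulated cohort, by group.

Per subject: post-reversal learning curve, observational-vs-experiential
choice propensity, and the behavioral arbitration index.  Cohort-wise:
mixed-effects logistic regressions of choice on the previous outcome
(experiential signature) and the partner's action (observational
signature), overall and split by uncertainty trial type.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from learnarb.io import read_sessions
from learnarb.signatures import (build_glm_design, fit_me_glm, label_trials,
                                 signature_report)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/cohort"))
    ap.add_argument("--fits", type=Path, default=Path("results/fits"))
    ap.add_argument("--out", type=Path, default=Path("results/signatures"))
    args = ap.parse_args()

    sessions = read_sessions(args.data / "sessions")
    groups = pd.read_csv(args.fits / "comparison.csv",
                         index_col="subject_id")["group"]

    args.out.mkdir(parents=True, exist_ok=True)
    report = signature_report(sessions)
    report["group"] = groups.reindex(report["subject_id"]).to_numpy()
    report.to_csv(args.out / "signature_report.csv", index=False)

    print("per-group behavioral signatures (means):")
    curve_cols = [c for c in report.columns if c.startswith("curve_")]
    summary = report.groupby("group")[
        ["ol_propensity", "arbitration_index", *curve_cols]].mean()
    summary["curve_slope"] = summary["curve_8"] - summary["curve_1"]
    print(summary[["ol_propensity", "arbitration_index",
                   "curve_1", "curve_8", "curve_slope"]].round(3).to_string())
    summary.to_csv(args.out / "group_summary.csv")

    for scheme in ("main", "by_ol_unc", "by_el_unc", "by_mag"):
        design = pd.concat([build_glm_design(s, label_trials(s), scheme)
                            for s in sessions], ignore_index=True)
        res = fit_me_glm(design)
        eff = pd.DataFrame({"estimate": res.fixed_effects,
                            "se": res.fixed_se})
        eff.to_csv(args.out / f"glm_{scheme}_fixed.csv")
        res.random_effects.to_csv(args.out / f"glm_{scheme}_random.csv")
        print(f"\nmixed-effects GLM ({scheme}, {res.method}):")
        print(eff.round(3).to_string())


if __name__ == "__main__":
    main()
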