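#!/usr/bin/env python
"""Fit all five strategy models to the simulated cohort and classify.

Per subject x model: MAP parameters, negative log likelihood, Laplace log
evidence, AIC, and (optionally) leave-one-block-out predictive accuracy.
Cohort level: random-effects model frequencies, per-subject
responsibilities, exceedance probabilities, and the argmax-responsibility
group label, summarized in a model-fit table alongside classification
accuracy against the generating models.
"""

import argparse
from pathlib import Path

import pandas as pd

from learnarb.fitting import FitConfig, cohort_compare, fit_cohort
from learnarb.io import read_sessions
from learnarb.models import MODEL_ORDER, get_model


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=12)
    ap.add_argument("--data", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/fits"))
    ap.add_argument("--with-oos", action="store_true",
                    help="also compute leave-one-block-out accuracy (slow)")
    args = ap.parse_args()

    sessions = read_sessions(args.data / "sessions")
    truth = pd.read_csv(args.data / "ground_truth.csv",
                        index_col="subject_id")
    for s in sessions:
        s.true_model = truth.loc[s.subject_id, "true_model"]

    fits = fit_cohort(sessions, models=MODEL_ORDER, config=FitConfig(),
                      seed=args.seed, with_oos=args.with_oos)
    args.out.mkdir(parents=True, exist_ok=True)
    fits.to_csv(args.out / "fits.csv", index=False)

    lme = fits.pivot(index="subject_id", columns="model",
                     values="log_evidence")[MODEL_ORDER]
    comp = cohort_compare(lme, seed=args.seed)
    table = pd.DataFrame({
        "n_par": {m: get_model(m).k for m in MODEL_ORDER},
        "mean_aic": fits.groupby("model")["aic"].mean(),
        "mean_oos_acc": fits.groupby("model")["oos_accuracy"].mean(),
        "frequency": comp.frequencies,
        "n_best": comp.groups.value_counts().reindex(MODEL_ORDER).fillna(0),
    }).loc[MODEL_ORDER]
    table.to_csv(args.out / "model_table.csv")

    resp = comp.responsibilities.copy()
    resp["group"] = comp.groups
    resp["true_model"] = truth["true_model"]
    resp.to_csv(args.out / "comparison.csv")
    pd.DataFrame({"frequency": comp.frequencies,
                  "exceedance": comp.exceedance}).to_csv(args.out / "bms.csv")

    correct = (comp.groups == truth["true_model"]).mean()
    print("model-fit summary:")
    print(table.round(3).to_string())
    print(f"\nclassification vs generating model: {correct:.2%} correct")


if __name__ == "__main__":
    main()
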