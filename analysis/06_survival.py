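"""Evaluate module prognostic value and the Cox risk score.

Screens every detected module by clustering patients on its expression and
log-rank-testing the resulting groups; fits a multivariate Cox model on
the best module's members; scores patients with RiskScore = sum r_i Exp_i;
dichotomizes at the training-cohort median; and evaluates survival
separation, time-dependent AUC, Table-1-style Cox models and age/grade
stratification.

Usage: python analysis/06_survival.py [--data results/data] [--run results/run]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from icenet.cpm import CliqueCommunity
from icenet.survival import (
    dichotomize,
    fit_cox,
    logrank_test,
    risk_score,
    screen_modules_for_prognosis,
    split_train_test,
    stratified_km,
    time_dependent_roc_auc,
)
from icenet.pipeline import COX_PENALIZER, _cox_table
from icenet.synthetic import read_fixture_bundle


def load_modules(path: Path) -> list[CliqueCommunity]:
    df = pd.read_csv(path, sep="\t")
    return [
        CliqueCommunity(
            k=int(r.k),
            members=frozenset(r.members.split(",")),
            clique_count=int(r.clique_count),
        )
        for r in df.itertuples()
    ]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--run", type=Path, default=Path("results/run"))
    ap.add_argument("--cutoff", choices=("median", "mean"), default="median")
    args = ap.parse_args()

    bundle = read_fixture_bundle(args.data)
    expr, clinical = bundle["expression"], bundle["clinical"]
    seed = bundle["config"].seed
    modules = load_modules(args.run / "modules.tsv")

    screen = screen_modules_for_prognosis(modules, expr, clinical)
    screen.to_csv(args.run / "module_screen.tsv", sep="\t", index=False,
                  float_format="%.17g")
    best = modules[int(screen["module_index"].iloc[0])]
    members = sorted(best.members)
    print(f"screened {len(screen)} modules; best (k={best.k}): {members}")
    print(f"  clustering log-rank p = {screen['p_value'].iloc[0]:.3g}")

    covars = clinical.join(expr.loc[members].T)
    cox = fit_cox(covars, members, penalizer=COX_PENALIZER)
    cox.summary_frame().to_csv(args.run / "cox_model.tsv", sep="\t",
                               float_format="%.17g")
    scores = risk_score(expr, cox)

    train_ids, test_ids = split_train_test(clinical, seed=seed)
    train = dichotomize(scores.loc[train_ids], cutoff_kind=args.cutoff)
    test = dichotomize(scores.loc[test_ids], cutoff_value=train.cutoff)
    entire = dichotomize(scores, cutoff_kind=args.cutoff)

    summary = {}
    for name, res in (("training", train), ("test", test), ("entire", entire)):
        clin = clinical.loc[res.scores.index]
        hi = res.scores.index[res.groups == "high"]
        lo = res.scores.index[res.groups == "low"]
        chi2, p = logrank_test(
            (clin.loc[hi, "dfs_months"], clin.loc[hi, "event"]),
            (clin.loc[lo, "dfs_months"], clin.loc[lo, "event"]),
        )
        auc = time_dependent_roc_auc(res.scores, clin)
        _cox_table(res, clin).to_csv(args.run / f"cox_table_{name}.tsv", sep="\t",
                                     float_format="%.17g")
        summary[name] = {
            "n": int(len(clin)), "n_high": int(len(hi)), "n_low": int(len(lo)),
            "cutoff": float(res.cutoff), "logrank_chi2": chi2, "logrank_p": p,
            "auc": auc,
        }
        print(f"{name}: n={len(clin)} ({len(hi)} high / {len(lo)} low), "
              f"cutoff {res.cutoff:.3f}, log-rank p={p:.3g}, AUC={auc:.3f}")

    risk_table = pd.DataFrame({"score": scores, "group": entire.groups})
    risk_table.to_csv(args.run / "risk_table.tsv", sep="\t", float_format="%.17g")

    strata = {
        "age": stratified_km(entire.groups, clinical, stratum="age_threshold"),
        "grade": stratified_km(entire.groups, clinical, stratum="grade"),
    }
    strat_summary = {}
    for family, rep in strata.items():
        for name, s in rep.items():
            strat_summary[name] = {
                k: v for k, v in s.items() if not isinstance(v, pd.DataFrame)
            }
            if s["evaluable"]:
                print(f"stratum {name}: n={s['n']}, log-rank p={s['p_value']:.3g}")
            else:
                print(f"stratum {name}: not evaluable")
    (args.run / "survival_summary.json").write_text(
        json.dumps({"datasets": summary, "strata": strat_summary}, indent=2)
    )


if __name__ == "__main__":
    main()
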