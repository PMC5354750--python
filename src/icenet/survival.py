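"""Survival analysis of candidate prognostic modules.

Implements the evaluation chain: unsupervised clustering of patients on
module expression, Kaplan-Meier curves with two-sided log-rank tests,
Cox proportional-hazards fits (Efron ties), the linear risk score
RiskScore = sum_i r_i * Exp(i) with median (or mean) dichotomization,
a random train/test split, cumulative/dynamic time-dependent ROC AUC with
Kaplan-Meier censoring weights, and stratification by age and grade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# patient clustering


def hierarchical_cluster_patients(
    expr_module: pd.DataFrame, n_clusters: int = 3, min_group: int = 5
):
    """Agglomerative clustering of patients on module expression.

    Each molecule is standardized across patients (as in a scaled
    expression heatmap) and patients are clustered by Euclidean distance
    with Ward linkage, the tree cut into ``n_clusters``.  Ward linkage is
    used because it favours compact, balanced groups; average linkage
    tends to peel off singleton outliers when the module signal is one
    dominant continuous factor.  Standardized
    Euclidean distance is used rather than correlation distance because
    patient-profile correlation is invariant to a shift common to all
    module members -- exactly the signal a co-expression module carries.
    Returns ``(labels, removed)`` where ``labels`` maps sample id ->
    cluster id (1-based) and ``removed`` is the set of cluster ids smaller
    than ``min_group`` to exclude from survival comparison.
    """
    if expr_module.shape[0] < 2:
        raise ValueError("need at least 2 molecules to cluster patients")
    if expr_module.shape[1] < n_clusters:
        raise ValueError("fewer patients than clusters")
    X = expr_module.to_numpy(dtype=float)  # molecules x patients
    sds = X.std(axis=1)
    if (sds == 0).any():
        bad = [expr_module.index[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant molecule expression, cannot standardize: {bad}")
    Xs = (X - X.mean(axis=1, keepdims=True)) / sds[:, None]
    Z = linkage(Xs.T, method="ward", metric="euclidean")
    lab = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = pd.Series(lab, index=expr_module.columns, name="cluster")
    sizes = labels.value_counts()
    removed = {int(c) for c, s in sizes.items() if s < min_group}
    return labels, removed


# ---------------------------------------------------------------------------
# KM / log-rank


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate; returns (time, survival) step points."""
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(group_a, group_b):
    """Two-sided log-rank test between two (times, events) groups.

    Returns (chi_square, p_value) with 1 degree of freedom.
    """
    ta, ea = (np.asarray(v, dtype=float) for v in group_a)
    tb, eb = (np.asarray(v, dtype=float) for v in group_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must have at least one subject")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox model and risk score


@dataclass
class CoxRiskModel:
    molecules: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    mode: str

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "HR_ci_low": self.ci_low,
                "HR_ci_high": self.ci_high,
                "p": self.p_values,
            },
            index=pd.Index(self.molecules, name="variable"),
        )


def fit_cox(
    clinical: pd.DataFrame,
    covariates: list[str],
    mode: str = "multivariate",
    duration_col: str = "dfs_months",
    event_col: str = "event",
    ties: str = "efron",
    penalizer: float = 0.0,
) -> CoxRiskModel:
    """Cox proportional-hazards fit with Wald 95% CIs.

    ``mode="multivariate"`` fits all covariates jointly; ``"univariate"``
    fits one model per covariate and collects the rows.  Ties are handled
    by the Efron approximation by default ("breslow" optional).  A small
    ridge ``penalizer`` stabilises fits on strongly co-expressed
    (near-collinear) module members.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    if clinical[clinical[event_col] == 1][duration_col].nunique() < 2:
        raise ValueError("need at least 2 distinct event times")
    for c in covariates:
        if clinical[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant: non-identifiable")

    def _one_fit(cols: list[str]) -> pd.DataFrame:
        cph = CoxPHFitter(penalizer=penalizer)
        try:
            cph.fit(
                clinical[[duration_col, event_col] + cols],
                duration_col=duration_col,
                event_col=event_col,
            )
        except Exception as err:  # lifelines raises ConvergenceError subclasses
            raise RuntimeError(
                f"Cox fit failed for covariates {cols}: {err}"
            ) from err
        return cph.summary

    if mode == "multivariate":
        summaries = [_one_fit(list(covariates))]
    else:
        summaries = [_one_fit([c]) for c in covariates]
    s = pd.concat(summaries)
    return CoxRiskModel(
        molecules=list(s.index),
        coefficients=s["coef"].to_numpy(),
        hazard_ratios=s["exp(coef)"].to_numpy(),
        ci_low=s["exp(coef) lower 95%"].to_numpy(),
        ci_high=s["exp(coef) upper 95%"].to_numpy(),
        p_values=s["p"].to_numpy(),
        mode=mode,
    )


def risk_score(expr_module: pd.DataFrame, model: CoxRiskModel) -> pd.Series:
    """Linear risk score per patient: sum_i r_i * Exp(i, patient)."""
    missing = [m for m in model.molecules if m not in expr_module.index]
    if missing:
        raise KeyError(f"molecules absent from expression: {missing}")
    X = expr_module.loc[model.molecules].to_numpy(dtype=float)
    scores = model.coefficients @ X
    return pd.Series(scores, index=expr_module.columns, name="risk_score")


@dataclass
class RiskScoreResult:
    scores: pd.Series
    groups: pd.Series  # "high" / "low"
    cutoff: float
    cutoff_kind: str


def dichotomize(
    scores: pd.Series, cutoff_kind: str = "median", cutoff_value: float | None = None
) -> RiskScoreResult:
    """Split patients into high (> cutoff) and low (<= cutoff) risk groups.

    The cutoff is the median (default) or mean of the supplied scores; a
    training-set cutoff can be reused on a test set via ``cutoff_value``.
    Ties at the cutoff go to the low-risk group.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 patients")
    if scores.nunique() == 1 and cutoff_value is None:
        raise ValueError("degenerate dichotomization: all scores identical")
    if cutoff_value is not None:
        cutoff = float(cutoff_value)
    elif cutoff_kind == "median":
        cutoff = float(scores.median())
    elif cutoff_kind == "mean":
        cutoff = float(scores.mean())
    else:
        raise ValueError(f"cutoff_kind must be 'median' or 'mean', got {cutoff_kind!r}")
    groups = pd.Series(
        np.where(scores.to_numpy() > cutoff, "high", "low"),
        index=scores.index,
        name="risk_group",
    )
    return RiskScoreResult(
        scores=scores, groups=groups, cutoff=cutoff, cutoff_kind=cutoff_kind
    )


def split_train_test(clinical: pd.DataFrame, seed: int):
    """Uniform random partition into floor(n/2) training and ceil(n/2) test ids."""
    ids = list(clinical.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = len(ids) // 2
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


# ---------------------------------------------------------------------------
# time-dependent ROC


def time_dependent_roc_auc(
    scores: pd.Series,
    clinical: pd.DataFrame,
    eval_time: float | None = None,
    duration_col: str = "dfs_months",
    event_col: str = "event",
) -> float:
    """Cumulative-case / dynamic-control AUC at ``eval_time``.

    Censoring is handled by inverse-probability-of-censoring weights from
    the Kaplan-Meier estimate of the censoring distribution.  The default
    evaluation time is the median observed follow-up.
    """
    clin = clinical.loc[scores.index]
    t = clin[duration_col].to_numpy(dtype=float)
    e = clin[event_col].to_numpy(dtype=bool)
    if eval_time is None:
        eval_time = float(np.median(t))
    if not (e & (t <= eval_time)).any():
        raise ValueError(f"no events observed before eval_time={eval_time}")
    if not (t > eval_time).any():
        raise ValueError(f"no subjects at risk beyond eval_time={eval_time}")
    surv = Surv.from_arrays(event=e, time=t)
    auc, _ = cumulative_dynamic_auc(
        surv, surv, scores.to_numpy(dtype=float), [eval_time]
    )
    return float(auc[0])


# ---------------------------------------------------------------------------
# module screen and stratified analysis


def screen_modules_for_prognosis(
    modules,
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    min_group: int = 5,
    n_clusters: int = 3,
    duration_col: str = "dfs_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Log-rank screen of candidate modules, ranked by p ascending.

    Each module's member expression drives an unsupervised patient
    clustering; clusters smaller than ``min_group`` are removed; the
    remaining groups are compared by (multivariate) log-rank test.
    """
    if not modules:
        raise ValueError("no modules supplied")
    rows = []
    for idx, mod in enumerate(modules):
        members = sorted(set(mod.members) & set(expr.index))
        if len(members) < 2:
            logger.warning("module %d: <2 members in expression; skipped", idx)
            continue
        labels, removed = hierarchical_cluster_patients(
            expr.loc[members, clinical.index], n_clusters=n_clusters,
            min_group=min_group,
        )
        keep = labels[~labels.isin(removed)]
        if keep.nunique() < 2:
            logger.warning("module %d: <2 usable patient groups; skipped", idx)
            continue
        clin = clinical.loc[keep.index]
        res = multivariate_logrank_test(
            clin[duration_col], keep, clin[event_col]
        )
        rows.append(
            {
                "module_index": idx,
                "k": mod.k,
                "n_members": len(mod.members),
                "n_members_in_expr": len(members),
                "n_groups": int(keep.nunique()),
                "n_patients_used": int(len(keep)),
                "chi_square": float(res.test_statistic),
                "p_value": float(res.p_value),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["p_value", "module_index"]).reset_index(drop=True)
    return out


def stratified_km(
    groups: pd.Series,
    clinical: pd.DataFrame,
    stratum: str = "age_threshold",
    age_threshold: float = 60.0,
    duration_col: str = "dfs_months",
    event_col: str = "event",
) -> dict:
    """Per-stratum KM curves and log-rank tests between risk groups.

    ``stratum="age_threshold"`` splits patients at ``age_threshold`` years;
    ``stratum="grade"`` uses the grade column levels.  A stratum missing a
    risk group is reported as not evaluable.
    """
    clin = clinical.loc[groups.index]
    if stratum == "age_threshold":
        strata = {
            f"age<{age_threshold:g}": clin["age"] < age_threshold,
            f"age>={age_threshold:g}": clin["age"] >= age_threshold,
        }
    elif stratum == "grade":
        levels = sorted(clin["grade"].unique())
        if len(levels) == 1:
            logger.warning("grade is constant: single stratum")
        strata = {f"grade={g}": clin["grade"] == g for g in levels}
    else:
        raise ValueError(f"unknown stratum {stratum!r}")

    report = {}
    for name, mask in strata.items():
        ids = clin.index[mask]
        g = groups.loc[ids]
        if g.nunique() < 2:
            report[name] = {"evaluable": False, "n": int(mask.sum())}
            continue
        hi = ids[g == "high"]
        lo = ids[g == "low"]
        chi2, p = logrank_test(
            (clin.loc[hi, duration_col], clin.loc[hi, event_col]),
            (clin.loc[lo, duration_col], clin.loc[lo, event_col]),
        )
        report[name] = {
            "evaluable": True,
            "n": int(mask.sum()),
            "n_high": int(len(hi)),
            "n_low": int(len(lo)),
            "chi_square": chi2,
            "p_value": p,
            "km_high": km_estimate(clin.loc[hi, duration_col], clin.loc[hi, event_col]),
            "km_low": km_estimate(clin.loc[lo, duration_col], clin.loc[lo, event_col]),
        }
    return report
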