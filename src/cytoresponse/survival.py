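"""Survival analysis: nested leave-one-out Lasso-Cox feature selection,
median-split Kaplan-Meier / log-rank stratification, multivariable Cox with
a time-dependent transplant covariate, Fisher exact tests, and
Benjamini-Hochberg adjustment.

The feature-selection design follows the small-cohort protocol: with n
patients, every 1-patient subset serves as a test sample (outer loop), every
1-patient subset of the remainder as a validation sample (inner loop picking
the penalty by cross-validated partial likelihood), and the final model is
refit on all patients at the penalty chosen by the inner criterion on the
full cohort.  Per selected feature we report the log hazard ratio per
standard deviation and Wald p from an *unpenalized* Cox refit on the
selected set (the penalized point estimates are biased toward zero), plus a
Benjamini-Hochberg adjusted p across the refit features.  Raw univariate
Cox p-values are also emitted for reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError
from .lassocox import (
    breslow_loglik,
    fit_lasso_cox,
    lambda_max,
    loo_cv_partial_loglik,
    select_lambda_1se,
)

HORIZON_DAYS = {"2y": 730.0, "5y": 1826.0}


def apply_horizon(time, event, horizon):
    """Administrative censoring at a horizon ('2y', '5y' or days)."""
    h = HORIZON_DAYS.get(horizon, None)
    if h is None:
        h = float(horizon)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time < 0):
        raise ValidationError("survival times must be >= 0")
    capped = np.minimum(time, h)
    ev = np.where(time <= h, event, 0)
    return capped, ev


# ---------------------------------------------------------------------------
# Nested LOOCV Lasso-Cox selection
# ---------------------------------------------------------------------------

@dataclass
class PenalizedCoxResult:
    lambdas: np.ndarray
    chosen_lambda: float
    selected_features: list
    coefficients: pd.Series          # penalized, per-SD, at chosen lambda
    selection_frequency: pd.Series   # per feature, over outer folds
    refit: pd.DataFrame              # log_hr, se, p, p_adj per selected feature
    univariate_p: pd.Series          # raw univariate Cox p per selected feature
    n_folds: int
    n_folds_skipped: int


def _unpenalized_refit(Xs: pd.DataFrame, time, event) -> pd.DataFrame:
    """Wald table from an unpenalized Cox fit on z-scored features."""
    df = Xs.copy()
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(df, duration_col="time", event_col="event")
    out = pd.DataFrame(
        {
            "log_hr": cph.params_,
            "se": cph.standard_errors_,
            "p": cph.summary["p"],
        }
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def _univariate_p(Xs: pd.DataFrame, time, event) -> pd.Series:
    ps = {}
    for col in Xs.columns:
        df = Xs[[col]].copy()
        df["time"] = time
        df["event"] = event
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        ps[col] = float(cph.summary.loc[col, "p"])
    return pd.Series(ps)


def nested_loocv_select(
    X: pd.DataFrame,
    time,
    event,
    lambdas=None,
    n_lambdas: int = 15,
    lambda_min_ratio: float = 0.1,
    tol: float = 1e-6,
    rule: str = "1se",
    seed: int = 0,
) -> PenalizedCoxResult:
    """Nested leave-one-out Lasso-Cox feature selection (deterministic).

    Outer folds leave one patient out; the inner leave-one-out on the
    remainder picks the penalty by the cross-validated partial likelihood;
    per-fold selected features are tallied into selection frequencies.  The
    final model is refit on all patients at the penalty chosen by the inner
    criterion on the full cohort.

    ``rule`` picks the penalty from the inner CV curve: '1se' (default)
    takes the largest penalty within one standard error of the best value —
    the standard sparser choice for feature selection — while 'min' takes
    the best value itself.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    n = len(X)
    if n < 10:
        raise ValidationError(f"nested LOOCV needs n >= 10 patients, got {n}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    Xv = X.to_numpy(dtype=float)
    if lambdas is None:
        lmax = lambda_max(Xv, time, event)
        lambdas = lmax * np.logspace(0.0, np.log10(lambda_min_ratio), n_lambdas)
    lambdas = np.asarray(lambdas, dtype=float)

    sel_counts = np.zeros(X.shape[1])
    skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if event[mask].sum() < 2:
            skipped += 1
            warnings.warn(f"outer fold {i}: fewer than 2 events in training, skipped")
            continue
        cvpl, folds, _ = loo_cv_partial_loglik(Xv[mask], time[mask], event[mask], lambdas, tol=tol)
        li = select_lambda_1se(cvpl, folds) if rule == "1se" else int(np.argmax(cvpl))
        path = fit_lasso_cox(Xv[mask], time[mask], event[mask], lambdas=lambdas, tol=tol)
        sel_counts[path.nonzero(li)] += 1
    n_used = n - skipped
    sel_freq = pd.Series(sel_counts / max(n_used, 1), index=X.columns)

    cvpl_full, folds_full, _ = loo_cv_partial_loglik(Xv, time, event, lambdas, tol=tol)
    li_star = (
        select_lambda_1se(cvpl_full, folds_full)
        if rule == "1se"
        else int(np.argmax(cvpl_full))
    )
    path = fit_lasso_cox(Xv, time, event, lambdas=lambdas, tol=tol, feature_names=X.columns)
    chosen = float(lambdas[li_star])
    nz = path.nonzero(li_star)
    selected = [X.columns[j] for j in nz]
    coef = pd.Series(path.coefs[li_star][nz], index=selected)

    if selected:
        Xs = (X[selected] - X[selected].mean()) / X[selected].std(ddof=0).replace(0, 1)
        refit = _unpenalized_refit(Xs, time, event)
        uni = _univariate_p(Xs, time, event)
    else:
        refit = pd.DataFrame(columns=["log_hr", "se", "p", "p_adj"])
        uni = pd.Series(dtype=float)
    return PenalizedCoxResult(
        lambdas=lambdas,
        chosen_lambda=chosen,
        selected_features=selected,
        coefficients=coef,
        selection_frequency=sel_freq.sort_values(ascending=False),
        refit=refit,
        univariate_p=uni,
        n_folds=n,
        n_folds_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Median split, Kaplan-Meier, log-rank
# ---------------------------------------------------------------------------

def median_split(values) -> np.ndarray:
    """Label patients 'low' (value <= median) or 'high' (value > median).

    With even n and distinct values the split is exactly equal."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValidationError("median split needs at least 2 patients")
    if np.all(v == v[0]):
        raise ValidationError("degenerate split: all values identical")
    med = np.median(v)
    return np.where(v <= med, "low", "high")


def km_estimate(time, event, groups, group_order=None) -> dict:
    """Product-limit survival estimate per group.

    Returns group -> DataFrame(time, survival, at_risk) step functions with
    S(0) = 1; censored subjects leave the risk set after their time.
    ``group_order`` optionally names the expected groups; a named group with
    no members is an error."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    out = {}
    for g in group_order if group_order is not None else pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValidationError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        sf = kmf.survival_function_
        ev = kmf.event_table
        out[g] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": ev["at_risk"].reindex(sf.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out


@dataclass
class KMLogRankResult:
    chi2: float
    p: float
    hazard_ratio: float          # (O1/E1) / (O2/E2), group order as given
    hr_ci: tuple
    groups: tuple
    group_sizes: dict
    observed: dict
    expected: dict
    curves: dict = field(default_factory=dict)


def logrank_test(time, event, groups, group_order=None) -> KMLogRankResult:
    """Mantel-Cox log-rank test with the O/E hazard-ratio summary.

    The chi-square statistic accumulates observed minus expected events in
    group 1 over the distinct event times; HR = (O1/E1)/(O2/E2) with the
    log-rank confidence interval exp(log HR +/- 1.96 * sqrt(1/E1 + 1/E2)).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = list(group_order) if group_order is not None else list(pd.unique(groups))
    if len(labels) != 2:
        raise ValidationError(f"log-rank test requires exactly 2 groups, got {labels}")
    g1 = groups == labels[0]
    g2 = groups == labels[1]
    if not g1.any() or not g2.any():
        raise ValidationError("both groups must be non-empty")
    if event.sum() == 0:
        raise ValidationError("no events in the data")
    O1 = E1 = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    O_tot = float(event.sum())
    O2 = O_tot - O1
    E2 = O_tot - E1
    chi2 = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    if E1 > 0 and E2 > 0 and O2 > 0:
        hr = (O1 / E1) / (O2 / E2)
    else:
        hr = np.inf if O2 == 0 and O1 > 0 else np.nan
    half = 1.96 * np.sqrt(1.0 / E1 + 1.0 / E2) if E1 > 0 and E2 > 0 else np.nan
    ci = (
        (float(hr * np.exp(-half)), float(hr * np.exp(half)))
        if np.isfinite(hr) and hr > 0
        else (np.nan, np.nan)
    )
    return KMLogRankResult(
        chi2=float(chi2),
        p=p,
        hazard_ratio=float(hr),
        hr_ci=ci,
        groups=tuple(labels),
        group_sizes={labels[0]: int(g1.sum()), labels[1]: int(g2.sum())},
        observed={labels[0]: float(O1), labels[1]: float(O2)},
        expected={labels[0]: float(E1), labels[1]: float(E2)},
        curves=km_estimate(time, event, groups),
    )


# ---------------------------------------------------------------------------
# Multivariable Cox with a time-dependent transplant covariate
# ---------------------------------------------------------------------------

def episode_split(surv: pd.DataFrame, transplant_col: str = "transplant_day") -> pd.DataFrame:
    """Counting-process episode splitting at the transplant day.

    Each patient contributes one episode (0, t] with covariate 0 if never
    transplanted, or two episodes (0, tx] / (tx, t] with covariate 0 / 1.
    Total follow-up time is conserved exactly.
    """
    rows = []
    for r in surv.itertuples(index=False):
        tx = getattr(r, transplant_col, None)
        t = float(r.time)
        if tx is None or (isinstance(tx, float) and np.isnan(tx)):
            rows.append((r.patient_id, 0.0, t, int(r.event), 0))
            continue
        tx = float(tx)
        if tx >= t:
            raise ValidationError(
                f"patient {r.patient_id}: transplant day {tx} is not before "
                f"the observed time {t}"
            )
        if tx < 0:
            raise ValidationError(f"patient {r.patient_id}: negative transplant day")
        rows.append((r.patient_id, 0.0, tx, 0, 0))
        rows.append((r.patient_id, tx, t, int(r.event), 1))
    return pd.DataFrame(rows, columns=["patient_id", "start", "stop", "event", "transplant"])


def fit_cox_td(
    surv: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    transplant_col: str = "transplant_day",
):
    """Multivariable Cox with transplant as a time-dependent covariate.

    ``surv`` needs patient_id, time, event and optionally a transplant-day
    column; ``covariates`` is patient_id-indexed fixed covariates.  Constant
    covariates are inestimable and reported as dropped.  Returns (summary
    DataFrame with log_hr and p per covariate, dropped column list).
    """
    long = episode_split(surv, transplant_col)
    if covariates is not None:
        cov = covariates.copy()
        if "patient_id" in cov.columns:
            cov = cov.set_index("patient_id")
        long = long.join(cov, on="patient_id")
    dropped = []
    for col in long.columns:
        if col in ("patient_id", "start", "stop", "event"):
            continue
        if long[col].nunique() <= 1:
            dropped.append(col)
            long = long.drop(columns=col)
    ctv = CoxTimeVaryingFitter()
    ctv.fit(long, id_col="patient_id", start_col="start", stop_col="stop", event_col="event")
    summary = pd.DataFrame({"log_hr": ctv.params_, "p": ctv.summary["p"]})
    return summary, dropped


# ---------------------------------------------------------------------------
# Fisher exact and multiplicity adjustment
# ---------------------------------------------------------------------------

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all tables (with the observed margins) no more probable than the
    observed one, with relative tolerance 1e-7 on the comparison."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValidationError("table entries must be non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
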