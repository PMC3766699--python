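"""Univariate Cox proportional-hazards screening and Kaplan-Meier curves.

The screen fits one Cox model per miRNA covariate, assuming a linear
functional form, and controls the family-wise error across the screened list
with Bonferroni's adjustment.  The partial likelihood uses Breslow tie
handling by default (Efron available); the Newton iteration starts at zero
and flags monotone likelihood (a diverging coefficient) instead of reporting
a spurious estimate.  Kaplan-Meier curves are drawn after dichotomizing the
covariate at its median (ties to "low"), via lifelines' product-limit
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io_formats import SurvivalRecord

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class SurvivalFit:
    covariate_name: str
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    p_adjusted: float | None
    n: int
    n_events: int
    converged: bool


def _extract(records: list[SurvivalRecord], covariate_name: str):
    times, events, x = [], [], []
    for rec in records:
        if covariate_name not in rec.covariates:
            raise KeyError(f"record {rec.patient_id} lacks covariate {covariate_name!r}")
        times.append(rec.time)
        events.append(rec.event)
        x.append(float(rec.covariates[covariate_name]))
    return np.asarray(times), np.asarray(events, dtype=bool), np.asarray(x)


def cox_partial_loglik(beta: float, times, events, x, ties: str = "breslow") -> float:
    """Log partial likelihood at ``beta`` (Breslow or Efron tie handling)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    eta = beta * x
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[events]):
        risk = times >= t
        dead = events & (times == t)
        d = int(dead.sum())
        ll += eta[dead].sum()
        if ties == "breslow" or d == 1:
            ll -= d * np.log(w[risk].sum())
        else:  # efron
            s_risk = w[risk].sum()
            s_dead = w[dead].sum()
            for j in range(d):
                ll -= np.log(s_risk - (j / d) * s_dead)
    return float(ll)


def _score_info(beta: float, times, events, x, ties: str):
    """Score and information of the partial likelihood, O(n log n)."""
    w = np.exp(beta * x)
    order = np.argsort(-times, kind="stable")  # descending time
    t_s, e_s, x_s, w_s = times[order], events[order], x[order], w[order]
    c0 = np.cumsum(w_s)
    c1 = np.cumsum(w_s * x_s)
    c2 = np.cumsum(w_s * x_s**2)
    # index of the last subject still at risk for each time (ties share risk sets)
    U = 0.0
    info = 0.0
    unique_times = np.unique(t_s[e_s])
    for t in unique_times:
        at_risk = np.searchsorted(-t_s, -t, side="right") - 1
        S0, S1, S2 = c0[at_risk], c1[at_risk], c2[at_risk]
        dead = e_s & (t_s == t)
        d = int(dead.sum())
        xsum = x_s[dead].sum()
        if ties == "breslow" or d == 1:
            U += xsum - d * S1 / S0
            info += d * (S2 / S0 - (S1 / S0) ** 2)
        else:  # efron
            wd = w_s[dead]
            D0, D1, D2 = wd.sum(), (wd * x_s[dead]).sum(), (wd * x_s[dead] ** 2).sum()
            for j in range(d):
                f = j / d
                s0 = S0 - f * D0
                s1 = S1 - f * D1
                s2 = S2 - f * D2
                U += xsum / d - s1 / s0
                info += s2 / s0 - (s1 / s0) ** 2
    return U, info


def cox_fit_univariate(
    records: list[SurvivalRecord],
    covariate_name: str,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
    beta_bound: float = 10.0,
) -> SurvivalFit:
    """Newton fit of the univariate Cox model starting from beta = 0.

    Convergence when the absolute score drops below ``tol``; a coefficient
    escaping ``beta_bound`` marks monotone likelihood and the fit is returned
    with ``converged=False``.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    times, events, x = _extract(records, covariate_name)
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("all records censored: Cox model undefined")
    if n_events < 2:
        raise ValueError("need at least 2 events for a stable fit")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")

    beta = 0.0
    converged = False
    info = np.nan
    for _ in range(max_iter):
        U, info = _score_info(beta, times, events, x, ties)
        if info <= 0:
            break
        step = U / info
        step = float(np.clip(step, -5.0, 5.0))  # guard huge early steps
        beta += step
        if abs(beta) > beta_bound:
            break
        if abs(U) < tol:
            converged = True
            break
    if abs(beta) > beta_bound:  # monotone likelihood: coefficient diverges
        converged = False
    se = float(1.0 / np.sqrt(info)) if info and info > 0 else np.nan
    z = beta / se if se and np.isfinite(se) and se > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return SurvivalFit(
        covariate_name=covariate_name,
        beta=float(beta),
        se=se,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)) if np.isfinite(se) else np.nan,
        ci_high=float(np.exp(beta + Z_95 * se)) if np.isfinite(se) else np.nan,
        p=p,
        p_adjusted=None,
        n=len(records),
        n_events=n_events,
        converged=converged,
    )


def bonferroni_alpha(family_alpha: float = 0.05, m: int = 1) -> float:
    """Per-test significance level controlling the family-wise error."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


def bonferroni_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Adjusted p = min(1, m * p)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)


def dichotomize_by_median(values: pd.Series | dict) -> pd.Series:
    """Split a continuous covariate at its median; ties go to 'low'."""
    s = pd.Series(values, dtype=float)
    median = s.median()
    return pd.Series(np.where(s <= median, "low", "high"), index=s.index)


def km_curve(
    records: list[SurvivalRecord], group_labels: pd.Series | dict | None = None
) -> dict[str, dict]:
    """Product-limit survival step function and median survival per group.

    ``group_labels`` maps patient_id -> label; omitted, all records form one
    group.  Median survival is the first time S(t) <= 0.5 and is ``None``
    when the curve never reaches it.
    """
    labels = pd.Series(group_labels) if group_labels is not None else None
    groups: dict[str, list[SurvivalRecord]] = {}
    for rec in records:
        label = "all" if labels is None else str(labels.get(rec.patient_id))
        groups.setdefault(label, []).append(rec)
    out = {}
    for label, recs in sorted(groups.items()):
        times = [r.time for r in recs]
        events = [r.event for r in recs]
        kmf = KaplanMeierFitter()
        kmf.fit(times, events)
        sf = kmf.survival_function_
        median = kmf.median_survival_time_
        out[label] = {
            "curve": pd.DataFrame(
                {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
            ),
            "median": None if np.isinf(median) else float(median),
            "n": len(recs),
            "n_events": int(sum(events)),
        }
    return out


def screen_mirnas(
    records: list[SurvivalRecord],
    mirna_list: list[str] | None = None,
    family_alpha: float = 0.05,
    ties: str = "breslow",
) -> pd.DataFrame:
    """One univariate Cox fit per miRNA with Bonferroni adjustment.

    The per-test level is ``family_alpha / m`` over the screened list; the
    output is sorted by adjusted p ascending, with unconverged or degenerate
    fits reported last.
    """
    if mirna_list is None:
        mirna_list = sorted({name for rec in records for name in rec.covariates})
    if not mirna_list:
        return pd.DataFrame(
            columns=["covariate_name", "beta", "se", "hr", "ci_low", "ci_high",
                     "p", "p_adjusted", "n", "n_events", "converged"]
        )
    m = len(mirna_list)
    rows = []
    for name in mirna_list:
        try:
            fit = cox_fit_univariate(records, name, ties=ties)
        except (ValueError, KeyError):
            rows.append({"covariate_name": name, "beta": np.nan, "se": np.nan,
                         "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "p_adjusted": np.nan, "n": len(records),
                         "n_events": np.nan, "converged": False})
            continue
        p_adj = float(bonferroni_adjust([fit.p], m)[0]) if np.isfinite(fit.p) else np.nan
        rows.append({
            "covariate_name": fit.covariate_name, "beta": fit.beta, "se": fit.se,
            "hr": fit.hr, "ci_low": fit.ci_low, "ci_high": fit.ci_high,
            "p": fit.p, "p_adjusted": p_adj, "n": fit.n,
            "n_events": fit.n_events, "converged": fit.converged,
        })
    df = pd.DataFrame(rows)
    df["per_test_alpha"] = bonferroni_alpha(family_alpha, m)
    return df.sort_values("p_adjusted", na_position="last", kind="stable").reset_index(drop=True)
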