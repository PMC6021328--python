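"""From-scratch survival machinery.

Inclusion filtering, Kaplan-Meier product-limit curves with the
"smallest t with S(t) <= 0.5" median convention, k-group log-rank tests
with hypergeometric variance, Cox proportional-hazards regression with
Breslow tie handling, and univariate-gated forward stepwise selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class SurvivalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# inclusion filter
# ---------------------------------------------------------------------------

def apply_inclusion_filter(
    records: pd.DataFrame,
    min_os: float = 1,
    min_followup: float = 18,
    os_col: str = "os_months",
    event_col: str = "event",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (included, excluded-with-reasons).

    Excluded are: records with missing OS (reason ``missing_os``), deaths at
    ``os <= min_os`` months (``early_death``), and censored records with
    ``os < min_followup`` months of follow-up (``short_followup``).
    """
    os_v = pd.to_numeric(records[os_col], errors="coerce")
    ev = records[event_col]
    reasons = pd.Series("", index=records.index, dtype=object)
    reasons[os_v.isna()] = "missing_os"
    reasons[os_v.notna() & (ev == 1) & (os_v <= min_os)] = "early_death"
    reasons[os_v.notna() & (ev == 0) & (os_v < min_followup)] = "short_followup"
    excluded = records[reasons != ""].copy()
    excluded["exclusion_reason"] = reasons[reasons != ""]
    included = records[reasons == ""].copy()
    logger.info(
        "inclusion filter: %d included, %d excluded (%s)",
        len(included), len(excluded),
        dict(excluded["exclusion_reason"].value_counts()) if len(excluded) else {},
    )
    return included, excluded


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(t) evaluated at the distinct event times."""

    times: np.ndarray        # distinct event (death) times, ascending
    at_risk: np.ndarray      # n at risk just before each event time
    events: np.ndarray       # deaths at each event time
    survival: np.ndarray     # S(t) at each event time
    n: int
    n_events: int
    n_censored: int

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier product-limit fit; ``events`` is 1 for death, 0 censored."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise SurvivalError("km_fit requires at least one subject")
    if t.shape != e.shape:
        raise SurvivalError("times and events differ in length")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    at_risk = np.empty(len(uniq), dtype=int)
    deaths = np.empty(len(uniq), dtype=int)
    surv = np.empty(len(uniq))
    s = 1.0
    for i, u in enumerate(uniq):
        n_i = int((t >= u).sum())
        d_i = int(((t == u) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        at_risk[i], deaths[i], surv[i] = n_i, d_i, s
    return KMCurve(
        uniq, at_risk, deaths, surv,
        n=len(t), n_events=int(e.sum()), n_censored=int((e == 0).sum()),
    )


def km_median(curve: KMCurve) -> float | None:
    """Smallest t with S(t) <= 0.5, or None when the curve never reaches 0.5."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.times[below[0]]) if len(below) else None


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(groups) -> LogrankResult:
    """k-group log-rank test.

    ``groups`` is a sequence of ``(times, events)`` pairs. Observed-minus-
    expected death counts with the hypergeometric variance at each distinct
    event time; statistic is chi-square with ``k - 1`` df.
    """
    k = len(groups)
    if k < 2:
        raise SurvivalError("log-rank needs at least two groups")
    ts, es = [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if len(t) == 0:
            raise SurvivalError(f"log-rank group {g} is empty")
        ts.append(t)
        es.append(e)
    event_times = np.unique(np.concatenate([t[e == 1] for t, e in zip(ts, es)]))
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in event_times:
        n_g = np.array([(t >= u).sum() for t in ts], dtype=float)
        d_g = np.array([((t == u) & (e == 1)).sum() for t, e in zip(ts, es)],
                       dtype=float)
        n_tot, d_tot = n_g.sum(), d_g.sum()
        O += d_g
        E += d_tot * n_g / n_tot
        if n_tot > 1:
            p = n_g / n_tot
            hyper = d_tot * (n_tot - d_tot) / (n_tot - 1)
            V += hyper * (np.diag(p) - np.outer(p, p))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    return LogrankResult(stat, df, float(stats.chi2.sf(stat, df)), O, E)


def logrank_pairwise(groups, labels=None) -> pd.DataFrame:
    """All pairwise two-group log-rank tests; rows (a, b, statistic, p)."""
    labels = labels if labels is not None else list(range(len(groups)))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            r = logrank_test([groups[i], groups[j]])
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "statistic": r.statistic, "p_value": r.p_value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    params: pd.DataFrame          # coef, se, hr, ci_low, ci_high, p per column
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool
    separation_flag: bool = False
    selected: list[str] = field(default_factory=list)
    selection_log: list[str] = field(default_factory=list)

    @property
    def lr_statistic(self) -> float:
        return 2.0 * (self.loglik - self.loglik_null)


def _breslow_loglik(beta, t, e, X):
    """Breslow partial log-likelihood, gradient and information.

    Subjects sorted by descending time; risk sets accumulate as we walk
    toward earlier times.
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
    s0, s1, s2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:  # everyone tied at this time enters risk set
            s0 += w[j]
            s1 += w[j] * X[j]
            s2 += w[j] * np.outer(X[j], X[j])
            j += 1
        d_idx = [m for m in range(i, j) if e[m] == 1]
        d = len(d_idx)
        if d:
            xbar = s1 / s0
            ll += eta[d_idx].sum() - d * np.log(s0)
            grad += X[d_idx].sum(axis=0) - d * xbar
            info += d * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return ll, grad, info


def cox_fit(
    times, events, X: pd.DataFrame | np.ndarray,
    max_iter: int = 100, tol: float = 1e-8,
) -> CoxFit:
    """Cox PH fit maximizing the Breslow partial likelihood by Newton steps.

    Deterministic given input order; convergence is gradient norm < ``tol``.
    Non-convergence raises; runaway coefficients are flagged as separation.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{i}" for i in range(Xm.shape[1])]
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() < 1:
        raise SurvivalError("cox_fit requires at least one event")
    order = np.argsort(-t, kind="stable")
    t, e, Xm = t[order], e[order], Xm[order]
    # center covariates for numerical stability (does not change coefficients)
    centers = Xm.mean(axis=0)
    Xc = Xm - centers

    p = Xc.shape[1]
    ll_null, _, _ = _breslow_loglik(np.zeros(p), t, e, Xc) if p else (0.0, None, None)
    if p == 0:
        # null model: partial log-likelihood with all coefficients at zero
        ll0, _, _ = _breslow_loglik(np.zeros(1), t, e, np.zeros((len(t), 1)))
        empty = pd.DataFrame(
            columns=["coef", "se", "hr", "ci_low", "ci_high", "p"])
        return CoxFit(empty, ll0, ll0, len(t), int(e.sum()), True)

    beta = np.zeros(p)
    ll, grad, info = _breslow_loglik(beta, t, e, Xc)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_grad, new_info = _breslow_loglik(new_beta, t, e, Xc)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _breslow_loglik(new_beta, t, e, Xc)
            halvings += 1
        ll_change = abs(new_ll - ll)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        # float64 round-off floors the attainable gradient norm on large
        # cohorts; a stationary log-likelihood with a tiny gradient is done
        if ll_change < 1e-10 * (1.0 + abs(ll)) and np.linalg.norm(grad) < 1e-4:
            converged = True
            break
    else:
        if np.linalg.norm(grad) < tol:
            converged = True
    if not converged:
        raise SurvivalError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(last gradient norm {np.linalg.norm(grad):.3g})"
        )
    # monotone-likelihood heuristic: runaway coefficient or exploded SE
    separation = bool(np.any(np.abs(beta) > 10))
    if separation:
        logger.warning("cox_fit: runaway coefficients, possible complete separation")
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    z = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    zq = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # CI of a separated fit may overflow
        params = pd.DataFrame({
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - zq * se),
            "ci_high": np.exp(beta + zq * se),
            "p": pvals,
        }, index=names)
    return CoxFit(params, float(ll), float(ll_null), len(t), int(e.sum()),
                  converged, separation)


# ---------------------------------------------------------------------------
# stepwise Cox with univariate log-rank gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Covariate:
    """A candidate model variable.

    ``levels`` (reference first) marks a categorical column to dummy-code;
    ``levels=None`` treats the column as numeric.
    """

    name: str
    column: str
    levels: tuple[str, ...] | None = None


def _design(df: pd.DataFrame, cov: Covariate) -> pd.DataFrame:
    if cov.levels is None:
        return df[[cov.column]].astype(float).rename(columns={cov.column: cov.name})
    out = {}
    for lev in cov.levels[1:]:
        out[f"{cov.name}[{lev}]"] = (df[cov.column] == lev).astype(float)
    return pd.DataFrame(out, index=df.index)


def univariate_logrank_p(df: pd.DataFrame, cov: Covariate,
                         os_col="os_months", event_col="event") -> float:
    """Univariate screen: log-rank across the variable's categories."""
    sub = df.dropna(subset=[cov.column])
    if cov.levels is not None:
        cats = [lev for lev in cov.levels if (sub[cov.column] == lev).any()]
        groups = [
            (sub.loc[sub[cov.column] == lev, os_col],
             sub.loc[sub[cov.column] == lev, event_col])
            for lev in cats
        ]
        if len(groups) < 2:
            return 1.0
        return logrank_test(groups).p_value
    fit = cox_fit(sub[os_col], sub[event_col], sub[[cov.column]])
    return float(fit.params["p"].iloc[0])


def stepwise_cox(
    records: pd.DataFrame,
    candidates: list[Covariate],
    os_col: str = "os_months",
    event_col: str = "event",
    gate_p: float = 0.05,
    entry_p: float = 0.05,
) -> CoxFit:
    """Forward stepwise Cox model over univariate-significant candidates.

    Candidates are first gated by a univariate log-rank p < ``gate_p``; the
    surviving ones then enter by likelihood-ratio test at ``entry_p``, ties
    broken by the larger likelihood improvement. Records missing any gated
    candidate are dropped (complete cases) with a logged count. When no
    candidate passes the gate the null model is returned with a warning.
    """
    log: list[str] = []
    gated = []
    for cov in candidates:
        p = univariate_logrank_p(records, cov, os_col, event_col)
        log.append(f"gate {cov.name}: univariate p={p:.4g} "
                   f"{'PASS' if p < gate_p else 'drop'}")
        if p < gate_p:
            gated.append(cov)
    cols = {c.column for c in gated} | {os_col, event_col}
    df = records.dropna(subset=sorted(cols))
    n_drop = len(records) - len(df)
    if n_drop:
        log.append(f"complete cases: dropped {n_drop} of {len(records)} records")
        logger.info("stepwise_cox: dropped %d records with missing covariates",
                    n_drop)

    def fit_with(selected: list[Covariate]) -> CoxFit:
        if not selected:
            return cox_fit(df[os_col], df[event_col],
                           pd.DataFrame(index=df.index))
        X = pd.concat([_design(df, c) for c in selected], axis=1)
        return cox_fit(df[os_col], df[event_col], X)

    selected: list[Covariate] = []
    current = fit_with(selected)
    if not gated:
        logger.warning("stepwise_cox: no candidate passed the univariate gate; "
                       "returning the null model")
        current.selection_log = log
        return current
    remaining = list(gated)
    while remaining:
        trials = []
        for cov in remaining:
            try:
                fit = fit_with(selected + [cov])
            except SurvivalError as err:
                log.append(f"try {cov.name}: fit failed ({err})")
                continue
            df_added = len(fit.params) - len(current.params)
            lr = 2.0 * (fit.loglik - current.loglik)
            p = float(stats.chi2.sf(max(lr, 0.0), max(df_added, 1)))
            trials.append((p, -lr, cov, fit))
            log.append(f"try {cov.name}: LR={lr:.3f} df={df_added} p={p:.4g}")
        if not trials:
            break
        trials.sort(key=lambda t: (t[0], t[1], t[2].name))
        best_p, _, best_cov, best_fit = trials[0]
        if best_p >= entry_p:
            break
        selected.append(best_cov)
        remaining.remove(best_cov)
        current = best_fit
        log.append(f"enter {best_cov.name} (p={best_p:.4g})")
    current.selected = [c.name for c in selected]
    current.selection_log = log
    return current


# ---------------------------------------------------------------------------
# grouped survival summary
# ---------------------------------------------------------------------------

def km_by_group(
    records: pd.DataFrame, group_col: str,
    os_col: str = "os_months", event_col: str = "event",
    group_order=None,
) -> pd.DataFrame:
    """Per-group n, events, KM median and range of observed times."""
    rows = []
    groups = group_order if group_order is not None else (
        sorted(records[group_col].dropna().unique())
    )
    for g in groups:
        sub = records[records[group_col] == g]
        if len(sub) == 0:
            rows.append({"group": g, "n": 0, "events": 0, "median": None,
                         "min_os": None, "max_os": None})
            continue
        curve = km_fit(sub[os_col], sub[event_col])
        med = km_median(curve)
        rows.append({
            "group": g, "n": len(sub), "events": int(sub[event_col].sum()),
            "median": med,
            "min_os": float(sub[os_col].min()), "max_os": float(sub[os_col].max()),
        })
    return pd.DataFrame(rows)
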