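"""Survival analysis and random-effects meta-analysis across omic levels.

Provides the log-rank test (via lifelines), a univariate Cox
proportional-hazards fit (Newton-Raphson on the partial likelihood, with
Breslow tie handling by default and Efron available as a cross-check),
and a per-gene random-effects meta-analysis pooling log hazard ratios
from copy number, transcript, and protein data with an empirical-Bayes
(Paule-Mandel-type) heterogeneity estimator and Storey q-value selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.optimize import brentq

from .association_stats import storey_qvalue


def km_logrank(records: pd.DataFrame, groups) -> tuple[float, float]:
    """Log-rank test across groups.

    ``records`` needs ``time_years`` and ``event`` columns aligned with
    ``groups``. Returns (chi-square statistic, p on groups-1 df). With no
    events the test is undefined and p = 1 is returned with a warning.
    """
    groups = np.asarray(groups)
    if records["event"].sum() == 0:
        warnings.warn("no events observed; log-rank p set to 1")
        return 0.0, 1.0
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")
    res = multivariate_logrank_test(
        records["time_years"], groups, records["event"]
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    log_hr: float
    se: float
    p: float
    converged: bool
    flagged: bool = False     # monotone likelihood / divergence


def _cox_score_info(
    beta: float, t: np.ndarray, d: np.ndarray, x: np.ndarray, ties: str
) -> tuple[float, float, float]:
    """Log partial likelihood, score and information at beta.

    Arrays must be sorted by time ascending; ``d`` is the event flag.
    """
    eta = beta * x
    w = np.exp(eta)
    # risk-set sums from the largest time downward
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * x)[::-1])[::-1]
    s2 = np.cumsum((w * x * x)[::-1])[::-1]

    ll = 0.0
    score = 0.0
    info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.where(d[i:j] == 1)[0] + i
        m = len(ev)
        if m:
            xs = x[ev]
            if ties == "breslow":
                ll += beta * xs.sum() - m * np.log(s0[i])
                score += xs.sum() - m * s1[i] / s0[i]
                info += m * (s2[i] / s0[i] - (s1[i] / s0[i]) ** 2)
            elif ties == "efron":
                wd = np.exp(beta * xs)
                d0, d1, d2 = wd.sum(), (wd * xs).sum(), (wd * xs * xs).sum()
                for l in range(m):
                    f = l / m
                    a0 = s0[i] - f * d0
                    a1 = s1[i] - f * d1
                    a2 = s2[i] - f * d2
                    ll -= np.log(a0)
                    score -= a1 / a0
                    info += a2 / a0 - (a1 / a0) ** 2
                ll += beta * xs.sum()
                score += xs.sum()
            else:
                raise ValueError(f"unknown tie handling {ties!r}")
        i = j
    return ll, score, info


def cox_univariate(
    records: pd.DataFrame,
    covariate,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
    min_events: int = 5,
) -> CoxResult:
    """Univariate Cox proportional-hazards regression.

    Newton-Raphson maximization of the partial likelihood; SE from the
    observed information; Wald p. Non-convergence within ``max_iter``
    iterations or a monotone likelihood (diverging estimate) yields a
    flagged result with missing SE.
    """
    x = np.asarray(covariate, dtype=float)
    t = records["time_years"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    ok = np.isfinite(x) & np.isfinite(t)
    x, t, d = x[ok], t[ok], d[ok]
    if d.sum() < min_events:
        raise ValueError(f"need at least {min_events} events, got {int(d.sum())}")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    order = np.argsort(t, kind="stable")
    t, d, x = t[order], d[order], x[order]
    # center/scale internally for numerical stability, rescale afterwards
    mu, sd = x.mean(), x.std()
    xs = (x - mu) / sd

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        _, score, info = _cox_score_info(beta, t, d, xs, ties)
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > 20.0:    # monotone likelihood
            return CoxResult(
                log_hr=np.sign(beta) * np.inf, se=np.nan, p=np.nan,
                converged=False, flagged=True,
            )
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        return CoxResult(log_hr=beta / sd, se=np.nan, p=np.nan,
                         converged=False, flagged=True)
    _, _, info = _cox_score_info(beta, t, d, xs, ties)
    se_s = 1.0 / np.sqrt(info)
    log_hr = beta / sd
    se = se_s / sd
    z = log_hr / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(log_hr=float(log_hr), se=float(se), p=float(p), converged=True)


@dataclass
class MetaResult:
    pooled: float
    se: float
    tau2: float
    p: float
    converged: bool


def random_effects_meta(
    estimates, standard_errors, tol: float = 1e-8, max_iter: int = 200
) -> MetaResult:
    """Random-effects pooling of k estimates with empirical-Bayes tau2.

    tau2 solves the Paule-Mandel-type estimating equation: the weighted
    residual statistic Q(tau2) = sum w_i (y_i - mu(tau2))**2 with
    w_i = 1/(se_i**2 + tau2) equals its expectation k - 1, with tau2
    clipped at 0 when even tau2 = 0 over-disperses. The pooled estimate is
    the inverse-variance weighted mean at the solved tau2; Wald p. On
    numerical failure a DerSimonian-Laird tau2 is used and the result is
    flagged as non-converged.
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(standard_errors, dtype=float) ** 2
    ok = np.isfinite(y) & np.isfinite(v) & (v > 0)
    y, v = y[ok], v[ok]
    k = len(y)
    if k < 2:
        raise ValueError("need at least 2 usable estimates")

    def q_excess(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = (w * y).sum() / w.sum()
        return (w * (y - mu) ** 2).sum() - (k - 1)

    converged = True
    if q_excess(0.0) <= 0:
        tau2 = 0.0
    else:
        hi = max(v.max(), y.var(ddof=1)) * 10 + 1.0
        tries = 0
        while q_excess(hi) > 0 and tries < 60:
            hi *= 4.0
            tries += 1
        try:
            tau2 = brentq(q_excess, 0.0, hi, xtol=tol, maxiter=max_iter)
        except ValueError:
            # DerSimonian-Laird fallback
            w = 1.0 / v
            mu = (w * y).sum() / w.sum()
            q = (w * (y - mu) ** 2).sum()
            c = w.sum() - (w**2).sum() / w.sum()
            tau2 = max(0.0, (q - (k - 1)) / c)
            converged = False

    w = 1.0 / (v + tau2)
    pooled = (w * y).sum() / w.sum()
    se = 1.0 / np.sqrt(w.sum())
    z = pooled / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MetaResult(pooled=float(pooled), se=float(se), tau2=float(tau2),
                      p=float(p), converged=converged)


def meta_analyze_genes(
    per_omic: pd.DataFrame, q_threshold: float = 0.3
) -> pd.DataFrame:
    """Random-effects meta-analysis per gene across omic levels.

    ``per_omic`` is indexed by gene with columns ``loghr_<omic>`` and
    ``se_<omic>`` for each omic level; genes need at least two usable
    (estimate, SE) pairs. Adds Storey q-values and a ``selected`` flag at
    q <= ``q_threshold``. Duplicate gene symbols are resolved by first
    occurrence.
    """
    per_omic = per_omic[~per_omic.index.duplicated(keep="first")]
    loghr_cols = sorted(c for c in per_omic.columns if c.startswith("loghr_"))
    se_cols = [c.replace("loghr_", "se_") for c in loghr_cols]
    rows = []
    for gene, row in per_omic.iterrows():
        y = row[loghr_cols].to_numpy(dtype=float)
        se = row[se_cols].to_numpy(dtype=float)
        usable = np.isfinite(y) & np.isfinite(se) & (se > 0)
        if usable.sum() < 2:
            continue
        res = random_effects_meta(y[usable], se[usable])
        rows.append((gene, res.pooled, res.se, res.tau2, res.p, res.converged))
    out = pd.DataFrame(
        rows, columns=["gene", "pooled_loghr", "pooled_se", "tau2", "p", "converged"]
    ).set_index("gene")
    if len(out):
        q, pi0 = storey_qvalue(out["p"].to_numpy())
        out["q"] = q
        out["selected"] = out["q"] <= q_threshold
        out.attrs["pi0"] = pi0
    return out
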