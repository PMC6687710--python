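"""Differential expression and categorical association statistics.

The toolbox behind the cohort-level results: the rank-sum / fold-change /
BH differential-expression rule, two-sided Fisher exact tests reporting the
conditional-MLE odds ratio, the 1-df Cochran-Mantel-Haenszel ordinal
(nonzero-correlation) test, Benjamini-Hochberg and Storey q-value
multiple-testing adjustments, and a hypergeometric over-representation
test for gene-set labeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

EXACT_RANKSUM_MAX_N = 25


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1).

    NaN entries are ignored and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value: exact null for combined n <= 25 (no
    ties), normal approximation with tie correction otherwise. All values
    tied -> p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        return 1.0
    n = len(combined)
    has_ties = len(np.unique(combined)) < n
    method = "exact" if (n <= EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def wilcoxon_de(
    matrix: pd.DataFrame,
    group_mask,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    min_group_n: int = 3,
    estimator: str = "median",
) -> pd.DataFrame:
    """Per-feature rank-sum differential expression on a log2 matrix.

    ``group_mask`` selects the foreground columns; the rest of the cohort
    is the background. Fold change is ``2**(median_A - median_B)``
    (``estimator="mean"`` switches to group means). A feature is
    significant iff |fold change| >= ``fc_threshold`` and the BH-adjusted
    p-value is <= ``alpha``. Features with fewer than ``min_group_n``
    non-missing values in either group are skipped (NaN p, never
    significant).
    """
    mask = np.asarray(group_mask, dtype=bool)
    if mask.shape[0] != matrix.shape[1]:
        raise ValueError("group_mask length must match the number of samples")
    center = np.nanmedian if estimator == "median" else np.nanmean
    values = matrix.to_numpy(dtype=float)
    a_all, b_all = values[:, mask], values[:, ~mask]

    pvals = np.full(len(matrix), np.nan)
    lfc = np.full(len(matrix), np.nan)
    for i in range(len(matrix)):
        a = a_all[i][np.isfinite(a_all[i])]
        b = b_all[i][np.isfinite(b_all[i])]
        if len(a) < min_group_n or len(b) < min_group_n:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lfc[i] = center(a) - center(b)
        pvals[i] = wilcoxon_rank_sum(a, b)

    padj = bh_adjust(pvals)
    sig = (
        np.isfinite(lfc)
        & (np.abs(lfc) >= np.log2(fc_threshold))
        & np.isfinite(padj)
        & (padj <= alpha)
    )
    return pd.DataFrame(
        {
            "feature": matrix.index,
            "log2_fc": lfc,
            "p": pvals,
            "p_adj": padj,
            "significant": sig,
        }
    ).set_index("feature")


@dataclass
class FisherResult:
    odds_ratio: float   # conditional MLE (0 and inf allowed at boundaries)
    p: float            # two-sided exact p


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher exact test with the conditional-MLE odds ratio.

    The p-value sums margin-fixed hypergeometric probabilities of tables
    at most as probable as the observed one; the odds ratio maximizes the
    noncentral hypergeometric likelihood at the observed cell (the value
    exact-test software reports, not the sample cross-product ratio).
    A zero margin gives p = 1 and a missing odds ratio.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return FisherResult(odds_ratio=float("nan"), p=1.0)
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    cmle = float(_odds_ratio(t, kind="conditional").statistic)
    return FisherResult(odds_ratio=cmle, p=min(p, 1.0))


def cmh_ordinal_test(
    table, scores=None, variant: str = "correlation"
) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel test of a 2 x K ordered contingency table.

    The default ``variant="correlation"`` is the 1-df nonzero-correlation
    statistic M2 = (N-1) * r**2, where r is the Pearson correlation between
    the binary row indicator and the ordinal category score over all N
    individuals; p comes from chi-square with 1 df. The general-association
    variant ((N-1)/N times the Pearson chi-square, K-1 df) is available via
    ``variant="general"``. Zero variance in either margin gives p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2 or (t < 0).any():
        raise ValueError("table must be 2 x K (K >= 2) with nonnegative counts")
    n = t.sum()
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if scores is None:
        scores = np.arange(t.shape[1], dtype=float)
    scores = np.asarray(scores, dtype=float)

    if variant == "general":
        occupied = t.sum(axis=0) > 0
        tt = t[:, occupied]
        chi2, _, dof, _ = stats.chi2_contingency(tt, correction=False)
        m2 = (n - 1) / n * chi2
        return float(m2), float(stats.chi2.sf(m2, dof))
    if variant != "correlation":
        raise ValueError(f"unknown variant {variant!r}")

    counts = t.ravel()
    g = np.repeat([0.0, 1.0], t.shape[1])
    s = np.tile(scores, 2)
    w = counts / n
    mg, ms = (w * g).sum(), (w * s).sum()
    vg = (w * (g - mg) ** 2).sum()
    vs = (w * (s - ms) ** 2).sum()
    if vg == 0 or vs == 0:
        return 0.0, 1.0
    cov = (w * (g - mg) * (s - ms)).sum()
    r = cov / np.sqrt(vg * vs)
    m2 = (n - 1) * r * r
    return float(m2), float(stats.chi2.sf(m2, 1))


def storey_qvalue(
    pvalues, lambdas=None, pi0: float | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated from pi0(lambda) = #{p > lambda} / (m * (1 - lambda))
    over the lambda grid, smoothed with a cubic polynomial and evaluated at
    the largest lambda, clipped into (0, 1]. With fewer than 20 p-values
    the smoother is unreliable and pi0 falls back to 1 (with a warning),
    making the q-values equal to the BH adjustment.
    """
    p = np.asarray(pvalues, dtype=float)
    mask = np.isfinite(p)
    pv = p[mask]
    m = len(pv)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if pi0 is None:
        if m < 20:
            warnings.warn("fewer than 20 p-values; pi0 set to 1")
            pi0 = 1.0
        else:
            pi0_l = np.array(
                [(pv > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
            )
            coef = np.polyfit(lambdas, pi0_l, deg=3)
            pi0 = float(np.polyval(coef, lambdas.max()))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    q = np.full(p.shape, np.nan)
    if m:
        order = np.argsort(pv)
        ranked = pv[order]
        qv = pi0 * m * ranked / np.arange(1, m + 1)
        qv = np.minimum.accumulate(qv[::-1])[::-1]
        qs = np.empty(m)
        qs[order] = np.minimum(qv, 1.0)
        q[mask] = qs
    return q, float(pi0)


def hypergeom_ora(
    query: set | list,
    collection: dict[str, list[str] | set[str]],
    universe: set | list,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query gene set.

    For each set in the collection, p = P(overlap >= observed) under
    sampling ``len(query)`` genes from the universe without replacement;
    BH adjustment across sets. The query must be a subset of the universe.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe, e.g. {extra}")
    m = len(universe)
    rows = []
    for name, genes in collection.items():
        genes = set(genes) & universe
        k = len(query & genes)
        if not query:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, m, len(genes), len(query)))
        rows.append((name, k, len(genes), min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.set_index("set")
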