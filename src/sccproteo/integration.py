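"""Cross-omic correlation analyses and the vulnerability intersection cascade.

Operations here connect the bridged protein matrix to copy number,
transcript, mutation, and functional-screen data: feature-paired Spearman
correlation with a minimum-support rule, high/low correlation band
partitioning, differential co-expression around an anchor protein between
two sample groups, transcription-factor target correlation summaries, the
candidate-vulnerability intersection cascade (dosage-correlated genes x
subtype-elevated proteins x screen-essential genes), and gene-level
reduction of filtered copy-number segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association_stats import bh_adjust, wilcoxon_rank_sum

MIN_SUPPORT_FRACTION = 0.10


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rho and t-approximation p over pairwise-complete values."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan, np.nan, n
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p), n


def paired_spearman(
    x: pd.DataFrame,
    y: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    min_fraction: float = MIN_SUPPORT_FRACTION,
) -> pd.DataFrame:
    """Spearman correlation for feature pairs across shared samples.

    ``pairs`` lists (x_feature, y_feature); when omitted, features shared
    by both matrices are paired with themselves. Pairs where either vector
    has fewer than ``min_fraction`` non-missing values over the shared
    samples are skipped. BH adjustment across the computed pairs.
    """
    samples = x.columns.intersection(y.columns)
    if samples.empty:
        raise ValueError("no shared sample columns between the matrices")
    if pairs is None:
        feats = x.index.intersection(y.index)
        pairs = [(f, f) for f in feats]
    xs = x[samples]
    ys = y[samples]
    n_samples = len(samples)
    rows = []
    for fx, fy in pairs:
        vx = xs.loc[fx].to_numpy(dtype=float)
        vy = ys.loc[fy].to_numpy(dtype=float)
        if (np.isfinite(vx).sum() < min_fraction * n_samples
                or np.isfinite(vy).sum() < min_fraction * n_samples):
            continue
        rho, p, n = _spearman(vx, vy)
        rows.append((fx, fy, rho, n, p))
    out = pd.DataFrame(rows, columns=["feature_x", "feature_y", "rho", "n_used", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def mean_rho(records: pd.DataFrame) -> float:
    """Cohort mean Spearman correlation over defined pairs."""
    return float(records["rho"].mean(skipna=True))


def correlation_band_sets(
    records: pd.DataFrame,
    high: float = 0.5,
    low_band: tuple[float, float] = (-0.2, 0.2),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition correlation records into strictly-high and strictly-low
    bands (open intervals: rho > high; low_band[0] < rho < low_band[1])."""
    rho = records["rho"]
    high_set = records[rho > high]
    low_set = records[(rho > low_band[0]) & (rho < low_band[1])]
    return high_set, low_set


@dataclass
class DifferentialCorrelation:
    per_feature: pd.DataFrame       # rho/p/p_adj in each group + delta
    significant_a: list[str]
    significant_b: list[str]
    difference_set: list[str]


def differential_correlation(
    expr: pd.DataFrame,
    anchor: str,
    mask_a,
    mask_b,
    delta_threshold: float = 0.5,
    sig_rho: float = 0.5,
    sig_padj: float = 0.25,
    min_fraction: float = MIN_SUPPORT_FRACTION,
) -> DifferentialCorrelation:
    """Correlation to an anchor feature, contrasted between two groups.

    Computes, per feature, the Spearman correlation to the anchor within
    group A and within group B (pairwise-complete, minimum-support rule),
    with BH adjustment per group. Reports (i) features significantly
    correlated within a group (rho > sig_rho and P_adj <= sig_padj) and
    (ii) features whose correlation differs between groups by more than
    ``delta_threshold``.
    """
    if anchor not in expr.index:
        raise ValueError(f"anchor feature {anchor!r} not in the matrix")
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.sum() < 5 or mask_b.sum() < 5:
        raise ValueError("both groups need at least 5 samples")

    def group_corr(mask: np.ndarray) -> pd.DataFrame:
        sub = expr.loc[:, expr.columns[mask]]
        anchor_vec = sub.loc[anchor].to_numpy(dtype=float)
        n_s = mask.sum()
        rows = []
        for feat in sub.index:
            if feat == anchor:
                continue
            v = sub.loc[feat].to_numpy(dtype=float)
            if (np.isfinite(v).sum() < min_fraction * n_s
                    or np.isfinite(anchor_vec).sum() < min_fraction * n_s):
                rows.append((feat, np.nan, 0, np.nan))
                continue
            rho, p, n = _spearman(anchor_vec, v)
            rows.append((feat, rho, n, p))
        df = pd.DataFrame(rows, columns=["feature", "rho", "n_used", "p"]).set_index("feature")
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        return df

    a = group_corr(mask_a)
    b = group_corr(mask_b)
    per_feature = a.join(b, lsuffix="_a", rsuffix="_b")
    per_feature["delta_rho"] = per_feature["rho_a"] - per_feature["rho_b"]

    def sig(df: pd.DataFrame) -> list[str]:
        keep = (df["rho"] > sig_rho) & (df["p_adj"] <= sig_padj)
        return sorted(df.index[keep.fillna(False)])

    diff = per_feature["delta_rho"].abs() > delta_threshold
    return DifferentialCorrelation(
        per_feature=per_feature,
        significant_a=sig(a),
        significant_b=sig(b),
        difference_set=sorted(per_feature.index[diff.fillna(False)]),
    )


def tf_target_summary(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    target_sets: dict[str, list[str]],
    subtype_labels: pd.Series,
    compare: tuple | None = None,
    min_pairs: int = 10,
    min_samples: int = 5,
    min_fraction: float = MIN_SUPPORT_FRACTION,
) -> pd.DataFrame:
    """Mean transcript-protein correlation of target sets, per subtype.

    For every target set and subtype, per-gene Spearman correlations are
    recomputed within that subtype's samples and averaged. When
    ``compare=(s1, s2)`` is given, the two subtypes' per-gene correlation
    values are compared with a rank-sum test per set. Subtypes with fewer
    than ``min_samples`` samples are excluded with a warning.
    """
    shared = rna.columns.intersection(protein.columns).intersection(subtype_labels.index)
    labels = subtype_labels.loc[shared]
    usable = []
    for s in sorted(labels.unique()):
        if (labels == s).sum() < min_samples:
            warnings.warn(f"subtype {s} has fewer than {min_samples} samples; excluded")
        else:
            usable.append(s)

    rows = []
    for name, genes in target_sets.items():
        genes = [g for g in genes if g in rna.index and g in protein.index]
        if len(genes) < min_pairs:
            raise ValueError(
                f"target set {name!r} has {len(genes)} measured pairs; need {min_pairs}"
            )
        per_subtype: dict = {}
        gene_rhos: dict = {}
        for s in usable:
            cols = labels.index[labels == s]
            rec = paired_spearman(
                rna[cols], protein[cols], pairs=[(g, g) for g in genes],
                min_fraction=min_fraction,
            )
            gene_rhos[s] = rec["rho"].dropna().to_numpy()
            per_subtype[f"mean_rho_{s}"] = (
                float(np.mean(gene_rhos[s])) if len(gene_rhos[s]) else np.nan
            )
        row = {"set": name, **per_subtype}
        if compare is not None:
            s1, s2 = compare
            if s1 in gene_rhos and s2 in gene_rhos and len(gene_rhos[s1]) and len(gene_rhos[s2]):
                row["p_compare"] = wilcoxon_rank_sum(gene_rhos[s1], gene_rhos[s2])
            else:
                row["p_compare"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")


@dataclass
class CascadeResult:
    """Gene sets of the vulnerability intersection cascade."""

    high_correlation: set[str]      # H: dosage-correlated at both levels
    elevated: set[str]              # E: significantly elevated in the focal subtype
    essential: set[str]             # D: screen-essential in >= 1 cell line
    primary: list[str]              # H & E & D
    secondary: list[str]            # (E & D) \ H
    confirmed: dict[str, bool]      # Bayes-factor confirmation per candidate

    def table(self) -> pd.DataFrame:
        rows = [
            (g, "primary", self.confirmed.get(g)) for g in self.primary
        ] + [(g, "secondary", self.confirmed.get(g)) for g in self.secondary]
        return pd.DataFrame(rows, columns=["gene", "tier", "bf_confirmed"])


def vulnerability_cascade(
    cnv_prot: pd.DataFrame,
    rna_prot: pd.DataFrame,
    de_table: pd.DataFrame,
    screen: pd.DataFrame,
    rho_min: float = 0.5,
    padj_max: float = 0.25,
    rsa_max: float = -3.0,
    bf_min: float = 3.0,
) -> CascadeResult:
    """Intersect dosage-correlated, subtype-elevated, and essential genes.

    H = genes with both CNV-protein and RNA-protein Spearman rho >
    ``rho_min`` and both P_adj < ``padj_max``; E = genes significantly
    elevated (positive fold change) in the focal subtype per ``de_table``
    (a ``wilcoxon_de`` result); D = genes with RSA < ``rsa_max`` in at
    least one cell line. Primary candidates are H & E & D; secondary are
    (E & D) not in H. Candidates with a Bayes factor > ``bf_min`` in any
    line are flagged as confirmed.
    """

    def corr_genes(rec: pd.DataFrame) -> set[str]:
        keep = (rec["rho"] > rho_min) & (rec["p_adj"] < padj_max)
        return set(rec.loc[keep.fillna(False), "feature_x"])

    h = corr_genes(cnv_prot) & corr_genes(rna_prot)
    e = set(de_table.index[(de_table["significant"]) & (de_table["log2_fc"] > 0)])
    ess = screen[screen["rsa"] < rsa_max]
    d = set(ess["gene"])

    universes = [
        set(cnv_prot["feature_x"]) | set(rna_prot["feature_x"]),
        set(de_table.index),
        set(screen["gene"]),
    ]
    common = set.intersection(*universes)
    if not common:
        raise ValueError(
            "gene namespaces do not intersect across the cascade inputs "
            f"(sizes {[len(u) for u in universes]})"
        )

    primary = sorted(h & e & d)
    secondary = sorted((e & d) - h)
    confirmed = {}
    if "bayes_factor" in screen.columns:
        bf_hits = set(screen.loc[screen["bayes_factor"] > bf_min, "gene"])
        for g in primary + secondary:
            confirmed[g] = g in bf_hits
    return CascadeResult(
        high_correlation=h,
        elevated=e,
        essential=d,
        primary=primary,
        secondary=secondary,
        confirmed=confirmed,
    )


def summarize_cnv(
    segments: pd.DataFrame,
    gene_models: pd.DataFrame,
    min_probes: int = 50,
    min_length: int = 400_000,
    state_threshold: float = 0.1,
    reduction: str = "max_abs",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample copy-number values from filtered segments.

    Segments supported by fewer than ``min_probes`` probes or spanning
    ``min_length`` bases or less are dropped (the length gate is a strict
    inequality). Coordinates are 0-based half-open. A gene's value is the
    log2 of the overlapping filtered segment with maximal |log2|
    (``reduction="length_weighted"`` switches to the overlap-length
    weighted mean). Returns the gene x sample log2 matrix and per-gene
    gain/loss counts (log2 beyond +-``state_threshold``). Malformed
    intervals are rejected record-by-record with their row positions
    reported in a warning.
    """
    required = {"sample", "chrom", "start", "end", "n_probes", "log2"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns {sorted(missing)}")
    bad_rows = segments.index[
        ~(segments["end"] > segments["start"]) | (segments["n_probes"] < 1)
    ].tolist()
    if bad_rows:
        warnings.warn(f"rejected malformed segment rows at positions {bad_rows[:10]}")
        segments = segments.drop(index=bad_rows)

    kept = segments[
        (segments["n_probes"] >= min_probes)
        & ((segments["end"] - segments["start"]) > min_length)
    ]
    samples = sorted(segments["sample"].unique())
    values = pd.DataFrame(0.0, index=gene_models["gene"], columns=samples)

    for (sample, chrom), segs in kept.groupby(["sample", "chrom"]):
        genes = gene_models[gene_models["chrom"] == chrom]
        if genes.empty:
            continue
        gs = genes["start"].to_numpy()
        ge = genes["end"].to_numpy()
        names = genes["gene"].to_numpy()
        for g_i in range(len(names)):
            ov = segs[(segs["start"] < ge[g_i]) & (segs["end"] > gs[g_i])]
            if ov.empty:
                continue
            if reduction == "max_abs":
                val = ov.loc[ov["log2"].abs().idxmax(), "log2"]
            elif reduction == "length_weighted":
                w = (
                    np.minimum(ov["end"], ge[g_i]) - np.maximum(ov["start"], gs[g_i])
                ).to_numpy(dtype=float)
                val = float(np.average(ov["log2"], weights=w))
            else:
                raise ValueError(f"unknown reduction {reduction!r}")
            values.loc[names[g_i], sample] = val

    counts = pd.DataFrame(
        {
            "n_gain": (values > state_threshold).sum(axis=1),
            "n_loss": (values < -state_threshold).sum(axis=1),
        }
    )
    return values, counts
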