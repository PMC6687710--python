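"""Pool-referenced normalization and cross-plex bridging of TMT intensities.

Within each plex, every channel's spectral reporter intensities are
normalized against the fixed reference-pool channel (the bridge channel)
with a rank-invariant scaling procedure, spectral log2 ratios versus the
pool are averaged into protein-level ratios, and the pool channel itself is
rolled up to protein-level abundances (geometric mean of unlogged spectral
intensities).

Across plexes, the per-plex reference-pool protein abundances are
normalized against a cohort reference pool (the pool whose median log2
abundance is the median over pools), a per-protein abundance scale is
taken as the geometric mean of the normalized pool abundances, and each
sample's abundance is reconstructed as ``scale * 2**log_ratio``, log2
transformed, with replicate measurements of a tumor averaged on the log2
scale. No imputation is performed anywhere: missing stays missing.

All ratios use log base 2 throughout, so the scale/ratio pairing is
internally consistent (base-agnostic in the reconstruction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import io
from .synthetic_cohort import PlexDesign, POOL, TUMOR

MIN_SHARED_FEATURES = 20


def rank_invariant_normalize(
    sample_vec: np.ndarray | pd.Series,
    reference_vec: np.ndarray | pd.Series,
    tol_start: float = 0.05,
    tol_floor: float = 0.01,
    max_iter: int = 10,
    estimator: str = "median",
    return_factor: bool = False,
):
    """Scale ``sample_vec`` onto ``reference_vec`` via a rank-invariant set.

    Iteratively selects features whose rank difference between sample and
    reference falls below a shrinking tolerance (a fraction of the current
    set size, halved each iteration from ``tol_start`` down to
    ``tol_floor``), then fits a single multiplicative factor from the
    log-ratios over that set — by default their median (exact whenever a
    majority of the invariant set is exactly proportional), or the
    geometric mean with ``estimator="geomean"``. Iteration stops when the
    invariant set stabilizes or after ``max_iter`` rounds.

    Both vectors must be strictly positive on a shared support of at least
    20 features. Degenerate (constant) inputs fall back to median-ratio
    scaling with a warning.
    """
    s = np.asarray(sample_vec, dtype=float)
    r = np.asarray(reference_vec, dtype=float)
    if s.shape != r.shape:
        raise ValueError("sample and reference must have the same length")
    shared = np.isfinite(s) & np.isfinite(r) & (s > 0) & (r > 0)
    n_shared = int(shared.sum())
    if n_shared < MIN_SHARED_FEATURES:
        raise ValueError(
            f"only {n_shared} shared positive features; "
            f"need at least {MIN_SHARED_FEATURES}"
        )
    log_ratio = np.log2(r[shared]) - np.log2(s[shared])

    if np.ptp(s[shared]) == 0 or np.ptp(r[shared]) == 0:
        warnings.warn("degenerate (constant) vector; falling back to median-ratio scaling")
        factor = 2.0 ** float(np.median(log_ratio))
        out = s * factor
        return (out, factor) if return_factor else out

    idx = np.arange(n_shared)
    tol = tol_start
    for _ in range(max_iter):
        rs = rankdata(s[shared][idx])
        rr = rankdata(r[shared][idx])
        keep = np.abs(rs - rr) <= max(1.0, tol * len(idx))
        new_idx = idx[keep]
        if len(new_idx) < MIN_SHARED_FEATURES:
            break
        stable = len(new_idx) == len(idx)
        idx = new_idx
        if stable and tol <= tol_floor:
            break
        tol = max(tol_floor, tol / 2.0)

    ratios = log_ratio[idx]
    if estimator == "median":
        log_factor = float(np.median(ratios))
    elif estimator == "geomean":
        log_factor = float(np.mean(ratios))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    factor = 2.0 ** log_factor
    out = s * factor
    return (out, factor) if return_factor else out


@dataclass
class PlexRollup:
    """Protein-level summaries of one plex, referenced to its pool channel."""

    plex: int
    log_ratios: pd.DataFrame       # proteins x channels, log2 ratio vs pool
    pool_abundance: pd.Series      # per-protein geometric-mean pool abundance
    channel_samples: dict[int, str]
    channel_roles: dict[int, str]
    pool_channel: int
    channel_factors: dict[int, float]


def rollup_protein(
    plex_psms: pd.DataFrame,
    pool_channel: int,
    channel_samples: dict[int, str],
    channel_roles: dict[int, str],
    normalize: bool = True,
) -> PlexRollup:
    """Roll spectral intensities of one plex up to protein level.

    Per protein and channel the log2 ratio versus the pool channel is the
    arithmetic mean of the spectral log2 ratios (after rank-invariant
    normalization of the channel against the pool when ``normalize``);
    the pool abundance is the geometric mean of the unlogged pool-channel
    spectral intensities. A protein with no usable spectra in a channel is
    missing, never zero.
    """
    if plex_psms["decoy"].any():
        plex_psms = plex_psms[~plex_psms["decoy"]]
    channels = sorted(channel_samples)
    int_cols = {c: f"{io.INTENSITY_PREFIX}{c}" for c in channels}
    plex = int(plex_psms["plex"].iloc[0]) if len(plex_psms) else -1

    pool_int = plex_psms[int_cols[pool_channel]].to_numpy(dtype=float)
    proteins = plex_psms["protein_group"].to_numpy()
    factors: dict[int, float] = {pool_channel: 1.0}
    ratio_cols = {}
    for c in channels:
        vals = plex_psms[int_cols[c]].to_numpy(dtype=float)
        if c != pool_channel and normalize:
            vals, f = rank_invariant_normalize(vals, pool_int, return_factor=True)
            factors[c] = f
        elif c != pool_channel:
            factors[c] = 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = np.where(
                (vals > 0) & (pool_int > 0),
                np.log2(vals) - np.log2(pool_int),
                np.nan,
            )
        ratio_cols[c] = lr

    spec = pd.DataFrame(ratio_cols, index=proteins)
    log_ratios = spec.groupby(level=0, sort=True).mean()

    with np.errstate(divide="ignore"):
        log_pool = np.where(pool_int > 0, np.log2(pool_int), np.nan)
    pool_ab = (
        pd.Series(log_pool, index=proteins).groupby(level=0, sort=True).mean()
    )
    pool_abundance = 2.0 ** pool_ab

    return PlexRollup(
        plex=plex,
        log_ratios=log_ratios,
        pool_abundance=pool_abundance,
        channel_samples=dict(channel_samples),
        channel_roles=dict(channel_roles),
        pool_channel=pool_channel,
        channel_factors=factors,
    )


@dataclass
class BridgeResult:
    """Cohort-wide bridged abundances and bridging metadata."""

    matrix: pd.DataFrame           # proteins x tumors, log2 abundance
    pool_matrix: pd.DataFrame      # proteins x pool replicate measurements
    reference_pool: str            # sample id of the cohort reference pool
    scale: pd.Series               # per-protein abundance scale (log2)
    plex_factors: dict[int, float]

    def report(self) -> dict:
        return {
            "reference_pool": self.reference_pool,
            "n_proteins": int(self.matrix.shape[0]),
            "n_tumors": int(self.matrix.shape[1]),
            "plex_factors": {str(k): v for k, v in self.plex_factors.items()},
        }


def bridge_across_plexes(
    rollups: list[PlexRollup],
    design: PlexDesign,
    estimator: str = "median",
) -> BridgeResult:
    """Combine per-plex rollups into one cohort-wide log2 abundance matrix.

    Steps: (1) normalize each plex's reference-pool protein abundances
    against the cohort reference pool (rank-invariant); (2) per-protein
    scale = geometric mean of the normalized pool abundances; (3) sample
    abundance = scale * 2**log_ratio; (4) log2 transform; (5) average
    replicate measurements per tumor on the log2 scale.
    """
    if not rollups:
        raise ValueError("no plexes to bridge")
    for r in rollups:
        if r.pool_abundance.dropna().empty:
            raise ValueError(f"plex {r.plex} has no usable pool channel")

    pools = pd.DataFrame({r.plex: r.pool_abundance for r in rollups})
    with np.errstate(divide="ignore"):
        log_pools = np.log2(pools)
    medians = log_pools.median(axis=0, skipna=True)
    target = medians.median()
    # cohort reference pool: the pool whose median is the median of medians
    # (closest on even counts); ties broken by smallest pool sample id
    pool_ids = {
        r.plex: design.reference_pool_sample(r.plex) for r in rollups
    }
    cand = sorted(
        medians.index, key=lambda p: (abs(medians[p] - target), pool_ids[p])
    )
    ref_plex = cand[0]

    ref_vec = pools[ref_plex].to_numpy()
    normalized = {}
    plex_factors = {}
    for p in pools.columns:
        if p == ref_plex:
            normalized[p] = pools[p].to_numpy()
            plex_factors[p] = 1.0
        else:
            vals, f = rank_invariant_normalize(
                pools[p].to_numpy(), ref_vec, estimator=estimator, return_factor=True
            )
            normalized[p] = vals
            plex_factors[p] = f
    norm_pools = pd.DataFrame(normalized, index=pools.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_scale = np.log2(norm_pools).mean(axis=1, skipna=True)
    # proteins absent from every pool remain missing downstream
    scale = log_scale

    sample_cols: dict[str, list[pd.Series]] = {}
    pool_cols: dict[str, pd.Series] = {}
    for r in rollups:
        for c, sample in r.channel_samples.items():
            ratio = r.log_ratios[c] if c in r.log_ratios.columns else None
            if ratio is None:
                continue
            bridged = scale.reindex(ratio.index) + ratio
            role = r.channel_roles[c]
            if role == POOL:
                pool_cols[sample] = bridged
            else:
                sample_cols.setdefault(sample, []).append(bridged)

    # replicate measurements averaged on the log2 scale
    matrix = pd.DataFrame(
        {
            s: pd.concat(cols, axis=1).mean(axis=1, skipna=True)
            for s, cols in sample_cols.items()
        }
    ).sort_index(axis=1)
    pool_matrix = pd.DataFrame(pool_cols).sort_index(axis=1)
    return BridgeResult(
        matrix=matrix,
        pool_matrix=pool_matrix,
        reference_pool=pool_ids[ref_plex],
        scale=scale,
        plex_factors=plex_factors,
    )


def bridge_cohort(
    psms: pd.DataFrame,
    design: PlexDesign,
    normalize_within_plex: bool = True,
) -> BridgeResult:
    """Convenience wrapper: roll up every plex and bridge across plexes."""
    rollups = []
    for p, plex_psms in psms.groupby("plex"):
        chans = design.plex_channels(int(p))
        channel_samples = dict(zip(chans["channel"], chans["sample"]))
        channel_roles = dict(zip(chans["channel"], chans["role"]))
        rollups.append(
            rollup_protein(
                plex_psms,
                pool_channel=design.reference_channel,
                channel_samples=channel_samples,
                channel_roles=channel_roles,
                normalize=normalize_within_plex,
            )
        )
    return bridge_across_plexes(rollups, design)
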