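"""Target-decoy FDR control and two-step protein-group assembly.

The assembly mirrors the two-step strategy used for deep TMT tumor
proteomes: peptide-spectrum matches (PSMs) are first filtered at a
stringent FDR (default 0.1%) and protein groups are required to carry a
minimum number of distinct peptides; the PSM filter is then relaxed
(default 1%) but only spectra mapping to the step-1 protein groups are
admitted, increasing spectral depth without admitting new groups.

FDR is estimated from decoy counts. The default estimator is the
concatenated target-decoy convention FDR(t) = 2*D(t) / (T(t) + D(t));
the separate-search convention D(t)/T(t) is available via
``estimator="ratio"``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_MOD_ANNOTATION = re.compile(r"[\[\(\{][^\]\)\}]*[\]\)\}]")


def peptide_key(peptide: str) -> str:
    """Canonical peptide string: modification annotations (bracketed mass or
    name tags) are stripped so modified forms of one peptide count once."""
    return _MOD_ANNOTATION.sub("", peptide).strip()


@dataclass
class ProteinGroupSet:
    """Result of the two-step assembly."""

    groups: pd.DataFrame          # protein_group, n_peptides, n_spectra
    psms: pd.DataFrame            # retained step-2 target PSMs
    psm_fdr_used: float
    strict_fdr: float
    protein_fdr: float
    strict_threshold: float
    relaxed_threshold: float
    empty: bool = False

    def report(self) -> dict:
        return {
            "n_groups": int(len(self.groups)),
            "n_spectra": int(len(self.psms)),
            "n_peptides": int(self.psms["peptide"].map(peptide_key).nunique())
            if len(self.psms)
            else 0,
            "psm_fdr_used": self.psm_fdr_used,
            "strict_fdr": self.strict_fdr,
            "protein_fdr": self.protein_fdr,
            "strict_threshold": self.strict_threshold,
            "relaxed_threshold": self.relaxed_threshold,
            "empty": self.empty,
        }


def _fdr_threshold(
    scores: np.ndarray, decoy: np.ndarray, fdr_target: float, estimator: str
) -> float:
    """Lowest score threshold t with estimated FDR(t) <= fdr_target.

    The threshold is a score value, so tied PSMs are admitted or excluded
    together; the FDR at the chosen cut point is tie-inclusive by
    construction. Returns +inf when no cut point qualifies.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    d = decoy[order].astype(float)
    cum_d = np.cumsum(d)
    cum_t = np.cumsum(1.0 - d)
    # evaluate only at the last index of each tie group (tie-inclusive cuts)
    last_of_group = np.append(s[1:] != s[:-1], True)
    idx = np.where(last_of_group)[0]
    if estimator == "concatenated":
        fdr = 2.0 * cum_d[idx] / (cum_t[idx] + cum_d[idx])
    elif estimator == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = np.where(cum_t[idx] > 0, cum_d[idx] / cum_t[idx], np.inf)
    else:
        raise ValueError(f"unknown FDR estimator {estimator!r}")
    ok = fdr <= fdr_target
    if not ok.any():
        return np.inf
    # the most permissive qualifying cut point
    return float(s[idx[np.where(ok)[0][-1]]])


def psm_fdr_filter(
    psms: pd.DataFrame,
    fdr_target: float,
    estimator: str = "concatenated",
    return_threshold: bool = False,
):
    """Retain target PSMs at the requested score-threshold FDR.

    Retains every PSM with score >= the lowest threshold t at which the
    estimated FDR is <= ``fdr_target``; decoys are excluded from the
    returned set. Raises if no decoys are present (FDR inestimable).
    """
    if not (0.0 <= fdr_target <= 1.0):
        raise ValueError("fdr_target must lie in [0, 1]")
    decoy = psms["decoy"].to_numpy(dtype=bool)
    if not decoy.any():
        raise ValueError("no decoy PSMs present; FDR cannot be estimated")
    threshold = _fdr_threshold(
        psms["score"].to_numpy(dtype=float), decoy, fdr_target, estimator
    )
    retained = psms[(~decoy) & (psms["score"] >= threshold)]
    if return_threshold:
        return retained, threshold
    return retained


def _qualified_groups(psms: pd.DataFrame, min_peptides: int) -> pd.DataFrame:
    if psms.empty:
        return pd.DataFrame(columns=["protein_group", "n_peptides", "n_spectra"])
    keys = psms["peptide"].map(peptide_key)
    stats = (
        psms.assign(_pep=keys)
        .groupby("protein_group", sort=True)
        .agg(n_peptides=("_pep", "nunique"), n_spectra=("spectrum_id", "size"))
        .reset_index()
    )
    return stats[stats["n_peptides"] >= min_peptides].reset_index(drop=True)


def two_step_assembly(
    psms: pd.DataFrame,
    strict_fdr: float = 0.001,
    min_peptides: int = 2,
    relaxed_fdr: float = 0.01,
    estimator: str = "concatenated",
) -> ProteinGroupSet:
    """Two-step FDR-controlled protein-group assembly.

    Step 1: filter PSMs at ``strict_fdr`` and keep protein groups carrying
    at least ``min_peptides`` distinct peptides. Step 2: re-filter all PSMs
    at ``relaxed_fdr`` and keep only those mapping to step-1 groups.
    The protein-level FDR is estimated as the number of decoy groups
    surviving the same step-1 procedure divided by the number of target
    groups.
    """
    strict_psms, t_strict = psm_fdr_filter(
        psms, strict_fdr, estimator, return_threshold=True
    )
    step1 = _qualified_groups(strict_psms, min_peptides)
    if step1.empty:
        warnings.warn("two_step_assembly: no protein groups survive step 1")
        return ProteinGroupSet(
            groups=step1,
            psms=strict_psms.iloc[0:0],
            psm_fdr_used=relaxed_fdr,
            strict_fdr=strict_fdr,
            protein_fdr=float("nan"),
            strict_threshold=t_strict,
            relaxed_threshold=float("nan"),
            empty=True,
        )

    relaxed_psms, t_relaxed = psm_fdr_filter(
        psms, relaxed_fdr, estimator, return_threshold=True
    )
    keep = relaxed_psms["protein_group"].isin(set(step1["protein_group"]))
    final_psms = relaxed_psms[keep].reset_index(drop=True)

    # decoy groups put through the same step-1 gate estimate the protein FDR
    decoys = psms[psms["decoy"] & (psms["score"] >= t_strict)]
    decoy_groups = _qualified_groups(decoys, min_peptides)
    protein_fdr = len(decoy_groups) / len(step1)

    groups = _qualified_groups(final_psms, 1)
    groups = groups[groups["protein_group"].isin(set(step1["protein_group"]))]
    return ProteinGroupSet(
        groups=groups.reset_index(drop=True),
        psms=final_psms,
        psm_fdr_used=relaxed_fdr,
        strict_fdr=strict_fdr,
        protein_fdr=protein_fdr,
        strict_threshold=t_strict,
        relaxed_threshold=t_relaxed,
    )


def filter_by_observation(matrix: pd.DataFrame, min_fraction: float) -> pd.DataFrame:
    """Keep features observed (non-missing) in at least ``min_fraction`` of
    samples; feature order is preserved."""
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in (0, 1]")
    frac = matrix.notna().mean(axis=1)
    return matrix.loc[frac >= min_fraction]
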