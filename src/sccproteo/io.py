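"""Readers and writers for the plain-text formats used by the pipeline.

All tabular artifacts are tab-separated text. Abundance matrices are
features x samples with an explicit header row; missing values are empty
cells (never sentinel numbers). PSM tables are written in long form (one
row per spectrum x channel) but held in memory in wide form (one row per
spectrum, one intensity column per channel).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

INTENSITY_PREFIX = "intensity_"


def intensity_columns(n_channels: int) -> list[str]:
    return [f"{INTENSITY_PREFIX}{c}" for c in range(n_channels)]


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a features x samples matrix as TSV (empty cell = missing)."""
    matrix.to_csv(path, sep="\t", index=True, index_label="feature", na_rep="")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")


def write_psms(psms: pd.DataFrame, path: str | Path) -> None:
    """Write a wide PSM table in long form: one row per spectrum x channel."""
    int_cols = [c for c in psms.columns if c.startswith(INTENSITY_PREFIX)]
    id_cols = [c for c in psms.columns if c not in int_cols]
    long = psms.melt(
        id_vars=id_cols, value_vars=int_cols, var_name="channel", value_name="intensity"
    )
    long["channel"] = long["channel"].str.removeprefix(INTENSITY_PREFIX).astype(int)
    long = long.sort_values(["plex", "spectrum_id", "channel"], kind="stable")
    cols = ["plex", "channel", "spectrum_id", "peptide", "protein_group", "decoy", "score", "intensity"]
    long[cols].to_csv(path, sep="\t", index=False)


def read_psms(path: str | Path) -> pd.DataFrame:
    """Read a long-form PSM TSV back into the wide in-memory layout."""
    long = pd.read_csv(path, sep="\t")
    id_cols = ["plex", "spectrum_id", "peptide", "protein_group", "decoy", "score"]
    wide = long.pivot_table(
        index=id_cols, columns="channel", values="intensity", aggfunc="first"
    )
    wide.columns = [f"{INTENSITY_PREFIX}{c}" for c in wide.columns]
    return wide.reset_index()


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def read_bed_genes(path: str | Path) -> pd.DataFrame:
    """Read gene models as BED (chrom, start, end, name); 0-based half-open."""
    genes = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"],
    )
    return genes[["gene", "chrom", "start", "end"]]
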