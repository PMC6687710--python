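"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` chains the stages — simulate (or ingest), assemble,
bridge, subtype, associate, integrate, survive — writing every artifact
under one output directory together with a JSON manifest recording
package and library versions, the fully resolved configuration, derived
per-stage seeds, and per-stage row counts. Given the same configuration
and environment the manifest is byte-identical across runs.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__, io
from ._seeding import child_seed
from .association_stats import bh_adjust, fisher_exact, wilcoxon_de
from .integration import paired_spearman, summarize_cnv, vulnerability_cascade
from .outcome_meta import cox_univariate, meta_analyze_genes
from .psm_assembly import filter_by_observation, two_step_assembly
from .subtype_discovery import (
    consensus_cluster,
    select_k,
    select_variable_features,
)
from .synthetic_cohort import CohortConfig, PlexDesign, generate_cohort
from .tmt_bridge import bridge_cohort

DEFAULTS: dict = {
    "seed": 1234,
    "cohort": {},
    "assembly": {"strict_fdr": 0.001, "relaxed_fdr": 0.01, "min_peptides": 2},
    "bridge": {"min_observed_fraction": 0.5},
    "subtype": {
        "n_features": 1000,
        "k_min": 2,
        "k_max": 8,
        "n_resamples": 250,
        "delta_threshold": 0.10,
        "p_item": 0.8,
    },
    "associate": {"fc_threshold": 1.5, "alpha": 0.05},
    "integrate": {
        "rho_min": 0.5,
        "padj_max": 0.25,
        "rsa_max": -3.0,
        "bf_min": 3.0,
        "min_probes": 50,
        "min_length": 400_000,
    },
    "survive": {"n_genes": 200, "q_threshold": 0.3, "min_events": 5},
}


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (defaults merged with overrides)."""

    seed: int = 1234
    cohort: dict = field(default_factory=dict)
    assembly: dict = field(default_factory=dict)
    bridge: dict = field(default_factory=dict)
    subtype: dict = field(default_factory=dict)
    associate: dict = field(default_factory=dict)
    integrate: dict = field(default_factory=dict)
    survive: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, overrides: dict | None) -> "PipelineConfig":
        merged = copy.deepcopy(DEFAULTS)
        overrides = overrides or {}
        unknown = set(overrides) - set(merged)
        if unknown:
            raise ValueError(f"unknown pipeline config sections: {sorted(unknown)}")
        for key, value in overrides.items():
            if key == "seed":
                merged["seed"] = int(value)
            else:
                if not isinstance(value, dict):
                    raise ValueError(f"section {key!r} must be a mapping")
                merged[key].update(value)
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("pipeline config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "cohort": dict(self.cohort),
            "assembly": dict(self.assembly),
            "bridge": dict(self.bridge),
            "subtype": dict(self.subtype),
            "associate": dict(self.associate),
            "integrate": dict(self.integrate),
            "survive": dict(self.survive),
        }


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every constraint violation (empty list means valid)."""
    problems: list[str] = []
    if not isinstance(config.seed, int) or config.seed < 0:
        problems.append("seed must be a nonnegative integer")

    try:
        cohort = CohortConfig(**config.cohort)
        problems.extend(f"cohort: {p}" for p in cohort.validate())
    except TypeError as exc:
        problems.append(f"cohort: {exc}")

    a = config.assembly
    if not (0 < a["strict_fdr"] <= a["relaxed_fdr"] <= 1):
        problems.append("assembly: need 0 < strict_fdr <= relaxed_fdr <= 1")
    if a["min_peptides"] < 1:
        problems.append("assembly: min_peptides must be >= 1")

    if not (0 < config.bridge["min_observed_fraction"] <= 1):
        problems.append("bridge: min_observed_fraction must lie in (0, 1]")

    s = config.subtype
    if not (2 <= s["k_min"] < s["k_max"]):
        problems.append("subtype: need 2 <= k_min < k_max")
    if s["n_resamples"] < 1:
        problems.append("subtype: n_resamples must be >= 1")
    if not (0 < s["p_item"] <= 1):
        problems.append("subtype: p_item must lie in (0, 1]")
    if not (0 < s["delta_threshold"] < 1):
        problems.append("subtype: delta_threshold must lie in (0, 1)")

    if config.associate["fc_threshold"] < 1:
        problems.append("associate: fc_threshold must be >= 1")
    if not (0 < config.associate["alpha"] <= 1):
        problems.append("associate: alpha must lie in (0, 1]")

    i = config.integrate
    if i["min_probes"] < 1 or i["min_length"] < 0:
        problems.append("integrate: min_probes >= 1 and min_length >= 0 required")
    if not (0 < i["padj_max"] <= 1):
        problems.append("integrate: padj_max must lie in (0, 1]")

    if config.survive["n_genes"] < 1:
        problems.append("survive: n_genes must be >= 1")
    if not (0 < config.survive["q_threshold"] <= 1):
        problems.append("survive: q_threshold must lie in (0, 1]")
    return problems


def _load_inputs(data_dir: Path) -> dict:
    """Read previously written cohort artifacts from ``data_dir``."""
    inputs = {
        "psms": io.read_psms(data_dir / "psms.tsv"),
        "design": PlexDesign(frame=io.read_table(data_dir / "design.tsv")),
        "rna": io.read_matrix(data_dir / "rna.tsv"),
        "mutations": io.read_table(data_dir / "mutations.tsv"),
        "cnv_segments": io.read_table(data_dir / "cnv_segments.tsv"),
        "gene_models": io.read_bed_genes(data_dir / "gene_models.bed"),
        "survival": io.read_table(data_dir / "survival.tsv"),
    }
    screen_path = data_dir / "screen.tsv"
    inputs["screen"] = io.read_table(screen_path) if screen_path.exists() else None
    return inputs


def _cox_row(survival: pd.DataFrame, covariate: pd.Series, min_events: int):
    """(log HR, SE) for one gene/omic, NaN on degeneracy or divergence."""
    aligned = covariate.reindex(survival["sample"]).to_numpy(dtype=float)
    try:
        res = cox_univariate(survival, aligned, min_events=min_events)
    except ValueError:
        return np.nan, np.nan
    if res.flagged or not np.isfinite(res.se):
        return np.nan, np.nan
    return res.log_hr, res.se


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    data_dir: str | Path | None = None,
) -> dict:
    """Run every stage and return the manifest (also written to disk).

    With ``data_dir`` the simulate stage is skipped and cohort artifacts
    are read from that directory instead; a missing screen table there
    skips the vulnerability cascade with a manifest note.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))
    outdir = Path(outdir)
    results = outdir / "results"
    results.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "config": config.to_dict(),
        "stage_seeds": {},
        "stages": {},
        "notes": [],
        "outputs": [],
    }

    def record(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(outdir)))

    # ---- simulate / ingest ------------------------------------------------
    if data_dir is None:
        sim_seed = int(config.cohort.get("seed", child_seed(config.seed, "simulate")))
        manifest["stage_seeds"]["simulate"] = sim_seed
        cohort_cfg = CohortConfig(**{**config.cohort, "seed": sim_seed})
        cohort = generate_cohort(cohort_cfg)
        data_out = outdir / "data"
        cohort.write(data_out)
        for f in sorted(data_out.iterdir()):
            record(f)
        inputs = {
            "psms": cohort.psms,
            "design": cohort.design,
            "rna": cohort.rna,
            "mutations": cohort.mutations,
            "cnv_segments": cohort.cnv_segments,
            "gene_models": cohort.gene_models,
            "screen": cohort.screen,
            "survival": cohort.survival,
        }
        manifest["stages"]["simulate"] = {
            "n_tumors": len(cohort.design.tumors),
            "n_psms": int(len(cohort.psms)),
        }
    else:
        inputs = _load_inputs(Path(data_dir))
        manifest["notes"].append("inputs read from an existing data directory")
        manifest["stages"]["simulate"] = {
            "skipped": True,
            "n_psms": int(len(inputs["psms"])),
        }

    design = inputs["design"]

    # ---- assemble ---------------------------------------------------------
    assembly = two_step_assembly(
        inputs["psms"],
        strict_fdr=config.assembly["strict_fdr"],
        min_peptides=config.assembly["min_peptides"],
        relaxed_fdr=config.assembly["relaxed_fdr"],
    )
    io.write_table(assembly.groups, results / "protein_groups.tsv")
    record(results / "protein_groups.tsv")
    manifest["stages"]["assemble"] = assembly.report()
    if assembly.empty:
        raise ValueError("no protein groups survived assembly; cannot continue")

    # ---- bridge -----------------------------------------------------------
    bridged = bridge_cohort(assembly.psms, design)
    protein = filter_by_observation(
        bridged.matrix, config.bridge["min_observed_fraction"]
    )
    io.write_matrix(protein, results / "protein_matrix.tsv")
    record(results / "protein_matrix.tsv")
    manifest["stages"]["bridge"] = {
        **bridged.report(),
        "n_proteins_after_observation_filter": int(protein.shape[0]),
    }

    # ---- subtype ----------------------------------------------------------
    sub_seed = child_seed(config.seed, "subtype")
    manifest["stage_seeds"]["subtype"] = sub_seed
    s = config.subtype
    n_feat = min(s["n_features"], protein.shape[0])
    features = select_variable_features(protein, n=n_feat)
    consensus = consensus_cluster(
        protein.loc[features],
        k_range=range(s["k_min"], s["k_max"] + 1),
        n_resamples=s["n_resamples"],
        p_item=s["p_item"],
        seed=sub_seed,
    )
    k = select_k(consensus, delta_threshold=s["delta_threshold"])
    labels = consensus.labels[k]
    labels.rename_axis("sample").rename("cluster").reset_index().to_csv(
        results / "subtype_labels.tsv", sep="\t", index=False
    )
    record(results / "subtype_labels.tsv")
    manifest["stages"]["subtype"] = {
        "n_features": n_feat,
        "chosen_k": int(k),
        "cluster_sizes": {
            str(c): int(n) for c, n in labels.value_counts().sort_index().items()
        },
    }

    # ---- associate --------------------------------------------------------
    de_by_cluster: dict[int, pd.DataFrame] = {}
    de_frames = []
    for c in sorted(labels.unique()):
        mask = (labels == c).to_numpy()
        de = wilcoxon_de(
            protein,
            mask,
            fc_threshold=config.associate["fc_threshold"],
            alpha=config.associate["alpha"],
        )
        de_by_cluster[int(c)] = de
        de_frames.append(de.assign(cluster=int(c)))
    de_all = pd.concat(de_frames).reset_index()
    io.write_table(de_all, results / "differential_expression.tsv")
    record(results / "differential_expression.tsv")

    mut_rows = []
    mutations = inputs["mutations"]
    for gene, sub in mutations.groupby("gene"):
        status = sub.set_index("sample")["status"].reindex(labels.index).fillna(0)
        for c in sorted(labels.unique()):
            in_c = labels == c
            table = [
                [int(((status == 1) & in_c).sum()), int(((status == 1) & ~in_c).sum())],
                [int(((status == 0) & in_c).sum()), int(((status == 0) & ~in_c).sum())],
            ]
            res = fisher_exact(table)
            mut_rows.append((gene, int(c), res.odds_ratio, res.p))
    mut_assoc = pd.DataFrame(
        mut_rows, columns=["gene", "cluster", "odds_ratio", "p"]
    )
    mut_assoc["p_adj"] = bh_adjust(mut_assoc["p"].to_numpy())
    io.write_table(mut_assoc, results / "mutation_associations.tsv")
    record(results / "mutation_associations.tsv")
    manifest["stages"]["associate"] = {
        "n_de_significant": int(de_all["significant"].sum()),
        "n_mutation_tests": int(len(mut_assoc)),
    }

    # ---- integrate --------------------------------------------------------
    i_cfg = config.integrate
    cnv_genes, _ = summarize_cnv(
        inputs["cnv_segments"],
        inputs["gene_models"],
        min_probes=i_cfg["min_probes"],
        min_length=i_cfg["min_length"],
    )
    rna = inputs["rna"]
    rna_prot = paired_spearman(rna, protein)
    cnv_prot = paired_spearman(cnv_genes, protein)
    io.write_table(rna_prot, results / "rna_protein_correlation.tsv")
    io.write_table(cnv_prot, results / "cnv_protein_correlation.tsv")
    record(results / "rna_protein_correlation.tsv")
    record(results / "cnv_protein_correlation.tsv")
    manifest["stages"]["integrate"] = {
        "mean_rna_protein_rho": round(float(rna_prot["rho"].mean(skipna=True)), 6),
        "n_rna_protein_pairs": int(rna_prot["rho"].notna().sum()),
    }

    if inputs["screen"] is None:
        manifest["notes"].append(
            "screen data unavailable; vulnerability cascade skipped"
        )
        manifest["stages"]["integrate"]["cascade"] = "skipped"
    else:
        # focal cluster: most significantly elevated proteins (ties: smallest)
        elevated_counts = {
            c: int((de["significant"] & (de["log2_fc"] > 0)).sum())
            for c, de in de_by_cluster.items()
        }
        focal = min(elevated_counts, key=lambda c: (-elevated_counts[c], c))
        cascade = vulnerability_cascade(
            cnv_prot,
            rna_prot,
            de_by_cluster[focal],
            inputs["screen"],
            rho_min=i_cfg["rho_min"],
            padj_max=i_cfg["padj_max"],
            rsa_max=i_cfg["rsa_max"],
            bf_min=i_cfg["bf_min"],
        )
        io.write_table(cascade.table(), results / "vulnerability_candidates.tsv")
        record(results / "vulnerability_candidates.tsv")
        manifest["stages"]["integrate"]["cascade"] = {
            "focal_cluster": int(focal),
            "n_primary": len(cascade.primary),
            "n_secondary": len(cascade.secondary),
        }

    # ---- survive ----------------------------------------------------------
    sv = config.survive
    survival = inputs["survival"]
    genes = select_variable_features(
        protein, n=min(sv["n_genes"], protein.shape[0])
    )
    omics = {"protein": protein, "rna": rna, "cnv": cnv_genes}
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for g in genes:
            row: dict = {"gene": g}
            for name, mat in omics.items():
                if g in mat.index:
                    loghr, se = _cox_row(survival, mat.loc[g], sv["min_events"])
                else:
                    loghr, se = np.nan, np.nan
                row[f"loghr_{name}"] = loghr
                row[f"se_{name}"] = se
            rows.append(row)
    per_omic = pd.DataFrame(rows).set_index("gene")
    meta = meta_analyze_genes(per_omic, q_threshold=sv["q_threshold"])
    io.write_table(meta.reset_index(), results / "survival_meta.tsv")
    record(results / "survival_meta.tsv")
    manifest["stages"]["survive"] = {
        "n_genes_tested": int(len(meta)),
        "n_selected": int(meta["selected"].sum()) if len(meta) else 0,
    }

    io.write_json(manifest, outdir / "manifest.json")
    return manifest
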