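"""Synthetic multi-omic tumor cohort generator with known ground truth.

The generator emulates the statistical structure of a multi-plex TMT
expression-proteomics study of a tumor cohort with matched RNA, targeted
mutation calls, array-based copy number segments, pooled knockdown screen
scores, and survival follow-up:

* a ``n_plexes x channels_per_plex`` isobaric-label design in which every
  plex carries ``tumors_per_plex`` tumors and ``pools_per_plex`` aliquots of
  a common reference pool, one of which is fixed in the first channel (the
  bridge channel);
* latent proteomic subtypes, each with its own differential protein
  program on the log2 scale;
* copy-number regions whose gain frequency differs by subtype, with
  cis dosage effects on protein and transcript for a small gene block;
* transcript abundances coupled to protein abundances so that the mean
  transcript-protein Spearman correlation hits a configurable target;
* subtype-biased mutation indicators, screen essentiality scores with
  planted hits, and exponential survival times tied to a few prognostic
  proteins.

Intensities are generated on the log2 scale and exponentiated to reporter
intensities at the PSM level; decoy PSMs are score-shifted null records so
the target-decoy FDR machinery can be exercised without sequence modeling.
Missingness is applied at the protein x plex level (all channels of a plex
missing together), matching the structure of real TMT missingness.

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io

TUMOR = "tumor"
POOL = "pool"

_MUTATION_GENE_COUNT = 5


def _pearson_for_spearman(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal whose Spearman rho is rho_s."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass
class CohortConfig:
    """Study-design and effect-size parameters of the synthetic cohort.

    Defaults mirror the cohort the pipeline is designed around: 108 tumors
    in 29 six-channel plexes (4 tumors + 2 pool replicates each, 116 tumor
    channel-slots and 58 pool slots in total), three latent subtypes at
    proportions 0.40/0.47/0.13, subtype programs of 1.0 log2 units, and a
    mean transcript-protein Spearman correlation of 0.38.
    """

    n_tumors: int = 108
    n_plexes: int = 29
    channels_per_plex: int = 6
    tumors_per_plex: int = 4
    pools_per_plex: int = 2

    n_proteins: int = 2000
    n_genes: int = 2000

    subtype_proportions: tuple[float, ...] = (0.40, 0.47, 0.13)
    program_size: int = 150
    de_effect_log2: float = 1.0
    focal_subtype: int = 1

    # variance components, all on the log2 scale
    protein_base_sd: float = 2.0
    sample_sd: float = 0.35      # per-sample biological deviation
    noise_sd: float = 0.25       # PSM-level residual noise per channel
    plex_shift_sd: float = 0.5   # per-plex global batch effect
    loading_sd: float = 0.2      # per-channel loading / mixing offset
    spectrum_sd: float = 0.5     # per-spectrum ionization offset

    psm_rate: float = 3.0                # Poisson mean spectra/protein/plex (min 1)
    peptides_per_protein: float = 4.0    # Poisson mean distinct peptides (min 2)
    single_peptide_fraction: float = 0.02
    decoy_fraction: float = 0.10
    target_score_mean: float = 5.0
    decoy_score_mean: float = 0.0
    score_sd: float = 1.0
    missing_rate: float = 0.05

    rna_protein_rho_target: float = 0.38
    dosage_rna_coupling: float = 0.85    # Pearson coupling for cis-dosage genes

    n_dosage: int = 20
    dosage_effect_log2: float = 1.2
    n_planted: int = 5
    focal_gain_prob: float = 0.7
    other_gain_prob: float = 0.1
    neutral_gain_prob: float = 0.3
    n_background_regions: int = 4
    background_alteration_prob: float = 0.15

    mutation_odds: Mapping[str, Sequence[float]] | None = None
    mutation_baseline: Mapping[str, float] | None = None

    n_cell_lines: int = 5
    n_prognostic: int = 10
    hazard_log: float = 0.5
    n_hazard_genes: int = 3
    median_survival_years: float = 5.0
    followup_years: tuple[float, float] = (1.0, 10.0)

    seed: int = 1234

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_proportions)

    def validate(self) -> list[str]:
        """Return a list of constraint violations (empty when valid)."""
        problems: list[str] = []
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            problems.append("subtype_proportions must sum to 1")
        if self.tumors_per_plex + self.pools_per_plex != self.channels_per_plex:
            problems.append("tumors_per_plex + pools_per_plex must equal channels_per_plex")
        for name in ("missing_rate", "decoy_fraction", "single_peptide_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.rna_protein_rho_target < 1.0):
            problems.append("rna_protein_rho_target must lie in [0, 1)")
        if self.n_tumors > self.n_plexes * self.tumors_per_plex:
            problems.append(
                f"cohort needs {self.n_tumors} tumor slots but the design provides "
                f"{self.n_plexes * self.tumors_per_plex}"
            )
        reserved = (
            self.n_subtypes * self.program_size
            + self.n_dosage + self.n_prognostic + _MUTATION_GENE_COUNT
        )
        if self.n_proteins < reserved:
            problems.append(
                f"n_proteins={self.n_proteins} too small for the configured gene "
                f"blocks (needs at least {reserved})"
            )
        if self.n_genes != self.n_proteins:
            problems.append("n_genes must equal n_proteins (one transcript per protein group)")
        if not (0 <= self.focal_subtype < self.n_subtypes):
            problems.append("focal_subtype out of range")
        if self.n_planted > self.n_dosage // 2:
            problems.append("n_planted must not exceed the focal dosage block (n_dosage/2)")
        return problems


class CohortSizingError(ValueError):
    """Raised when the plex design cannot accommodate the cohort."""


@dataclass
class PlexDesign:
    """Mapping plex -> channel -> sample and role, with the bridge channel.

    ``frame`` has columns ``plex`` (int), ``channel`` (int), ``sample`` (str)
    and ``role`` ('tumor' or 'pool'). ``reference_channel`` is the channel
    index holding the fixed reference pool in every plex (the ch-126 analog).
    """

    frame: pd.DataFrame
    reference_channel: int = 0

    @property
    def tumors(self) -> list[str]:
        mask = self.frame["role"] == TUMOR
        return sorted(self.frame.loc[mask, "sample"].unique())

    def plex_channels(self, plex: int) -> pd.DataFrame:
        return self.frame[self.frame["plex"] == plex].sort_values("channel")

    def reference_pool_sample(self, plex: int) -> str:
        rows = self.frame[
            (self.frame["plex"] == plex) & (self.frame["channel"] == self.reference_channel)
        ]
        return rows["sample"].iloc[0]


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort; consumed only by tests and QC."""

    subtype_label: pd.Series                  # sample -> subtype index
    true_de_proteins: dict[int, list[str]]    # subtype -> truly shifted proteins
    true_mutant_samples: dict[str, list[str]]
    true_cnv_states: pd.DataFrame             # region genes x samples, {-1,0,1}
    true_hazard_log: dict[str, float]
    protein_truth: pd.DataFrame               # proteins x tumors, true log2
    pool_profile: pd.Series                   # per-protein cohort-average log2
    planted_candidates: list[str]
    secondary_candidates: list[str]
    mutation_params: dict[str, dict]

    def to_json_dict(self) -> dict:
        return {
            "subtype_label": self.subtype_label.astype(int).to_dict(),
            "true_de_proteins": {str(k): v for k, v in self.true_de_proteins.items()},
            "true_mutant_samples": self.true_mutant_samples,
            "true_cnv_states": {
                g: self.true_cnv_states.loc[g].astype(int).to_dict()
                for g in self.true_cnv_states.index
            },
            "true_hazard_log": self.true_hazard_log,
            "planted_candidates": self.planted_candidates,
            "secondary_candidates": self.secondary_candidates,
            "mutation_params": self.mutation_params,
        }


@dataclass
class SyntheticCohort:
    """All artifacts of one simulated cohort."""

    config: CohortConfig
    design: PlexDesign
    psms: pd.DataFrame
    rna: pd.DataFrame
    mutations: pd.DataFrame
    cnv_segments: pd.DataFrame
    gene_models: pd.DataFrame
    screen: pd.DataFrame
    survival: pd.DataFrame
    truth: CohortTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_psms(self.psms, outdir / "psms.tsv")
        io.write_table(self.design.frame, outdir / "design.tsv")
        io.write_matrix(self.rna, outdir / "rna.tsv")
        io.write_table(self.mutations, outdir / "mutations.tsv")
        io.write_table(self.cnv_segments, outdir / "cnv_segments.tsv")
        self.gene_models[["chrom", "start", "end", "gene"]].to_csv(
            outdir / "gene_models.bed", sep="\t", index=False, header=False
        )
        io.write_table(self.screen, outdir / "screen.tsv")
        io.write_table(self.survival, outdir / "survival.tsv")
        io.write_json(self.truth.to_json_dict(), outdir / "truth.json")


# ---------------------------------------------------------------------------
# plex design


def generate_plex_design(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> PlexDesign:
    """Assign tumors and pool replicates to plex channels.

    Every plex receives ``pools_per_plex`` pool channels — one fixed in
    channel 0 (the bridge channel), the rest in randomly chosen channels —
    and ``tumors_per_plex`` tumor channels. Surplus tumor slots beyond
    ``n_tumors`` become replicate assignments of randomly chosen tumors
    (without replacement while possible), so a tumor is re-measured in at
    most one extra plex.
    """
    n_slots = config.n_plexes * config.tumors_per_plex
    if config.n_tumors > n_slots:
        raise CohortSizingError(
            f"{config.n_tumors} tumors require {config.n_tumors} tumor slots but the "
            f"design provides only {n_slots} "
            f"({config.n_plexes} plexes x {config.tumors_per_plex})"
        )
    problems = config.validate()
    if problems:
        raise ValueError("invalid cohort config: " + "; ".join(problems))
    if rng is None:
        rng = np.random.default_rng(config.seed)

    width = max(3, len(str(config.n_tumors)))
    tumors = np.array([f"T{i + 1:0{width}d}" for i in range(config.n_tumors)])
    surplus = n_slots - config.n_tumors
    if surplus:
        if surplus <= config.n_tumors:
            extra = rng.choice(tumors, size=surplus, replace=False)
        else:
            extra = rng.choice(tumors, size=surplus, replace=True)
        assignment = np.concatenate([tumors, extra])
    else:
        assignment = tumors.copy()

    # avoid placing a tumor twice in the same plex (bounded rejection)
    layout = None
    for _ in range(200):
        perm = rng.permutation(assignment)
        candidate = perm.reshape(config.n_plexes, config.tumors_per_plex)
        if all(len(set(row)) == len(row) for row in candidate):
            layout = candidate
            break
    if layout is None:  # pragma: no cover - essentially unreachable at sane sizes
        layout = perm.reshape(config.n_plexes, config.tumors_per_plex)

    rows = []
    for p in range(config.n_plexes):
        pool_channels = [0]
        if config.pools_per_plex > 1:
            others = rng.choice(
                np.arange(1, config.channels_per_plex),
                size=config.pools_per_plex - 1,
                replace=False,
            )
            pool_channels += sorted(int(c) for c in others)
        tumor_channels = [
            c for c in range(config.channels_per_plex) if c not in pool_channels
        ]
        for j, c in enumerate(pool_channels):
            rows.append((p, c, f"POOL_P{p:02d}_C{c}", POOL))
        for j, c in enumerate(tumor_channels):
            rows.append((p, c, layout[p, j], TUMOR))
    frame = pd.DataFrame(rows, columns=["plex", "channel", "sample", "role"])
    frame = frame.sort_values(["plex", "channel"], ignore_index=True)
    return PlexDesign(frame=frame, reference_channel=0)


# ---------------------------------------------------------------------------
# cohort generation


def _apportion(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of n into len(proportions) groups."""
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def _gene_blocks(config: CohortConfig) -> dict[str, np.ndarray]:
    """Index blocks reserved for subtype programs and special gene roles."""
    cursor = 0
    blocks: dict[str, np.ndarray] = {}
    for s in range(config.n_subtypes):
        blocks[f"program_{s}"] = np.arange(cursor, cursor + config.program_size)
        cursor += config.program_size
    half = config.n_dosage // 2
    blocks["dosage_focal"] = np.arange(cursor, cursor + half)
    blocks["dosage_neutral"] = np.arange(cursor + half, cursor + config.n_dosage)
    cursor += config.n_dosage
    blocks["prognostic"] = np.arange(cursor, cursor + config.n_prognostic)
    cursor += config.n_prognostic
    blocks["mutation"] = np.arange(cursor, cursor + _MUTATION_GENE_COUNT)
    return blocks


def _gene_models(config: CohortConfig, genes: np.ndarray) -> pd.DataFrame:
    """Toy genome: genes laid out sequentially on 4 chromosomes (0-based,
    half-open), 20 kb genes every 50 kb."""
    n = len(genes)
    per_chrom = int(np.ceil(n / 4))
    idx = np.arange(n)
    chrom = np.array([f"chr{c + 1}" for c in idx // per_chrom])
    start = (idx % per_chrom).astype(np.int64) * 50_000
    end = start + 20_000
    return pd.DataFrame({"gene": genes, "chrom": chrom, "start": start, "end": end})


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort: PSMs, RNA, mutations, CNV, screen, survival, truth."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid cohort config: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)
    design = generate_plex_design(config, rng)
    tumors = design.tumors
    n_t = len(tumors)

    # latent subtype labels with exact largest-remainder proportions
    counts = _apportion(n_t, config.subtype_proportions)
    labels = np.repeat(np.arange(config.n_subtypes), counts)
    rng.shuffle(labels)
    subtype = pd.Series(labels, index=tumors, name="subtype")

    width = max(4, len(str(config.n_proteins)))
    genes = np.array([f"G{i + 1:0{width}d}" for i in range(config.n_proteins)])
    blocks = _gene_blocks(config)
    gene_models = _gene_models(config, genes)

    # ---- copy number states per region -----------------------------------
    region_defs: list[tuple[str, np.ndarray, np.ndarray]] = []  # (name, gene idx, gain prob per sample)
    focal_mask = labels == config.focal_subtype
    p_focal = np.where(focal_mask, config.focal_gain_prob, config.other_gain_prob)
    region_defs.append(("region_focal", blocks["dosage_focal"], p_focal))
    region_defs.append(
        ("region_neutral", blocks["dosage_neutral"], np.full(n_t, config.neutral_gain_prob))
    )
    reserved = {i for b in blocks.values() for i in b}
    free = np.array([i for i in range(config.n_proteins) if i not in reserved])
    bg_width = 12
    for r in range(config.n_background_regions):
        anchor = free[rng.integers(0, max(1, len(free) - bg_width))]
        idxs = np.arange(anchor, min(anchor + bg_width, config.n_proteins))
        idxs = idxs[~np.isin(idxs, list(reserved))]
        if len(idxs) == 0:
            # anchor window fully consumed by earlier regions; skip it
            continue
        region_defs.append(
            (f"region_bg{r}", idxs, np.full(n_t, config.background_alteration_prob))
        )
        reserved.update(idxs)

    state = np.zeros((config.n_proteins, n_t), dtype=int)
    region_states: dict[str, np.ndarray] = {}
    for name, idxs, p_gain in region_defs:
        if name.startswith("region_bg"):
            u = rng.random(n_t)
            s = np.where(u < p_gain, 1, np.where(u < 2 * p_gain, -1, 0))
        else:
            s = (rng.random(n_t) < p_gain).astype(int)
        region_states[name] = s
        state[idxs] = s[None, :]

    # ---- true protein log2 matrix ----------------------------------------
    base = rng.normal(0.0, config.protein_base_sd, config.n_proteins)
    t_mat = np.tile(base[:, None], (1, n_t))
    for s in range(config.n_subtypes):
        t_mat[np.ix_(blocks[f"program_{s}"], np.where(labels == s)[0])] += config.de_effect_log2
    dosage_idx = np.concatenate([blocks["dosage_focal"], blocks["dosage_neutral"]])
    t_mat[dosage_idx] += config.dosage_effect_log2 * state[dosage_idx]
    if config.sample_sd > 0:
        t_mat += rng.normal(0.0, config.sample_sd, t_mat.shape)
    protein_truth = pd.DataFrame(t_mat, index=genes, columns=tumors)
    pool_profile = protein_truth.mean(axis=1)

    # ---- PSM table --------------------------------------------------------
    psms = _generate_psms(config, design, protein_truth, pool_profile, rng)

    # ---- RNA matrix -------------------------------------------------------
    z = t_mat - t_mat.mean(axis=1, keepdims=True)
    sd = t_mat.std(axis=1, ddof=0)
    nonconst = sd > 0
    z[nonconst] /= sd[nonconst, None]
    r = np.full(config.n_proteins, _pearson_for_spearman(config.rna_protein_rho_target))
    r[dosage_idx] = config.dosage_rna_coupling
    rna_base = rng.normal(5.0, 2.0, config.n_proteins)
    eps = rng.normal(0.0, 1.0, t_mat.shape)
    rna_mat = rna_base[:, None] + r[:, None] * z + np.sqrt(1 - r[:, None] ** 2) * eps
    rna = pd.DataFrame(rna_mat, index=genes, columns=tumors)

    # ---- mutations --------------------------------------------------------
    mut_genes = genes[blocks["mutation"]]
    odds_map: dict[str, np.ndarray] = {}
    base_map: dict[str, float] = {}
    if config.mutation_odds is None:
        default_or = np.ones(config.n_subtypes)
        default_or[config.focal_subtype] = 20.0
        odds_map[mut_genes[0]] = default_or
        base_map[mut_genes[0]] = 0.0175
        for g, b in zip(mut_genes[1:], (0.5, 0.15, 0.15, 0.15)):
            odds_map[g] = np.ones(config.n_subtypes)
            base_map[g] = b
    else:
        for g, ors in config.mutation_odds.items():
            if g not in set(genes):
                raise ValueError(f"mutation_odds names unknown gene {g!r}")
            odds_map[g] = np.asarray(ors, dtype=float)
            base_map[g] = (config.mutation_baseline or {}).get(g, 0.1)
    mut_rows = []
    mutant_samples: dict[str, list[str]] = {}
    for g, ors in odds_map.items():
        b = base_map[g]
        odds = b / (1 - b) * ors[labels]
        p = odds / (1 + odds)
        status = (rng.random(n_t) < p).astype(int)
        mutant_samples[g] = [t for t, s in zip(tumors, status) if s]
        mut_rows.extend((t, g, int(s)) for t, s in zip(tumors, status))
    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene", "status"])

    # ---- CNV segments -----------------------------------------------------
    seg_rows = []
    for name, idxs, _ in region_defs:
        sub = gene_models.iloc[idxs]
        chrom = sub["chrom"].iloc[0]
        start = int(sub["start"].min())
        end = int(sub["end"].max())
        n_probes = (end - start) // 800
        s = region_states[name]
        for j, tumor in enumerate(tumors):
            if s[j] != 0:
                log2 = 0.45 * s[j] + rng.normal(0.0, 0.05)
                seg_rows.append((tumor, chrom, start, end, n_probes, round(log2, 4)))
    # sub-threshold noise segments, dropped by the probe/length filters
    for tumor in tumors:
        for _ in range(2):
            chrom = f"chr{rng.integers(1, 5)}"
            pos = int(rng.integers(0, 20_000_000))
            if rng.random() < 0.5:
                length, n_probes = 24_000, 30          # fails both gates
            else:
                length, n_probes = 600_000, 40          # fails the probe gate
            log2 = float(np.round(rng.choice([-0.4, 0.4]), 4))
            seg_rows.append((tumor, chrom, pos, pos + length, n_probes, log2))
    cnv_segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "n_probes", "log2"]
    )

    # ---- screen scores ----------------------------------------------------
    lines = [f"CL{i + 1}" for i in range(config.n_cell_lines)]
    planted = list(genes[blocks["dosage_focal"][: config.n_planted]])
    secondary = list(genes[blocks[f"program_{config.focal_subtype}"][:2]])
    rsa = rng.normal(0.0, 1.0, (config.n_proteins, config.n_cell_lines))
    bf = rng.normal(0.0, 1.0, (config.n_proteins, config.n_cell_lines))
    ess_idx = np.array(
        [np.where(genes == g)[0][0] for g in planted + secondary]
    )
    rsa[ess_idx] = rng.normal(-5.0, 0.5, (len(ess_idx), config.n_cell_lines))
    bf[ess_idx] = rng.normal(6.0, 1.0, (len(ess_idx), config.n_cell_lines))
    screen = (
        pd.DataFrame(rsa, index=genes, columns=lines)
        .rename_axis("gene")
        .reset_index()
        .melt(id_vars="gene", var_name="cell_line", value_name="rsa")
    )
    screen["bayes_factor"] = (
        pd.DataFrame(bf, index=genes, columns=lines)
        .rename_axis("gene")
        .reset_index()
        .melt(id_vars="gene", var_name="cell_line", value_name="bf")["bf"]
    )

    # ---- survival ---------------------------------------------------------
    prog_genes = genes[blocks["prognostic"]]
    hazard = {g: 0.0 for g in prog_genes}
    for g in prog_genes[: config.n_hazard_genes]:
        hazard[g] = config.hazard_log
    lp = np.zeros(n_t)
    for g, beta in hazard.items():
        if beta:
            lp += beta * z[np.where(genes == g)[0][0]]
    rate = np.log(2) / config.median_survival_years * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    censor = rng.uniform(*config.followup_years, n_t)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    survival = pd.DataFrame(
        {"sample": tumors, "time_years": np.round(time, 6), "event": event}
    )

    true_de = {
        s: list(genes[blocks[f"program_{s}"]]) for s in range(config.n_subtypes)
    }
    true_de[config.focal_subtype] = (
        true_de[config.focal_subtype] + list(genes[blocks["dosage_focal"]])
    )
    region_gene_idx = np.concatenate([idxs for _, idxs, _ in region_defs])
    truth = CohortTruth(
        subtype_label=subtype,
        true_de_proteins=true_de,
        true_mutant_samples=mutant_samples,
        true_cnv_states=pd.DataFrame(
            state[region_gene_idx], index=genes[region_gene_idx], columns=tumors
        ),
        true_hazard_log={g: v for g, v in hazard.items()},
        protein_truth=protein_truth,
        pool_profile=pool_profile,
        planted_candidates=planted,
        secondary_candidates=secondary,
        mutation_params={
            g: {"baseline": base_map[g], "odds": list(map(float, odds_map[g]))}
            for g in odds_map
        },
    )
    return SyntheticCohort(
        config=config,
        design=design,
        psms=psms,
        rna=rna,
        mutations=mutations,
        cnv_segments=cnv_segments,
        gene_models=gene_models,
        screen=screen,
        survival=survival,
        truth=truth,
    )


def _generate_psms(
    config: CohortConfig,
    design: PlexDesign,
    protein_truth: pd.DataFrame,
    pool_profile: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Emit target and decoy PSMs for every plex (wide layout)."""
    genes = protein_truth.index.to_numpy()
    n_prot = len(genes)
    n_ch = config.channels_per_plex
    int_cols = io.intensity_columns(n_ch)

    # distinct peptide counts per protein (a small fraction single-peptide)
    n_pep = np.maximum(2, rng.poisson(config.peptides_per_protein, n_prot))
    single = rng.random(n_prot) < config.single_peptide_fraction
    n_pep[single] = 1

    frames = []
    for p in range(config.n_plexes):
        chans = design.plex_channels(p)
        # per-channel true log2 profile (tumor column or pool profile)
        profile = np.empty((n_prot, n_ch))
        for _, row in chans.iterrows():
            if row["role"] == POOL:
                profile[:, row["channel"]] = pool_profile.to_numpy()
            else:
                profile[:, row["channel"]] = protein_truth[row["sample"]].to_numpy()

        present = np.where(rng.random(n_prot) >= config.missing_rate)[0]
        n_spec = np.maximum(1, rng.poisson(config.psm_rate, len(present)))
        prot_rows = np.repeat(present, n_spec)
        total = len(prot_rows)

        pep_idx = rng.integers(0, n_pep[prot_rows])
        spec_off = rng.normal(0.0, config.spectrum_sd, total)
        plex_shift = rng.normal(0.0, config.plex_shift_sd)
        loading = rng.normal(0.0, config.loading_sd, n_ch)
        log2_int = (
            14.0
            + profile[prot_rows]
            + plex_shift
            + loading[None, :]
            + spec_off[:, None]
        )
        if config.noise_sd > 0:
            log2_int = log2_int + rng.normal(0.0, config.noise_sd, (total, n_ch))
        scores = rng.normal(config.target_score_mean, config.score_sd, total)

        frame = pd.DataFrame(
            {
                "plex": p,
                "spectrum_id": [f"P{p:02d}S{i:06d}" for i in range(total)],
                "peptide": [
                    f"{genes[g]}_pep{j}" for g, j in zip(prot_rows, pep_idx)
                ],
                "protein_group": genes[prot_rows],
                "decoy": False,
                "score": scores,
            }
        )
        frame[int_cols] = 2.0 ** log2_int
        frames.append(frame)

        n_dec = int(round(config.decoy_fraction * total))
        if n_dec:
            dec_prot = rng.integers(0, n_prot, n_dec)
            dec_pep = rng.integers(0, 3, n_dec)
            dec = pd.DataFrame(
                {
                    "plex": p,
                    "spectrum_id": [f"P{p:02d}D{i:06d}" for i in range(n_dec)],
                    "peptide": [
                        f"DECOY_{genes[g]}_pep{j}" for g, j in zip(dec_prot, dec_pep)
                    ],
                    "protein_group": [f"DECOY_{genes[g]}" for g in dec_prot],
                    "decoy": True,
                    "score": rng.normal(config.decoy_score_mean, config.score_sd, n_dec),
                }
            )
            dec[int_cols] = 2.0 ** (14.0 + rng.normal(0.0, 1.0, (n_dec, n_ch)))
            frames.append(dec)

    return pd.concat(frames, ignore_index=True)
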