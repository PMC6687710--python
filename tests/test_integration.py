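"""Tests for cross-omic integration: correlations, cascade, CNV reduction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sccproteo.association_stats import wilcoxon_de
from sccproteo.integration import (
    correlation_band_sets,
    differential_correlation,
    mean_rho,
    paired_spearman,
    summarize_cnv,
    tf_target_summary,
    vulnerability_cascade,
)
from sccproteo.psm_assembly import filter_by_observation, two_step_assembly
from sccproteo.synthetic_cohort import CohortConfig, generate_cohort
from sccproteo.tmt_bridge import bridge_cohort


# ---------------------------------------------------------------------------
# paired Spearman


def _matrix(rows: dict, columns) -> pd.DataFrame:
    return pd.DataFrame(rows, index=columns).T


def test_spearman_worked_examples():
    cols = list("abcde")
    x = _matrix({"f": [1, 2, 3, 4, 5]}, cols)
    y = _matrix({"f": [2, 1, 4, 3, 5]}, cols)
    rec = paired_spearman(x, y)
    # d = (1,-1,1,-1,0); rho = 1 - 6*4/(5*24) = 0.8
    assert rec.loc[0, "rho"] == pytest.approx(0.8)
    y2 = _matrix({"f": [10, 20, 30, 40, 50]}, cols)
    assert paired_spearman(x, y2).loc[0, "rho"] == pytest.approx(1.0)


def test_spearman_minimum_support_rule():
    cols = [f"s{i}" for i in range(20)]
    x = _matrix({"dense": np.arange(20.0), "sparse": [1.0] + [np.nan] * 19}, cols)
    y = _matrix({"dense": np.arange(20.0) ** 2, "sparse": np.arange(20.0)}, cols)
    rec = paired_spearman(x, y, min_fraction=0.10)
    assert list(rec["feature_x"]) == ["dense"]  # sparse pair skipped


def test_spearman_requires_shared_samples():
    x = pd.DataFrame({"a": [1.0]}, index=["f"])
    y = pd.DataFrame({"b": [1.0]}, index=["f"])
    with pytest.raises(ValueError, match="shared"):
        paired_spearman(x, y)


def test_mean_rho_and_band_boundaries():
    rec = pd.DataFrame(
        {
            "feature_x": list("abcdefg"),
            "feature_y": list("abcdefg"),
            "rho": [0.9, 0.5, 0.51, 0.2, -0.2, 0.0, -0.19],
        }
    )
    high, low = correlation_band_sets(rec)
    # strict inequalities: 0.5 excluded from high; +-0.2 excluded from low
    assert sorted(high["feature_x"]) == ["a", "c"]
    assert sorted(low["feature_x"]) == ["f", "g"]
    assert mean_rho(rec) == pytest.approx(np.mean(rec["rho"]))


# ---------------------------------------------------------------------------
# differential correlation


def test_differential_correlation_constructed(rng):
    n = 30
    cols = [f"s{i}" for i in range(2 * n)]
    anchor = rng.normal(size=2 * n)
    coupled = anchor.copy()
    coupled[n:] = rng.normal(size=n)  # follows the anchor only in group A
    uncoupled = rng.normal(size=2 * n)
    expr = pd.DataFrame(
        [anchor, coupled, uncoupled], index=["anchor", "coupled", "uncoupled"],
        columns=cols,
    )
    mask_a = np.arange(2 * n) < n
    res = differential_correlation(expr, "anchor", mask_a, ~mask_a)
    assert res.significant_a == ["coupled"]
    assert res.significant_b == []
    assert "coupled" in res.difference_set
    assert "uncoupled" not in res.difference_set


def test_differential_correlation_input_checks(rng):
    expr = pd.DataFrame(rng.normal(size=(3, 12)), index=list("abc"))
    with pytest.raises(ValueError, match="anchor"):
        differential_correlation(expr, "zzz", [True] * 6 + [False] * 6,
                                 [False] * 6 + [True] * 6)
    with pytest.raises(ValueError, match="5 samples"):
        differential_correlation(expr, "a", [True] * 2 + [False] * 10,
                                 [False] * 2 + [True] * 10)


def test_tf_target_summary_structure(rng):
    n = 24
    cols = [f"s{i}" for i in range(n)]
    genes = [f"g{i}" for i in range(15)]
    prot = pd.DataFrame(rng.normal(size=(15, n)), index=genes, columns=cols)
    rna = prot + rng.normal(0, 0.5, size=(15, n))
    labels = pd.Series([0] * 12 + [1] * 12, index=cols)
    out = tf_target_summary(
        rna, prot, {"setA": genes[:12]}, labels, compare=(0, 1)
    )
    assert {"mean_rho_0", "mean_rho_1", "p_compare"} <= set(out.columns)
    assert out.loc["setA", "mean_rho_0"] > 0.3
    with pytest.raises(ValueError, match="measured pairs"):
        tf_target_summary(rna, prot, {"tiny": genes[:3]}, labels)


# ---------------------------------------------------------------------------
# vulnerability cascade


@pytest.fixture(scope="module")
def cascade_cohort():
    config = CohortConfig(
        n_tumors=60, n_plexes=16, n_proteins=800, n_genes=800,
        program_size=80, seed=42,
    )
    cohort = generate_cohort(config)
    assembled = two_step_assembly(cohort.psms)
    protein = filter_by_observation(
        bridge_cohort(assembled.psms, cohort.design).matrix, 0.5
    )
    cnv_genes, _ = summarize_cnv(cohort.cnv_segments, cohort.gene_models)
    rna_prot = paired_spearman(cohort.rna, protein)
    cnv_prot = paired_spearman(cnv_genes, protein)
    labels = cohort.truth.subtype_label.loc[protein.columns]
    de = wilcoxon_de(protein, (labels == config.focal_subtype).to_numpy())
    return cohort, rna_prot, cnv_prot, de


def test_cascade_recovers_planted_candidates(cascade_cohort):
    cohort, rna_prot, cnv_prot, de = cascade_cohort
    res = vulnerability_cascade(cnv_prot, rna_prot, de, cohort.screen)
    assert res.primary == sorted(cohort.truth.planted_candidates)
    assert set(cohort.truth.secondary_candidates) <= set(res.secondary)
    for g in cohort.truth.planted_candidates + cohort.truth.secondary_candidates:
        assert res.confirmed[g]


def test_cascade_thresholds_are_monotone(cascade_cohort):
    cohort, rna_prot, cnv_prot, de = cascade_cohort
    loose = vulnerability_cascade(cnv_prot, rna_prot, de, cohort.screen,
                                  rho_min=0.3, rsa_max=-2.0)
    tight = vulnerability_cascade(cnv_prot, rna_prot, de, cohort.screen,
                                  rho_min=0.8, rsa_max=-4.5)
    assert set(tight.primary) <= set(loose.primary)
    assert tight.high_correlation <= loose.high_correlation
    assert tight.essential <= loose.essential


def test_cascade_disjoint_namespaces_raise(cascade_cohort):
    cohort, rna_prot, cnv_prot, de = cascade_cohort
    renamed = cohort.screen.copy()
    renamed["gene"] = "X_" + renamed["gene"]
    with pytest.raises(ValueError, match="namespaces"):
        vulnerability_cascade(cnv_prot, rna_prot, de, renamed)


# ---------------------------------------------------------------------------
# CNV segment reduction


def _gene_models_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _segments_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_probes", "log2"]
    )


def test_cnv_filter_gates_are_exact():
    genes = _gene_models_frame([("g1", "chr1", 100_000, 120_000)])
    segs = _segments_frame(
        [
            ("s1", "chr1", 0, 500_000, 49, 0.8),       # fails probe gate
            ("s2", "chr1", 0, 400_000, 50, 0.8),       # fails length gate (== min)
            ("s3", "chr1", 0, 400_001, 50, 0.8),       # passes both
        ]
    )
    values, counts = summarize_cnv(segs, genes)
    assert values.loc["g1", "s1"] == 0.0
    assert values.loc["g1", "s2"] == 0.0
    assert values.loc["g1", "s3"] == pytest.approx(0.8)
    assert counts.loc["g1", "n_gain"] == 1


def test_cnv_max_abs_reduction_picks_strongest_overlap():
    genes = _gene_models_frame([("g1", "chr1", 1_000_000, 1_020_000)])
    segs = _segments_frame(
        [
            ("s1", "chr1", 500_000, 1_010_000, 600, 0.3),
            ("s1", "chr1", 1_005_000, 2_000_000, 900, -0.9),
        ]
    )
    values, _ = summarize_cnv(segs, genes)
    assert values.loc["g1", "s1"] == pytest.approx(-0.9)
    weighted, _ = summarize_cnv(segs, genes, reduction="length_weighted")
    w1, w2 = 10_000, 15_000  # overlap lengths with the gene
    assert weighted.loc["g1", "s1"] == pytest.approx(
        (0.3 * w1 - 0.9 * w2) / (w1 + w2)
    )


def test_cnv_half_open_coordinates_do_not_overlap_at_touch():
    genes = _gene_models_frame([("g1", "chr1", 1_000_000, 1_020_000)])
    segs = _segments_frame(
        [("s1", "chr1", 500_000, 1_000_000, 600, 0.5)]  # ends where gene starts
    )
    values, _ = summarize_cnv(segs, genes)
    assert values.loc["g1", "s1"] == 0.0


def test_cnv_malformed_rows_rejected_with_warning():
    genes = _gene_models_frame([("g1", "chr1", 0, 20_000)])
    segs = _segments_frame(
        [
            ("s1", "chr1", 500_000, 400_000, 600, 0.5),  # end < start
            ("s1", "chr1", 0, 500_000, 0, 0.5),          # zero probes
            ("s1", "chr1", 0, 500_000, 600, 0.7),
        ]
    )
    with pytest.warns(UserWarning, match="malformed"):
        values, _ = summarize_cnv(segs, genes)
    assert values.loc["g1", "s1"] == pytest.approx(0.7)


def test_cnv_matches_brute_force_oracle(rng):
    """Random toy genome versus an independent loop-based overlap oracle."""
    genes = _gene_models_frame(
        [
            (f"g{i}", f"chr{rng.integers(1, 3)}",
             int(s := rng.integers(0, 5_000_000)), int(s + 20_000))
            for i in range(40)
        ]
    )
    seg_rows = []
    for i in range(120):
        start = int(rng.integers(0, 5_000_000))
        length = int(rng.integers(100_000, 1_500_000))
        seg_rows.append(
            (f"s{rng.integers(0, 4)}", f"chr{rng.integers(1, 3)}",
             start, start + length, int(rng.integers(10, 200)),
             float(np.round(rng.normal(0, 0.5), 3)))
        )
    segs = _segments_frame(seg_rows)
    values, _ = summarize_cnv(segs, genes)

    for _, g in genes.iterrows():
        for sample in values.columns:
            best = 0.0
            for _, seg in segs.iterrows():
                if (
                    seg["sample"] == sample
                    and seg["chrom"] == g["chrom"]
                    and seg["n_probes"] >= 50
                    and (seg["end"] - seg["start"]) > 400_000
                    and seg["start"] < g["end"]
                    and seg["end"] > g["start"]
                    and abs(seg["log2"]) > abs(best)
                ):
                    best = seg["log2"]
            assert values.loc[g["gene"], sample] == pytest.approx(best), (
                g["gene"], sample
            )


def test_cnv_result_invariant_to_segment_order(rng):
    genes = _gene_models_frame([("g1", "chr1", 0, 20_000), ("g2", "chr1", 3_000_000, 3_020_000)])
    segs = _segments_frame(
        [
            ("s1", "chr1", 0, 600_000, 100, 0.5),
            ("s1", "chr1", 2_900_000, 3_500_000, 100, -0.6),
            ("s1", "chr1", 0, 4_000_000, 500, 0.2),
        ]
    )
    a, _ = summarize_cnv(segs, genes)
    b, _ = summarize_cnv(segs.sample(frac=1.0, random_state=1).reset_index(drop=True), genes)
    pd.testing.assert_frame_equal(a, b)
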