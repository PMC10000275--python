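"""QC thresholds, TMM factors against the frozen edgeR oracle, CPM scaling,
detection filters and biotype composition summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snclock.datagen import SimConfig, generate_cohort
from snclock.preprocess import (
    AgeGrouping,
    DetectionRule,
    QCThresholds,
    composition_summary,
    cpm,
    detection_filter,
    qc_filter,
    tmm_factors,
)

DATA = Path(__file__).parent / "data"


def meta_row(transcriptome, total):
    return pd.DataFrame(
        {"transcriptome_reads": [transcriptome], "total_reads": [total], "age": [40]},
        index=["s1"],
    )


class TestQCFilter:
    @pytest.mark.parametrize(
        "transcriptome, total, kept",
        [
            (100_000, 150_000, True),  # 'minimum of 100,000' is inclusive
            (99_999, 150_000, False),
            (200_000, 400_000, False),  # ratio exactly 0.5 fails the strict rule
            (200_001, 400_000, True),
        ],
    )
    def test_boundaries(self, transcriptome, total, kept):
        retained, audit = qc_filter(meta_row(transcriptome, total))
        assert (retained == ["s1"]) is kept
        assert audit.loc["s1", "retained"] == kept

    def test_audit_names_failed_rule(self):
        _, audit = qc_filter(meta_row(50_000, 60_000))
        assert audit.loc["s1", "fail_reads"]
        assert not audit.loc["s1", "fail_ratio"]

    def test_missing_column_names_sample(self):
        meta = pd.DataFrame({"total_reads": [1]}, index=["odd_sample"])
        with pytest.raises(ValueError, match="transcriptome_reads"):
            qc_filter(meta)
        meta = meta_row(200_000, 400_000)
        meta.loc["s1", "total_reads"] = np.nan
        with pytest.raises(ValueError, match="s1"):
            qc_filter(meta)


def _oracle_counts():
    """Rebuild the seeded input the frozen edgeR oracle was computed on."""
    spec = json.loads((DATA / "tmm_oracle.json").read_text())
    rng = np.random.default_rng(spec["seed"])
    base = rng.lognormal(mean=3.0, sigma=1.2, size=spec["n_genes"])
    depth = rng.lognormal(mean=0.0, sigma=0.35, size=spec["n_samples"])
    mu = np.outer(base, depth)
    lam = rng.gamma(shape=5.0, scale=mu / 5.0)
    counts = rng.poisson(lam).astype(float)
    return pd.DataFrame(counts, columns=[f"s{i}" for i in range(spec["n_samples"])]), np.array(
        spec["factors"]
    )


class TestTMM:
    def test_identical_samples_unit_factors(self):
        col = np.array([10.0, 200.0, 3000.0, 5.0, 80.0])
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert np.allclose(tmm_factors(counts).to_numpy(), 1.0, atol=1e-12)

    def test_pure_depth_change_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(50, size=300).astype(float) + 1
        counts = pd.DataFrame({"a": a, "b": 3 * a})
        assert np.allclose(tmm_factors(counts).to_numpy(), 1.0, atol=1e-9)

    def test_matches_edger_reference(self):
        counts, expected = _oracle_counts()
        np.testing.assert_allclose(tmm_factors(counts).to_numpy(), expected, atol=1e-6)

    def test_geometric_mean_is_one(self):
        counts, _ = _oracle_counts()
        f = tmm_factors(counts).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_support_errors(self):
        counts = pd.DataFrame({"a": [5.0, 9.0, 0, 0], "b": [4.0, 8.0, 0, 0], "c": [0, 0, 3.0, 7.0]})
        with pytest.raises(ValueError, match="no positively expressed genes"):
            tmm_factors(counts)


class TestCPM:
    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(20, size=(50, 4)).astype(float))
        out = cpm(counts)
        np.testing.assert_allclose(out.sum(axis=0), 1e6, rtol=1e-12)

    def test_single_gene_value(self):
        counts = pd.DataFrame({"s": [50.0]})
        lib = pd.Series({"s": 1_000_000.0})
        assert cpm(counts, lib_sizes=lib).iloc[0, 0] == pytest.approx(50.0)

    def test_factor_scales_linearly(self):
        counts = pd.DataFrame({"s": [10.0, 30.0]})
        lib = pd.Series({"s": 1e6})
        one = cpm(counts, pd.Series({"s": 1.0}), lib)
        two = cpm(counts, pd.Series({"s": 2.0}), lib)
        np.testing.assert_allclose(two.to_numpy(), one.to_numpy() / 2)

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"s": [0.0]})
        with pytest.raises(ValueError, match="library size"):
            cpm(counts)


def _expr_meta(cpm_rows: dict, ages: list):
    samples = [f"s{i}" for i in range(len(ages))]
    expr = pd.DataFrame(cpm_rows, index=samples).T
    meta = pd.DataFrame({"age": ages}, index=samples)
    return expr, meta


class TestDetectionFilter:
    def test_examples(self):
        ages = [25, 25, 45, 45, 70, 70]
        expr, meta = _expr_meta(
            {"high": [12.0] * 6, "low": [5.0] * 6}, ages
        )
        assert detection_filter(expr, meta, rule=DetectionRule(10, 0.30)) == ["high"]
        assert detection_filter(expr, meta, rule=DetectionRule(1, 0.30)) == ["high", "low"]

    def test_three_of_ten_within_one_group_keeps(self):
        ages = [25] * 10
        vals = [11.0] * 3 + [0.0] * 7
        expr, meta = _expr_meta({"g": vals}, ages)
        grouping = AgeGrouping({"young": (20, 30)})
        assert detection_filter(expr, meta, grouping, DetectionRule(10, 0.30)) == ["g"]
        # one sample fewer above threshold: 2/10 < 0.30
        expr.iloc[0, 2] = 0.0
        assert detection_filter(expr, meta, grouping, DetectionRule(10, 0.30)) == []

    @settings(max_examples=30, derandomize=True)
    @given(
        min_cpm=st.floats(0.5, 20),
        bump=st.floats(0.1, 10),
        frac=st.floats(0.1, 0.9),
        dfrac=st.floats(0.01, 0.5),
    )
    def test_monotone_in_thresholds(self, min_cpm, bump, frac, dfrac):
        """Raising min_cpm or min_fraction never adds genes."""
        rng = np.random.default_rng(11)
        ages = list(rng.integers(20, 90, size=30))
        expr, meta = _expr_meta(
            {f"g{i}": rng.lognormal(1.5, 1.5, size=30) for i in range(15)}, ages
        )
        base = set(detection_filter(expr, meta, rule=DetectionRule(min_cpm, frac)))
        stricter_cpm = set(detection_filter(expr, meta, rule=DetectionRule(min_cpm + bump, frac)))
        stricter_frac = set(
            detection_filter(expr, meta, rule=DetectionRule(min_cpm, min(1.0, frac + dfrac)))
        )
        assert stricter_cpm <= base
        assert stricter_frac <= base

    def test_expressed_superset_of_highly_expressed(self, small_cohort):
        counts, meta, _ = small_cohort
        expr = cpm(counts)
        expressed = set(detection_filter(expr, meta, rule=DetectionRule(1, 0.30)))
        high = set(detection_filter(expr, meta, rule=DetectionRule(10, 0.30)))
        assert high <= expressed

    def test_empty_group_warns(self):
        ages = [25] * 4
        expr, meta = _expr_meta({"g": [12.0] * 4}, ages)
        with pytest.warns(UserWarning, match="empty"):
            kept = detection_filter(expr, meta, rule=DetectionRule(10, 0.3))
        assert kept == ["g"]


class TestAgeGrouping:
    def test_boundary_assignment(self):
        g = AgeGrouping()
        assert g.assign([30, 31, 60, 61, 99]).tolist() == [
            "young",
            "adult",
            "adult",
            "aged",
            "aged",
        ]

    def test_outside_interval_errors(self):
        with pytest.raises(ValueError, match="outside"):
            AgeGrouping().assign([12])

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            AgeGrouping({"a": (20, 40), "b": (35, 60)})


class TestCompositionSummary:
    def test_single_biotype_share_is_one(self):
        ages = [25, 25, 45, 45, 70, 70]
        expr, meta = _expr_meta({"g1": [20.0] * 6, "g2": [30.0] * 6}, ages)
        bio = pd.Series({"g1": "miRNA", "g2": "miRNA"})
        out = composition_summary(expr, bio, meta)
        assert np.allclose(out["cpm_share"], 1.0)
        assert np.allclose(out["gene_share"], 1.0)

    def test_equal_cpm_splits_half(self):
        ages = [25, 25, 45, 45, 70, 70]
        expr, meta = _expr_meta({"g1": [25.0] * 6, "g2": [25.0] * 6}, ages)
        bio = pd.Series({"g1": "miRNA", "g2": "tRNA"})
        out = composition_summary(expr, bio, meta)
        assert np.allclose(out["cpm_share"], 0.5)

    def test_trend_cohort_mirna_share_falls_with_age(self, small_cohort):
        counts, meta, truth = small_cohort
        expr = cpm(counts, tmm_factors(counts))
        out = composition_summary(expr, truth.genes["biotype"], meta)
        piv = out.pivot(index="group", columns="biotype", values="cpm_share")
        assert piv.loc["aged", "miRNA"] < piv.loc["young", "miRNA"]
        assert piv.loc["aged", "tRNA"] > piv.loc["young", "tRNA"]

    def test_missing_biotype_errors(self):
        ages = [25, 25, 45, 45, 70, 70]
        expr, meta = _expr_meta({"g1": [25.0] * 6}, ages)
        with pytest.raises(ValueError, match="biotype"):
            composition_summary(expr, pd.Series(dtype=object), meta)


def test_thresholds_validate():
    with pytest.raises(ValueError):
        QCThresholds(min_transcriptome_reads=0)
    with pytest.raises(ValueError):
        DetectionRule(min_cpm=0)
    with pytest.raises(ValueError):
        DetectionRule(min_fraction=1.5)
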