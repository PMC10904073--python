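"""Per-profile preprocessing against brute-force group-by oracles."""

import numpy as np
import pandas as pd
import pytest

from gemresponse.profiles import (
    OmicsProfile,
    aggregate_probes_to_islands,
    aggregate_segments_to_genes,
    concatenate_profiles,
    drop_incomplete_features,
    encode_clinical,
    log2_rpm,
)


def _profile(values, kind="mirna_log2rpm", samples=None, features=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"S{i}" for i in range(values.shape[0])]
    features = features or [f"f{j}" for j in range(values.shape[1])]
    return OmicsProfile(pd.DataFrame(values, index=samples, columns=features), kind=kind)


class TestOmicsProfileInvariants:
    def test_duplicate_feature_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            _profile(np.zeros((2, 2)), features=["a", "a"])

    def test_beta_range_enforced(self):
        with pytest.raises(ValueError, match="0, 1"):
            _profile([[0.2, 1.4]], kind="cpg_beta")

    def test_fpkm_nonnegative_enforced(self):
        with pytest.raises(ValueError, match="non-negative"):
            _profile([[-1.0, 2.0]], kind="fpkm")


class TestDropIncompleteFeatures:
    def test_columns_with_missing_removed(self):
        values = np.arange(15, dtype=float).reshape(3, 5)
        values[0, 1] = np.nan
        values[2, 3] = np.nan
        out = drop_incomplete_features(_profile(values))
        assert out.feature_ids == ["f0", "f2", "f4"]
        assert out.n_samples == 3

    def test_fully_observed_unchanged(self):
        profile = _profile(np.ones((3, 4)))
        out = drop_incomplete_features(profile)
        pd.testing.assert_frame_equal(out.values, profile.values)

    def test_random_mask_count_matches_independent_count(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(20, 1000))
        mask = rng.random(values.shape) < 0.1
        values[mask] = np.nan
        expected = int((~mask.any(axis=0)).sum())
        out = drop_incomplete_features(_profile(values))
        assert out.n_features == expected

    def test_all_removed_raises(self):
        with pytest.raises(ValueError):
            drop_incomplete_features(_profile([[np.nan], [1.0]]))


class TestLog2Rpm:
    def test_exact_values(self):
        out = log2_rpm(_profile([[8.0, 0.0]], kind="mirna_log2rpm"), pseudocount=0)
        assert out.values.iloc[0, 0] == 3.0
        out = log2_rpm(_profile([[0.0]]), pseudocount=1)
        assert out.values.iloc[0, 0] == 0.0

    def test_round_trip_to_machine_precision(self):
        rng = np.random.default_rng(1)
        raw = rng.exponential(50.0, size=(10, 30))
        out = log2_rpm(_profile(raw), pseudocount=1.0)
        back = 2 ** out.values.to_numpy() - 1.0
        np.testing.assert_allclose(back, raw, rtol=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log2_rpm(_profile([[-0.5]]))


class TestProbeIslandAggregation:
    def test_two_probe_island_mean(self):
        profile = _profile([[0.2, 0.4]], kind="cpg_beta", features=["p1", "p2"])
        out = aggregate_probes_to_islands(profile, {"p1": "isl1", "p2": "isl1"})
        assert out.values.iloc[0, 0] == pytest.approx(0.3)
        assert out.kind == "cgi_beta"

    def test_singleton_island_passes_through(self):
        profile = _profile([[0.7, 0.1]], kind="cpg_beta", features=["p1", "p2"])
        out = aggregate_probes_to_islands(profile, {"p1": "isl1"})
        assert out.feature_ids == ["isl1"]
        assert out.values.iloc[0, 0] == pytest.approx(0.7)

    def test_matches_brute_force_group_mean(self):
        rng = np.random.default_rng(2)
        probes = [f"cg{i:05d}" for i in range(200)]
        island_map = {p: f"island_{rng.integers(0, 40):02d}" for p in probes}
        values = rng.random((15, 200))
        profile = _profile(values, kind="cpg_beta", features=probes)
        out = aggregate_probes_to_islands(profile, island_map)
        # brute-force oracle: explicit per-island mean loop
        for island in sorted(set(island_map.values())):
            members = [i for i, p in enumerate(probes) if island_map[p] == island]
            expected = values[:, members].mean(axis=1)
            np.testing.assert_allclose(out.values[island].to_numpy(), expected, atol=1e-12)

    def test_empty_map_rejected(self):
        profile = _profile([[0.5]], kind="cpg_beta", features=["p1"])
        with pytest.raises(ValueError):
            aggregate_probes_to_islands(profile, {})


def _segments(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "value"])


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class TestSegmentAggregation:
    def test_gene_inside_single_segment(self):
        segments = _segments([("S1", "chr1", 0, 1000, 0.7)])
        genes = _genes([("g1", "chr1", 100, 200)])
        for stat in ("mean", "median"):
            out = aggregate_segments_to_genes(segments, genes, stat=stat)
            assert out.values.loc["S1", "g1"] == pytest.approx(0.7)

    def test_gene_over_three_segments_mean_vs_median(self):
        segments = _segments(
            [
                ("S1", "chr1", 0, 100, 0.2),
                ("S1", "chr1", 100, 200, 0.8),
                ("S1", "chr1", 200, 300, 0.8),
            ]
        )
        genes = _genes([("g1", "chr1", 50, 250)])
        assert aggregate_segments_to_genes(segments, genes, "mean").values.loc[
            "S1", "g1"
        ] == pytest.approx(0.6)
        assert aggregate_segments_to_genes(segments, genes, "median").values.loc[
            "S1", "g1"
        ] == pytest.approx(0.8)

    def test_no_overlap_gives_missing(self):
        segments = _segments([("S1", "chr1", 0, 100, 1.0)])
        genes = _genes([("g1", "chr1", 500, 600), ("g2", "chr2", 0, 100)])
        out = aggregate_segments_to_genes(segments, genes)
        assert out.values.loc["S1"].isna().all()

    def test_half_open_boundary_touch_is_not_overlap(self):
        segments = _segments([("S1", "chr1", 0, 100, 1.0)])
        genes = _genes([("g1", "chr1", 100, 200)])
        out = aggregate_segments_to_genes(segments, genes)
        assert np.isnan(out.values.loc["S1", "g1"])

    def test_malformed_interval_rejected(self):
        segments = _segments([("S1", "chr1", 100, 100, 1.0)])
        genes = _genes([("g1", "chr1", 0, 50)])
        with pytest.raises(ValueError):
            aggregate_segments_to_genes(segments, genes)


class TestConcatenateProfiles:
    def test_column_count_additivity(self):
        samples = [f"S{i}" for i in range(5)]
        a = _profile(np.ones((5, 4)), kind="fpkm", samples=samples)
        b = _profile(np.zeros((5, 3)), kind="clinical", samples=samples)
        out = concatenate_profiles([a, b])
        assert out.n_features == 7
        assert out.kind == "fpkm+clinical"
        assert all(":" in f for f in out.feature_ids)

    def test_inner_join_on_sample_intersection(self):
        a = _profile(np.ones((5, 2)), kind="fpkm", samples=[f"S{i}" for i in range(5)])
        b = _profile(np.zeros((7, 2)), kind="cpg_beta", samples=[f"S{i}" for i in range(2, 9)])
        out = concatenate_profiles([a, b])
        assert out.sample_ids == ["S2", "S3", "S4"]

    def test_self_concatenation_doubles_columns(self):
        samples = ["S0", "S1"]
        a = _profile([[1.0, 2.0], [3.0, 4.0]], kind="fpkm", samples=samples)
        b = _profile([[1.0, 2.0], [3.0, 4.0]], kind="fpkm_uq", samples=samples)
        out = concatenate_profiles([a, b])
        assert out.n_features == 4
        np.testing.assert_array_equal(
            out.values.to_numpy()[:, :2], out.values.to_numpy()[:, 2:]
        )

    def test_empty_intersection_rejected(self):
        a = _profile(np.ones((2, 2)), samples=["A1", "A2"])
        b = _profile(np.ones((2, 2)), kind="fpkm", samples=["B1", "B2"])
        with pytest.raises(ValueError):
            concatenate_profiles([a, b])


class TestEncodeClinical:
    def test_one_hot_and_numeric_passthrough(self):
        table = pd.DataFrame(
            {"age": [60.0, 70.0], "stage": ["II", "III"]}, index=["P1", "P2"]
        )
        out = encode_clinical(table)
        assert out.kind == "clinical"
        assert "age" in out.feature_ids
        assert {"stage=II", "stage=III"} <= set(out.feature_ids)
        assert out.values.loc["P1", "stage=II"] == 1.0
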