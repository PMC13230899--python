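"""Feature extraction: readers, statistics oracles, purity estimator,
group assembly and intra-group correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from snvpurify import features as ft


def brute_force_overlap(records, intervals):
    """Independent double-loop membership count."""
    hits = 0
    for r in records:
        pos0 = r.pos - 1
        if any(c == r.chrom and s <= pos0 < e for c, s, e in intervals):
            hits += 1
    return hits / len(records)


# -- readers ----------------------------------------------------------------

def test_read_vcf_empty(tmp_path):
    p = tmp_path / "empty.vcf"
    p.write_text("##fileformat=VCFv4.2\n"
                 '##contig=<ID=chrS,length=1000>\n'
                 '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
                 '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n")
    assert ft.read_vcf(p) == []


def test_read_vcf_handcrafted_vafs(tmp_path):
    p = tmp_path / "three.vcf"
    lines = ["##fileformat=VCFv4.2",
             '##contig=<ID=chr1,length=1000>',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">',
             '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS"]
    for pos in (10, 20, 30):
        lines.append(f"chr1\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT:DP:AD\t0/1:100:50,50")
    p.write_text("\n".join(lines) + "\n")
    records = ft.read_vcf(p)
    assert len(records) == 3
    assert all(r.vaf == 0.5 for r in records)


def test_read_vcf_splits_multiallelic_and_skips_indels(tmp_path):
    p = tmp_path / "mixed.vcf"
    lines = ["##fileformat=VCFv4.2",
             '##contig=<ID=chr1,length=1000>',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">',
             '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS",
             "chr1\t5\t.\tA\tG,T\t.\tPASS\t.\tGT:DP:AD\t1/2:90:30,40,20",
             "chr1\t9\t.\tAT\tA\t.\tPASS\t.\tGT:DP:AD\t0/1:50:25,25"]
    p.write_text("\n".join(lines) + "\n")
    records = ft.read_vcf(p)
    assert [(r.pos, r.alt, r.alt_count) for r in records] == [(5, "G", 40), (5, "T", 20)]


def test_read_bed_merges_overlaps(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t10\t20\nchr1\t15\t30\n")
    track = ft.read_bed(p, "repeat")
    assert track.intervals == [("chr1", 10, 30)]


def test_read_bed_empty_and_malformed(tmp_path):
    empty = tmp_path / "empty.bed"
    empty.write_text("")
    assert ft.read_bed(empty, "dnase").intervals == []
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t20\t10\n")
    with pytest.raises(ValueError, match="bad.bed:1"):
        ft.read_bed(bad, "dnase")


def test_track_membership_equals_brute_force(tmp_path):
    rng = np.random.default_rng(17)
    intervals = []
    for _ in range(100):
        s = int(rng.integers(0, 99_000))
        intervals.append(("chrS", s, s + int(rng.integers(1, 500))))
    track = ft.AnnotationTrack("repeat", list(intervals))
    positions = rng.integers(0, 100_000, size=1000)
    expected = np.array([
        any(s <= p < e for _, s, e in intervals) for p in positions
    ])
    np.testing.assert_array_equal(track.contains("chrS", positions), expected)
    assert not track.contains("chrX", positions).any()


# -- overlap fraction -------------------------------------------------------

def test_overlap_fraction_hand_count(records_factory):
    track = ft.AnnotationTrack("repeat", [("chrS", 10, 20)])
    records = [records_factory(p) for p in (5, 15, 25)]
    assert ft.overlap_fraction(records, track) == pytest.approx(1 / 3)


def test_overlap_fraction_empty_track(records_factory):
    records = [records_factory(5)]
    assert ft.overlap_fraction(records, ft.AnnotationTrack("repeat")) == 0.0


def test_overlap_fraction_matches_brute_force(random_record_sets):
    for recs, ivs in random_record_sets:
        track = ft.AnnotationTrack("repeat", list(ivs))
        assert ft.overlap_fraction(recs, track) == brute_force_overlap(recs, ivs)


def test_overlap_invariant_to_interval_splitting(records_factory):
    records = [records_factory(p) for p in range(1, 60, 3)]
    whole = ft.AnnotationTrack("repeat", [("chrS", 10, 40)])
    # split at positions where no record sits (record 0-based positions are even here)
    split = ft.AnnotationTrack("repeat", [("chrS", 10, 17), ("chrS", 17, 25),
                                          ("chrS", 25, 40)])
    assert ft.overlap_fraction(records, whole) == ft.overlap_fraction(records, split)


# -- VAF/depth statistics ----------------------------------------------------

def test_vaf_stats_constant_input(records_factory):
    records = [records_factory(p, vaf=0.5) for p in (1, 2, 3)]
    stats = ft.vaf_depth_stats(records)
    names = ft.GROUP_FEATURES["depth_vaf_stats"]
    s = dict(zip(names, stats))
    assert s["vaf_mean"] == s["vaf_median"] == 0.5
    assert s["vaf_std"] == 0.0
    assert s["empty_indicator"] == 0.0


def test_vaf_stats_simple_sequence(records_factory):
    records = [records_factory(i + 1, vaf=v, depth=10) for i, v in
               enumerate([0.1, 0.2, 0.3, 0.4])]
    s = dict(zip(ft.GROUP_FEATURES["depth_vaf_stats"], ft.vaf_depth_stats(records)))
    assert s["vaf_mean"] == pytest.approx(0.25)
    assert s["vaf_median"] == pytest.approx(0.25)


def test_vaf_stats_empty_input_indicator():
    stats = ft.vaf_depth_stats([])
    assert stats[-1] == 1.0 and np.all(stats[:-1] == 0.0)


def test_vaf_depth_stats_match_direct_recomputation(random_record_sets):
    for recs, _ in random_record_sets:
        got = ft.vaf_depth_stats(recs)
        vafs = np.array([r.alt_count / r.depth for r in recs])
        depths = np.array([float(r.depth) for r in recs])
        expected = [vafs.mean(), np.median(vafs), vafs.std(),
                    np.quantile(vafs, 0.1), np.quantile(vafs, 0.9),
                    depths.mean(), np.median(depths), depths.std(), 0.0]
        np.testing.assert_allclose(got, expected, rtol=0, atol=1e-12)


# -- purity estimator --------------------------------------------------------

@pytest.mark.parametrize("vaf,expected", [(0.5, 1.0), (0.15, 0.30), (0.6, 1.0)])
def test_estimate_purity_known_values(records_factory, vaf, expected):
    records = [records_factory(p, vaf=vaf) for p in (1, 2, 3)]
    assert ft.estimate_purity(records) == pytest.approx(expected)


def test_estimate_purity_fallback_outside_window(records_factory):
    records = [records_factory(p, vaf=0.9, depth=10) for p in (1, 2, 3)]
    est, fallback = ft.estimate_purity_flagged(records)
    assert fallback
    assert est == 1.0  # 2 * 0.9 clipped


@given(scale=st.integers(min_value=2, max_value=50))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_estimate_purity_scale_free_in_depth(scale):
    base = [ft.VariantRecord("chrS", p, "A", "C", 20, a)
            for p, a in [(1, 3), (2, 5), (3, 8), (4, 2)]]
    scaled = [ft.VariantRecord("chrS", r.pos, r.ref, r.alt,
                               r.depth * scale, r.alt_count * scale) for r in base]
    assert ft.estimate_purity(base) == ft.estimate_purity(scaled)


# -- group assembly ----------------------------------------------------------

def test_group_vector_shapes_are_stable(small_cohort):
    for sid in list(small_cohort.samples)[:10]:
        fgs = ft.build_feature_groups(small_cohort.samples[sid], small_cohort.tracks)
        for g, dim in ft.GROUP_DIMS.items():
            assert fgs.group(g).shape == (dim,)
    assert tuple(ft.GROUP_DIMS[g] for g in ft.GROUP_NAMES) == (9, 4, 5, 5, 5)


def test_empty_tracks_zero_fractions(small_cohort, empty_tracks):
    sid = next(iter(small_cohort.samples))
    fgs = ft.build_feature_groups(small_cohort.samples[sid], empty_tracks)
    assert fgs.repeat_region[0] == 0.0
    assert fgs.dnase_region[0] == 0.0
    assert fgs.blacklist_region[0] == 0.0


def test_missing_track_raises(small_cohort):
    sid = next(iter(small_cohort.samples))
    with pytest.raises(KeyError, match="blacklist"):
        ft.build_feature_groups(small_cohort.samples[sid],
                                {"repeat": ft.AnnotationTrack("repeat"),
                                 "dnase": ft.AnnotationTrack("dnase")})


def test_purity_estimate_recovers_pure_sample():
    from snvpurify.simulate import SimulationConfig, simulate_cohort
    cfg = SimulationConfig(n_samples=5, purity_range=(1.0, 1.0),
                           true_count_range=(300, 500), mean_depth=150.0,
                           fp_rate_at_min_purity=0.0, fn_rate_at_min_purity=0.0,
                           seed=8)
    cohort = simulate_cohort(cfg)
    for sid, records in cohort.samples.items():
        fgs = ft.build_feature_groups(records, cohort.tracks)
        assert fgs.purity_basic[0] == pytest.approx(1.0, abs=0.05)


def test_feature_table_round_trip(small_cohort):
    fsets = {sid: ft.build_feature_groups(recs, small_cohort.tracks)
             for sid, recs in list(small_cohort.samples.items())[:5]}
    df = ft.feature_table(fsets)
    back = ft.feature_sets_from_table(df)
    for sid in fsets:
        for g in ft.GROUP_NAMES:
            np.testing.assert_array_equal(fsets[sid].group(g), back[sid].group(g))


# -- correlations ------------------------------------------------------------

def _feature_sets_from_matrix(rng, n):
    sets = []
    for _ in range(n):
        sets.append(ft.FeatureGroupSet(
            depth_vaf_stats=rng.normal(size=9),
            purity_basic=rng.normal(size=4),
            repeat_region=rng.normal(size=5),
            dnase_region=rng.normal(size=5),
            blacklist_region=rng.normal(size=5),
        ))
    return sets


def test_correlation_requires_three_samples():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        ft.intra_group_correlation(_feature_sets_from_matrix(rng, 2))


def test_duplicated_feature_correlates_perfectly():
    rng = np.random.default_rng(1)
    sets = _feature_sets_from_matrix(rng, 50)
    for s in sets:
        s.depth_vaf_stats[1] = s.depth_vaf_stats[0]  # duplicate a column
    corr = ft.intra_group_correlation(sets)["depth_vaf_stats"]
    assert corr.iloc[0, 1] == pytest.approx(1.0)


def test_independent_columns_nearly_uncorrelated():
    rng = np.random.default_rng(2)
    sets = _feature_sets_from_matrix(rng, 1000)
    corr = ft.intra_group_correlation(sets)["purity_basic"].to_numpy()
    off = corr[~np.eye(4, dtype=bool)]
    assert np.nanmax(np.abs(off)) < 0.1


def test_correlation_symmetric_unit_diagonal_constant_flagged():
    rng = np.random.default_rng(3)
    sets = _feature_sets_from_matrix(rng, 30)
    for s in sets:
        s.repeat_region[3] = 0.0  # constant indicator column
    mats = ft.intra_group_correlation(sets)
    for mat in mats.values():
        arr = mat.to_numpy()
        assert np.array_equal(arr, arr.T, equal_nan=True)
        np.testing.assert_array_equal(np.diag(arr), 1.0)
        assert np.all((np.abs(arr) <= 1.0) | np.isnan(arr))
    rep = mats["repeat_region"].to_numpy()
    assert np.isnan(rep[3, 0]) and np.isnan(rep[0, 3])  # flagged, not zeroed
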