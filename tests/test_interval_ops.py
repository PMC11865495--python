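import numpy as np
import pytest
from scipy import stats

from centrokit import interval_ops as iops
from centrokit.interval_ops import Interval, IntervalSet

from _oracles import consensus_oracle


def iset(*triples):
    return IntervalSet([Interval("chr", s, e) for s, e in triples])


# ---------------------------------------------------------------------------
# IntervalSet basics
# ---------------------------------------------------------------------------

def test_interval_validation():
    with pytest.raises(ValueError):
        Interval("chr", 10, 10)
    with pytest.raises(ValueError):
        Interval("chr", -1, 5)


def test_bed_round_trip(tmp_path):
    s = IntervalSet(
        [Interval("chr2", 5, 9, "b"), Interval("chr1", 0, 10, "a")]
    )
    path = tmp_path / "x.bed"
    s.to_bed(path)
    back = IntervalSet.from_bed(path)
    assert [(r.chrom, r.start, r.end, r.name) for r in back] == [
        ("chr1", 0, 10, "a"),
        ("chr2", 5, 9, "b"),
    ]


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_consensus_example():
    # per-base coverage sweep oracle confirms {[50,100), [120,150)}
    sets = [iset((0, 100)), iset((50, 150)), iset((120, 200))]
    assert consensus_oracle(
        [[(0, 100)], [(50, 150)], [(120, 200)]], 2, 250
    ) == [(50, 100), (120, 150)]
    result = iops.consensus_intervals(sets, 2)
    assert [(r.start, r.end) for r in result] == [(50, 100), (120, 150)]


def test_consensus_identical_sets():
    sets = [iset((0, 100))] * 3
    assert [(r.start, r.end) for r in iops.consensus_intervals(sets, 2)] == [(0, 100)]


def test_consensus_single_set_empty():
    assert len(iops.consensus_intervals([iset((0, 100))], 2)) == 0


def test_consensus_bookended_runs_merge():
    # support-2 region [40,60) from A&B abuts [60,80) from A&C
    sets = [iset((40, 80)), iset((40, 60)), iset((60, 80))]
    result = iops.consensus_intervals(sets, 2)
    assert [(r.start, r.end) for r in result] == [(40, 80)]


def test_consensus_self_overlap_does_not_count_twice():
    # one replicate with two overlapping peaks must not reach support 2
    sets = [iset((0, 50), (25, 100)), iset((500, 600))]
    assert len(iops.consensus_intervals(sets, 2)) == 0


def test_consensus_min_support_validation():
    with pytest.raises(ValueError):
        iops.consensus_intervals([iset((0, 10))], 0)


def test_consensus_random_oracle():
    rng = np.random.default_rng(42)
    for _ in range(30):
        n_sets = rng.integers(2, 5)
        length = 2000
        raw, sets = [], []
        for _ in range(n_sets):
            ivs = []
            for _ in range(rng.integers(0, 8)):
                s = int(rng.integers(0, length - 50))
                e = s + int(rng.integers(1, 300))
                ivs.append((s, min(e, length)))
            raw.append(ivs)
            sets.append(iset(*ivs) if ivs else IntervalSet())
        support = int(rng.integers(1, n_sets + 1))
        expected = consensus_oracle(raw, support, length)
        got = [(r.start, r.end) for r in iops.consensus_intervals(sets, support)]
        assert got == expected


# ---------------------------------------------------------------------------
# venn
# ---------------------------------------------------------------------------

def test_venn_identical_sets():
    a = iset((0, 10), (20, 30), (40, 50))
    counts = iops.overlap_venn(a, a)
    assert counts["A_only"] == 0 and counts["B_only"] == 0
    assert counts["shared"] == 3


def test_venn_disjoint_sets():
    counts = iops.overlap_venn(iset((0, 10), (20, 30)), iset((100, 110)))
    assert counts == {
        "A_only": 2, "B_only": 1, "shared": 0,
        "A_overlapping": 0, "B_overlapping": 0,
    }


def test_venn_many_to_one_collapses():
    # one A interval overlapped by two B intervals: one shared event
    counts = iops.overlap_venn(iset((0, 100)), iset((10, 20), (50, 60)))
    assert counts["A_only"] == 0 and counts["B_only"] == 0
    assert counts["shared"] == 1
    assert counts["A_overlapping"] == 1 and counts["B_overlapping"] == 2


def test_venn_chain_component():
    # A1-B1-A2 chain is a single component
    counts = iops.overlap_venn(iset((0, 10), (15, 25)), iset((5, 20)))
    assert counts["shared"] == 1


# ---------------------------------------------------------------------------
# categorize
# ---------------------------------------------------------------------------

def test_categorize_examples():
    pbrm1 = iset((0, 10), (20, 30))
    parental = iset((0, 10))
    ko = iset((25, 35), (100, 110))
    result = iops.categorize_peaks(pbrm1, parental, ko)
    assert [(r.start, r.end) for r in result.specific] == [(0, 10)]
    assert [(r.start, r.end) for r in result.non_specific] == [(20, 30)]
    assert [(r.start, r.end) for r in result.ko_specific] == [(100, 110)]


def test_categorize_empty_ko():
    pbrm1 = iset((0, 10), (20, 30))
    result = iops.categorize_peaks(pbrm1, iset((0, 10)), IntervalSet())
    assert len(result.specific) == 2
    assert len(result.non_specific) == 0
    assert len(result.ko_specific) == 0


def test_categorize_partition_identity():
    rng = np.random.default_rng(3)
    for _ in range(20):
        def random_set():
            ivs = []
            for _ in range(rng.integers(1, 15)):
                s = int(rng.integers(0, 5000))
                ivs.append((s, s + int(rng.integers(1, 200))))
            return iset(*ivs)

        pbrm1 = random_set()
        result = iops.categorize_peaks(pbrm1, random_set(), random_set())
        assert len(result.specific) + len(result.non_specific) == len(pbrm1)


def test_categorize_lax_flag():
    pbrm1 = iset((0, 10))
    parental = IntervalSet()
    ko = iset((5, 15))  # overlaps pbrm1 but not parental
    strict = iops.categorize_peaks(pbrm1, parental, ko)
    lax = iops.categorize_peaks(pbrm1, parental, ko, ko_vs_both_parental=False)
    assert len(strict.ko_specific) == 0
    assert len(lax.ko_specific) == 1


# ---------------------------------------------------------------------------
# reldist
# ---------------------------------------------------------------------------

def _points(*positions):
    return IntervalSet([Interval("chr", p, p + 1) for p in positions])


def test_reldist_closed_form_examples():
    ref = _points(0, 100)
    assert iops.relative_distance(_points(50), ref).reldist[0] == pytest.approx(0.5)
    assert iops.relative_distance(_points(0), ref).reldist[0] == pytest.approx(0.0)
    assert iops.relative_distance(_points(25), ref).reldist[0] == pytest.approx(0.25)


def test_reldist_outside_reference_skipped():
    result = iops.relative_distance(_points(500), _points(0, 100))
    assert len(result.reldist) == 0
    assert result.n_skipped == 1


def test_reldist_reference_too_small_warns():
    with pytest.warns(UserWarning, match="< 2 locations"):
        result = iops.relative_distance(_points(5), _points(0))
    assert len(result.reldist) == 0


def test_reldist_reflection_symmetry():
    rng = np.random.default_rng(8)
    L = 100_000
    ref_pos = np.sort(rng.choice(L, size=20, replace=False))
    q_pos = rng.integers(ref_pos[0], ref_pos[-1], size=200)
    fwd = iops.relative_distance(_points(*q_pos), _points(*ref_pos))
    # reflect x -> L - x (intervals [p, p+1) map to [L-1-p, L-p))
    refl_ref = _points(*(L - 1 - ref_pos))
    refl_q = _points(*(L - 1 - q_pos))
    rev = iops.relative_distance(refl_q, refl_ref)
    assert sorted(np.round(fwd.reldist, 12)) == sorted(np.round(rev.reldist, 12))


def test_reldist_uniform_null_single_seed():
    rng = np.random.default_rng(0)
    ref_pos = np.arange(0, 1_000_001, 10_000)
    q_pos = rng.integers(0, 1_000_000, size=10_000)
    result = iops.relative_distance(_points(*q_pos), _points(*ref_pos))
    assert abs(result.reldist.mean() - 0.25) < 0.01
    p = stats.kstest(result.reldist, stats.uniform(0, 0.5).cdf).pvalue
    assert p > 0.01


def test_reldist_cumulative_curve_monotone():
    rng = np.random.default_rng(1)
    ref_pos = np.arange(0, 100_001, 1000)
    q_pos = rng.integers(0, 100_000, size=500)
    curve = iops.relative_distance(_points(*q_pos), _points(*ref_pos)).cumulative()
    frac = curve["cumulative_fraction"].to_numpy()
    assert (np.diff(frac) >= 0).all()
    assert frac[-1] <= 1.0 + 1e-12
    assert curve["reldist"].iloc[-1] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# signal matrix
# ---------------------------------------------------------------------------

def test_signal_matrix_uniform_coverage():
    cov = {"chr": np.full(20_000, 3.0)}
    ivs = iset((8000, 8200), (9000, 9100))
    mat = iops.signal_matrix(ivs, cov, flank=1000, bins=20)
    assert np.allclose(mat.values, 3.0)
    assert np.allclose(mat.profile, 3.0)


def test_signal_matrix_single_fragment_single_bin():
    cov = {"chr": np.zeros(20_000)}
    # one fragment exactly covering one 100-bp bin of the first interval
    center = 8100  # midpoint of [8000, 8200)
    cov["chr"][center - 1000: center - 900] = 1.0
    ivs = iset((8000, 8200))
    mat = iops.signal_matrix(ivs, cov, flank=1000, bins=20)
    assert mat.values[0, 0] == pytest.approx(1.0)
    assert mat.values[0, 1:].sum() == 0.0


def test_signal_matrix_row_ordering():
    cov = {"chr": np.zeros(30_000)}
    cov["chr"][10_000 - 500: 10_000 + 500] = 5.0
    cov["chr"][20_000 - 500: 20_000 + 500] = 9.0
    ivs = iset((9_990, 10_010), (19_990, 20_010))
    mat = iops.signal_matrix(ivs, cov, flank=1000, bins=10)
    assert mat.intervals[0].start == 19_990  # larger row sum first
    assert mat.values[0].sum() > mat.values[1].sum()


def test_signal_matrix_bins_must_divide():
    with pytest.raises(ValueError, match="divide"):
        iops.signal_matrix(iset((0, 10)), {"chr": np.zeros(100)}, flank=50, bins=7)


def test_signal_matrix_edge_padding_zero():
    cov = {"chr": np.full(1000, 2.0)}
    mat = iops.signal_matrix(iset((0, 10)), cov, flank=500, bins=10)
    # left half of the window is off-chromosome -> 0
    assert mat.values[0, 0] < 2.0
    assert mat.values[0, -1] == pytest.approx(2.0)


def test_coverage_from_fragments():
    frags = iset((0, 5), (3, 8))
    cov = iops.coverage_from_fragments(frags, {"chr": 10})
    assert list(cov["chr"]) == [1, 1, 1, 2, 2, 1, 1, 1, 0, 0]


# ---------------------------------------------------------------------------
# feature distribution
# ---------------------------------------------------------------------------

def _features():
    return IntervalSet(
        [
            Interval("chr", 0, 100, "promoter"),
            Interval("chr", 0, 400, "intron"),
            Interval("chr", 100, 200, "exon"),
            Interval("chr", 300, 400, "downstream"),
        ]
    )


def test_feature_priority():
    # peak center in both promoter and intron -> promoter wins
    fractions = iops.feature_distribution(iset((40, 60)), _features())
    assert fractions["promoter"] == pytest.approx(1.0)


def test_feature_no_features_all_intergenic():
    fractions = iops.feature_distribution(iset((0, 10), (20, 30)), IntervalSet())
    assert fractions["intergenic"] == pytest.approx(1.0)


def test_feature_four_categories_quarter_each():
    # direct-assignment oracle: centers 50->promoter, 150->exon,
    # 250->intron, 350->downstream (downstream beats intron? no -
    # intron covers [0,400) so 350 is in intron AND downstream; intron
    # has higher priority). Build disjoint features instead.
    features = IntervalSet(
        [
            Interval("chr", 0, 100, "promoter"),
            Interval("chr", 100, 200, "exon"),
            Interval("chr", 200, 300, "intron"),
            Interval("chr", 300, 400, "downstream"),
        ]
    )
    peaks = iset((40, 60), (140, 160), (240, 260), (340, 360))
    fractions = iops.feature_distribution(peaks, features)
    for label in ("promoter", "exon", "intron", "downstream"):
        assert fractions[label] == pytest.approx(0.25)
    assert sum(fractions.values()) == pytest.approx(1.0)


def test_feature_duplicate_priority_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        iops.feature_distribution(
            iset((0, 10)), IntervalSet(), priority=("promoter", "promoter")
        )


def test_promoter_windows():
    genes = IntervalSet([Interval("chr", 5000, 8000, "g1")])
    proms = iops.promoter_windows(genes)
    assert [(r.start, r.end, r.name) for r in proms] == [(2000, 8000, "promoter")]
    clipped = iops.promoter_windows(IntervalSet([Interval("chr", 100, 500)]))
    assert clipped[0].start == 0
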