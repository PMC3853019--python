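import numpy as np
import pandas as pd
import pytest

from morfpssm import (
    PROPERTY_GROUPS,
    ProteinRecord,
    composition,
    correlation_table,
    difference_curve,
    flank_correlation,
    partition,
    property_composition,
)
from morfpssm.regions import FLANK, MORF, NONMORF


def partition_oracle(n, intervals, w):
    """Per-residue distance-to-MoRF classification (0-based positions)."""
    morf = set()
    for s, e in intervals:
        morf.update(range(s - 1, e))
    tags = []
    for i in range(n):
        if i in morf:
            tags.append(MORF)
        elif morf and min(abs(i - j) for j in morf) <= w:
            tags.append(FLANK)
        else:
            tags.append(NONMORF)
    return tags


def random_record(rng, n=None):
    n = n or int(rng.integers(10, 80))
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n))
    intervals = []
    for _ in range(int(rng.integers(0, 3))):
        s = int(rng.integers(1, n + 1))
        e = min(n, s + int(rng.integers(0, 10)))
        intervals.append((s, e))
    return ProteinRecord(id=f"r{rng.integers(1e9)}", sequence=seq,
                         morf_intervals=intervals)


class TestPartition:
    def test_textbook_example(self):
        rec = ProteinRecord(id="p", sequence="A" * 10, morf_intervals=[(4, 6)])
        tags = partition(rec, 2)
        # 1-based: MoRF {4,5,6}, flank {2,3,7,8}, nonMoRF {1,9,10}
        expected = [NONMORF, FLANK, FLANK, MORF, MORF, MORF,
                    FLANK, FLANK, NONMORF, NONMORF]
        assert list(tags) == expected

    def test_zero_flank_length(self):
        rec = ProteinRecord(id="p", sequence="A" * 10, morf_intervals=[(4, 6)])
        assert FLANK not in set(partition(rec, 0))

    def test_close_morfs_share_intervening_flank(self):
        rec = ProteinRecord(id="p", sequence="A" * 12,
                            morf_intervals=[(1, 3), (8, 10)])
        tags = partition(rec, 5)
        assert list(tags[3:7]) == [FLANK] * 4  # tagged once, never double

    def test_matches_distance_oracle(self, rng):
        for _ in range(100):
            rec = random_record(rng)
            w = int(rng.integers(0, 8))
            got = list(partition(rec, w))
            assert got == partition_oracle(len(rec), rec.morf_intervals, w)

    def test_partition_covers_and_is_disjoint(self, rng):
        for _ in range(20):
            rec = random_record(rng)
            tags = partition(rec, 3)
            assert len(tags) == len(rec)
            assert set(tags) <= {MORF, FLANK, NONMORF}
            morf_mask = rec.labels().astype(bool)
            assert (np.asarray(tags)[morf_mask] == MORF).all()


class TestComposition:
    def test_single_letter_region(self):
        rec = ProteinRecord(id="p", sequence="AAAACCCC", morf_intervals=[(1, 4)])
        comp = composition([rec], 0, MORF)
        assert comp["A"] == 1.0 and comp.drop("A").sum() == 0.0

    def test_pooling_across_proteins(self):
        r1 = ProteinRecord(id="p1", sequence="ACGGG", morf_intervals=[(1, 2)])
        r2 = ProteinRecord(id="p2", sequence="CAGGG", morf_intervals=[(1, 2)])
        comp = composition([r1, r2], 0, MORF)
        assert comp["A"] == pytest.approx(0.5) and comp["C"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, rng):
        recs = [random_record(rng) for _ in range(10)]
        comp = composition(recs, 5, NONMORF)
        assert comp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_letter_tally_oracle(self, rng):
        recs = [random_record(rng) for _ in range(8)]
        for region in (MORF, FLANK, NONMORF):
            letters = []
            for rec in recs:
                tags = partition(rec, 4)
                letters += [c for c, t in zip(rec.sequence, tags) if t == region]
            comp = composition(recs, 4, region)
            if not letters:
                assert comp.isna().all()
                continue
            for aa in "ACDEFGHIKLMNPQRSTVWY":
                assert comp[aa] == pytest.approx(letters.count(aa) / len(letters))

    def test_three_regions_reconstruct_whole_dataset(self, rng):
        """Pooling regions weighted by residue counts recovers the global mix."""
        recs = [random_record(rng) for _ in range(10)]
        w = 4
        total = sum(len(r) for r in recs)
        blend = None
        for region in (MORF, FLANK, NONMORF):
            count = sum((partition(r, w) == region).sum() for r in recs)
            comp = composition(recs, w, region).fillna(0.0)
            part = comp * (count / total)
            blend = part if blend is None else blend + part
        whole = composition(recs, 0, NONMORF) * 0  # zero series template
        letters = "".join(r.sequence for r in recs)
        for aa in whole.index:
            whole[aa] = letters.count(aa) / total
        pd.testing.assert_series_equal(blend, whole, atol=1e-9)


class TestPropertyComposition:
    def test_full_membership(self):
        rec = ProteinRecord(id="p", sequence="DDEE", morf_intervals=[(1, 4)])
        prop = property_composition([rec], 0, MORF)
        assert prop["negative"] == 1.0

    def test_empty_membership(self):
        rec = ProteinRecord(id="p", sequence="GGGG", morf_intervals=[(1, 4)])
        prop = property_composition([rec], 0, MORF)
        assert prop["aromatic"] == 0.0

    def test_matches_membership_oracle(self, rng):
        recs = [random_record(rng) for _ in range(6)]
        prop = property_composition(recs, 3, NONMORF)
        letters = []
        for rec in recs:
            tags = partition(rec, 3)
            letters += [c for c, t in zip(rec.sequence, tags) if t == NONMORF]
        for name, members in PROPERTY_GROUPS.items():
            expected = sum(1 for c in letters if c in members) / len(letters)
            assert prop[name] == pytest.approx(expected)


class TestDifferenceCurve:
    def test_self_difference_is_zero(self, rng):
        recs = [random_record(rng) for _ in range(5)]
        diff = difference_curve(recs, FLANK, FLANK, [1, 2, 3])
        assert np.nanmax(np.abs(diff.to_numpy())) == 0.0

    def test_pure_serine_flank(self):
        # MoRF at (5,6); with W=2 the flank is SSSS, nonMoRF has no serine
        rec = ProteinRecord(id="p", sequence="AGSSKKSSGA", morf_intervals=[(5, 6)])
        diff = difference_curve([rec], FLANK, NONMORF, [2])
        assert diff.loc[2, "S"] == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        recs = [random_record(rng) for _ in range(6)]
        ab = difference_curve(recs, FLANK, NONMORF, [1, 3, 5])
        ba = difference_curve(recs, NONMORF, FLANK, [1, 3, 5])
        pd.testing.assert_frame_equal(ab, -ba)

    def test_entries_equal_independent_recomputation(self, rng):
        recs = [random_record(rng) for _ in range(6)]
        diff = difference_curve(recs, FLANK, NONMORF, [2, 4])
        for w in (2, 4):
            expected = composition(recs, w, FLANK) - composition(recs, w, NONMORF)
            pd.testing.assert_series_equal(diff.loc[w], expected,
                                           check_names=False)


class TestFlankCorrelation:
    def test_perfect_linearity(self):
        r, p = flank_correlation(pd.Series([1.0, 2.0, 3.0], index=[1, 2, 3]))
        assert r == pytest.approx(1.0)

    def test_perfect_antilinearity(self):
        r, _ = flank_correlation(pd.Series([3.0, 2.0, 1.0], index=[1, 2, 3]))
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        for _ in range(50):
            w = np.arange(1, 21, dtype=float)
            d = rng.normal(size=20)
            r, _ = flank_correlation(pd.Series(d, index=w))
            cov = np.mean((w - w.mean()) * (d - d.mean()))
            expected = cov / (w.std() * d.std())
            assert r == pytest.approx(expected)
            assert abs(r) <= 1.0

    def test_invariant_under_affine_rescaling_of_w(self, rng):
        d = rng.normal(size=10)
        a, _ = flank_correlation(pd.Series(d, index=np.arange(10.0)))
        b, _ = flank_correlation(pd.Series(d, index=3.0 * np.arange(10.0) + 7))
        assert a == pytest.approx(b)

    def test_constant_series_reported_absent(self):
        r, p = flank_correlation(pd.Series([2.0, 2.0, 2.0], index=[1, 2, 3]))
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            flank_correlation(pd.Series([1.0, 2.0], index=[1, 2]))


def test_correlation_table_covers_all_features(rng):
    recs = [random_record(rng) for _ in range(8)]
    diff = difference_curve(recs, FLANK, NONMORF, list(range(1, 11)))
    table = correlation_table(diff)
    assert set(table["feature"]) == set("ACDEFGHIKLMNPQRSTVWY")
    assert (table["r"].abs().dropna() <= 1.0 + 1e-12).all()
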