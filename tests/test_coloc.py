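"""Presence calling, prevalence filtering and the pairwise colocalization
screen."""

import itertools

import numpy as np
import pandas as pd
import pytest

import stromalink as sl
from stromalink.coloc import read_spot_matrix_long, write_spot_matrix_long


def presence_from_patterns(patterns, types=("A", "B", "C")):
    """Build a PresenceMatrix from per-spot tuples of 0/1 flags."""
    arr = np.array(patterns, dtype=bool)
    idx = pd.MultiIndex.from_arrays(
        [["s"] * len(arr), [f"spot{i}" for i in range(len(arr))]],
        names=["sample_id", "spot_id"],
    )
    return sl.PresenceMatrix(
        presence=pd.DataFrame(arr, index=idx, columns=list(types[: arr.shape[1]])),
        threshold_used=1.0,
    )


def spot_matrix_from_counts(counts, types):
    arr = np.asarray(counts, dtype=float)
    idx = pd.MultiIndex.from_arrays(
        [["s"] * len(arr), [f"spot{i}" for i in range(len(arr))]],
        names=["sample_id", "spot_id"],
    )
    coords = pd.DataFrame({"x": range(len(arr)), "y": 0}, index=idx)
    return sl.SpotMatrix(counts=pd.DataFrame(arr, index=idx, columns=types), coords=coords)


class TestCallPresence:
    def test_threshold_rule(self):
        m = spot_matrix_from_counts([[1.2, 0.4], [0.6, 2.0]], ["A", "B"])
        p = sl.call_presence(m, 1.0)
        assert p.presence.values.tolist() == [[True, False], [False, True]]
        p2 = sl.call_presence(m, 0.5)
        assert p2.presence.values.tolist() == [[True, False], [True, True]]
        assert p2.threshold_used == 0.5

    def test_nonpositive_threshold_rejected(self):
        m = spot_matrix_from_counts([[1.0]], ["A"])
        with pytest.raises(ValueError):
            sl.call_presence(m, 0.0)


class TestFilterPrevalence:
    def test_strictly_less_than_rule(self):
        pats = [(1, 1)] * 3 + [(0, 1)] * 97  # A in 3%, B in 100%
        p = sl.filter_prevalence(presence_from_patterns(pats, ("A", "B")), 0.04)
        assert p.cell_types == ["B"]
        pats4 = [(1, 1)] * 4 + [(0, 1)] * 96  # A in exactly 4%: retained
        p4 = sl.filter_prevalence(presence_from_patterns(pats4, ("A", "B")), 0.04)
        assert p4.cell_types == ["A", "B"]

    def test_zero_threshold_is_identity(self):
        p = presence_from_patterns([(1, 0), (0, 1)], ("A", "B"))
        assert sl.filter_prevalence(p, 0.0).presence.equals(p.presence)

    def test_dropping_everything_is_an_error(self):
        p = presence_from_patterns([(1, 0)] + [(0, 0)] * 99, ("A", "B"))
        with pytest.raises(ValueError):
            sl.filter_prevalence(p, 0.5)


class TestPairContingency:
    def test_four_pattern_enumeration(self):
        p = presence_from_patterns([(1, 1), (1, 0), (0, 1), (0, 0)], ("A", "B"))
        t = sl.pair_contingency(p, "A", "B")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_all_both_present(self):
        p = presence_from_patterns([(1, 1)] * 7, ("A", "B"))
        t = sl.pair_contingency(p, "A", "B")
        assert (t.a, t.b, t.c, t.d) == (7, 0, 0, 0)

    def test_hand_built_six_spots(self):
        pats = [(1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1), (0, 0, 0), (1, 0, 0)]
        p = presence_from_patterns(pats)
        t = sl.pair_contingency(p, "A", "C")
        # by hand: both {2nd, 4th}, A-only {1st, 6th}, C-only {3rd}, neither {5th}
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 1)

    def test_unknown_type_rejected(self):
        p = presence_from_patterns([(1, 1)], ("A", "B"))
        with pytest.raises(KeyError):
            sl.pair_contingency(p, "A", "Z")

    def test_matches_brute_force_tally_on_enumerated_matrices(self):
        patterns = list(itertools.product([0, 1], repeat=3))
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(1, 9)
            pats = [patterns[i] for i in rng.integers(0, 8, n)]
            p = presence_from_patterns(pats)
            for ta, tb in itertools.combinations("ABC", 2):
                t = sl.pair_contingency(p, ta, tb)
                ia, ib = "ABC".index(ta), "ABC".index(tb)
                brute = [0, 0, 0, 0]
                for pat in pats:
                    brute[{(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(pat[ia], pat[ib])]] += 1
                assert [t.a, t.b, t.c, t.d] == brute


class TestColocScreen:
    def test_number_of_pairs(self):
        rng = np.random.default_rng(1)
        p = presence_from_patterns(rng.integers(0, 2, (50, 3)))
        assert len(sl.coloc_screen(p)) == 3

    def test_spot_order_permutation_invariance(self):
        rng = np.random.default_rng(2)
        pats = rng.integers(0, 2, (80, 3))
        r1 = sl.coloc_screen(presence_from_patterns(pats))
        r2 = sl.coloc_screen(presence_from_patterns(pats[rng.permutation(80)]))
        for a, b in zip(r1, r2):
            assert (a.type_a, a.type_b) == (b.type_a, b.type_b)
            assert a.or_result.or_value == pytest.approx(b.or_result.or_value)
            assert a.fdr == pytest.approx(b.fdr)

    def test_pooling_two_samples_equals_pooled_spots(self):
        rng = np.random.default_rng(3)
        pats1, pats2 = rng.integers(0, 2, (40, 3)), rng.integers(0, 2, (60, 3))
        pooled = sl.coloc_screen(presence_from_patterns(np.vstack([pats1, pats2])))
        idx = pd.MultiIndex.from_tuples(
            [("s1", f"a{i}") for i in range(40)] + [("s2", f"b{i}") for i in range(60)],
            names=["sample_id", "spot_id"],
        )
        two = sl.PresenceMatrix(
            presence=pd.DataFrame(
                np.vstack([pats1, pats2]).astype(bool), index=idx, columns=["A", "B", "C"]
            ),
            threshold_used=1.0,
        )
        merged = sl.coloc_screen(two)
        for a, b in zip(pooled, merged):
            assert (a.table.a, a.table.b, a.table.c, a.table.d) == (
                b.table.a, b.table.b, b.table.c, b.table.d,
            )

    def test_fdr_dominates_p_and_sorted(self):
        rng = np.random.default_rng(4)
        p = presence_from_patterns(rng.integers(0, 2, (100, 4)), ("A", "B", "C", "D"))
        res = sl.coloc_screen(p)
        assert all(r.fdr >= r.or_result.p_value - 1e-15 for r in res)
        assert [r.fdr for r in res] == sorted(r.fdr for r in res)

    def test_single_type_rejected(self):
        with pytest.raises(ValueError):
            sl.coloc_screen(presence_from_patterns([(1,), (0,)], ("A",)))


def test_long_format_round_trip(tmp_path):
    m = sl.gen_spot_map(sl.SpotSimConfig(n_spots=50, grid_shape=(10, 5), seed=5))
    path = tmp_path / "spots.tsv"
    write_spot_matrix_long(m, path)
    m2 = read_spot_matrix_long(path)
    pd.testing.assert_frame_equal(
        m.counts.sort_index(axis=1), m2.counts.sort_index(axis=1), check_names=False
    )
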