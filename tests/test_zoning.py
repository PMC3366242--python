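import numpy as np
import pytest

from prezone.datasets import Dataset
from prezone.preprocessing import (build_transferred_table, rank_dataset,
                                   select_validation_candidates)
from prezone.zoning import (Region, assign_zone_numbers, build_zone_table,
                            find_candidate_region)

from oracles import oracle_region, oracle_zone_numbers, oracle_zone_table


def random_instance(rng, n_a_max=12, m_max=3, cn_max=4):
    """A random small pipeline instance: transferred table + candidate set."""
    n_a = int(rng.integers(3, n_a_max + 1))
    n_b = int(rng.integers(4, 15))
    m = int(rng.integers(1, m_max + 1))
    cn = int(rng.integers(1, min(cn_max, n_b) + 1))
    # coarse grids provoke plenty of ties
    a = Dataset([f"a{i}" for i in range(n_a)],
                rng.integers(0, 8, (n_a, m)).astype(float) / 2.0,
                [f"v{p}" for p in range(m)])
    b = Dataset([f"b{j}" for j in range(n_b)],
                rng.integers(0, 8, (n_b, m)).astype(float) / 2.0,
                [f"v{p}" for p in range(m)],
                validation=rng.integers(0, 40, n_b))
    for d in (a, b):  # keep every column non-constant so the transfer is defined
        for p in range(m):
            if np.ptp(d.scores[:, p]) == 0:
                d.scores[0, p] += 1.0
    t = build_transferred_table(a, b)
    c = select_validation_candidates(b, cn / n_b, ranks=rank_dataset(b))
    return t, c


class TestFindCandidateRegion:
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    ranks = np.array([1.0, 2.0, 3.0, 4.0])

    def test_case_one_extends_right_to_score_anchor(self):
        assert find_candidate_region(self.scores, self.ranks, 3.5, 1) == Region(1, 4)

    def test_case_two_extends_left_to_score_anchor(self):
        # rank anchor at position 3, score anchor below: region runs down to the
        # first object whose score has dropped to bx
        assert find_candidate_region(self.scores, self.ranks, 1.5, 3) == Region(1, 4)

    def test_anchors_beyond_top_clamp(self):
        assert find_candidate_region(self.scores, self.ranks, 9.0, 9.0) == Region(4, 4)

    def test_anchors_below_bottom_clamp(self):
        assert find_candidate_region(self.scores, self.ranks, 0.1, 0.1) == Region(1, 2)

    def test_between_scores_gives_one_step_region(self):
        assert find_candidate_region(self.scores, self.ranks, 2.5, 2) == Region(2, 3)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            find_candidate_region(np.array([]), np.array([]), 1.0, 1.0)

    def test_matches_literal_scan_on_random_inputs(self, rng):
        for _ in range(400):
            n = int(rng.integers(1, 13))
            xs = np.sort(rng.integers(0, 10, n).astype(float))
            rs = np.arange(1, n + 1) * float(rng.integers(1, 15)) / n
            bx = float(rng.integers(-2, 12))
            bs = float(rng.integers(0, 16))
            got = find_candidate_region(xs, rs, bx, bs)
            assert (got.lo, got.hi) == oracle_region(list(xs), list(rs), bx, bs)


class TestAssignZoneNumbers:
    def test_single_region_covers_axis(self):
        labels, cand = assign_zone_numbers([Region(1, 3)], 3)
        np.testing.assert_array_equal(labels, [1, 1, 1])
        assert cand == [1]

    def test_gap_between_regions_is_its_own_zone(self):
        labels, cand = assign_zone_numbers([Region(1, 2), Region(5, 6)], 6)
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 3, 3])
        assert cand == [1, 3]

    def test_overlapping_regions_merge(self):
        labels, cand = assign_zone_numbers([Region(1, 3), Region(3, 5)], 6)
        np.testing.assert_array_equal(labels, [1, 1, 1, 1, 1, 2])
        assert cand == [1, 1]

    def test_adjacent_regions_do_not_merge(self):
        labels, cand = assign_zone_numbers([Region(1, 2), Region(3, 4)], 4)
        np.testing.assert_array_equal(labels, [1, 1, 2, 2])
        assert cand == [1, 2]

    def test_terminal_gaps_are_numbered_runs(self):
        labels, _ = assign_zone_numbers([Region(3, 4)], 6)
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 3, 3])

    def test_labels_contiguous_and_unit_steps(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 15))
            k = int(rng.integers(1, 5))
            regions = []
            for _ in range(k):
                lo = int(rng.integers(1, n + 1))
                hi = int(rng.integers(lo, n + 1))
                regions.append(Region(lo, hi))
            labels, cand = assign_zone_numbers(regions, n)
            steps = np.diff(labels)
            assert np.all((steps == 0) | (steps == 1))
            assert labels[0] == 1
            assert set(cand) <= set(labels)

    def test_merge_is_order_independent(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            regions = []
            for _ in range(int(rng.integers(2, 5))):
                lo = int(rng.integers(1, n + 1))
                regions.append(Region(lo, int(rng.integers(lo, n + 1))))
            ref_labels, ref_cand = assign_zone_numbers(regions, n)
            perm = list(rng.permutation(len(regions)))
            labels, cand = assign_zone_numbers([regions[i] for i in perm], n)
            np.testing.assert_array_equal(labels, ref_labels)
            assert [cand[perm.index(i)] for i in range(len(regions))] == ref_cand

    def test_matches_brute_force_numbering(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 12))
            regions = []
            for _ in range(int(rng.integers(1, 5))):
                lo = int(rng.integers(1, n + 1))
                regions.append(Region(lo, int(rng.integers(lo, n + 1))))
            labels, cand = assign_zone_numbers(regions, n)
            o_labels, o_cand = oracle_zone_numbers([(r.lo, r.hi) for r in regions], n)
            np.testing.assert_array_equal(labels, o_labels)
            assert cand == o_cand


class TestBuildZoneTable:
    def test_self_zoning_candidates_land_in_own_zone(self, rng):
        # unknown set identical to the known set: each candidate's own object
        # must carry the candidate's zone label on every variable
        d = Dataset([f"h{i}" for i in range(6)], rng.normal(2, 1, (6, 2)),
                    ["x", "y"], validation=rng.permutation(6))
        t = build_transferred_table(d, d)
        c = select_validation_candidates(d, 0.5)
        z = build_zone_table(t, c)
        own = [d.object_ids.index(oid) for oid in c.object_ids]
        for ej, i in enumerate(own):
            np.testing.assert_array_equal(z.a_zones[i], z.b_zones[ej])

    def test_single_variable_single_candidate_label_budget(self, rng):
        a = Dataset([f"a{i}" for i in range(9)], rng.normal(2, 1, (9, 1)), ["x"])
        b = Dataset([f"b{j}" for j in range(12)], rng.normal(2, 1, (12, 1)),
                    ["x"], validation=rng.permutation(12))
        c = select_validation_candidates(b, 1 / 12)
        assert c.cn == 1
        z = build_zone_table(build_transferred_table(a, b), c)
        assert len(np.unique(z.a_zones[:, 0])) <= 3  # one region + two flanks

    def test_object_zones_stable_under_input_permutation(self, rng):
        n = 10
        a = Dataset([f"a{i}" for i in range(n)],
                    rng.normal(2, 1, (n, 2)), ["x", "y"])  # no ties a.s.
        b = Dataset([f"b{j}" for j in range(12)], rng.normal(2, 1, (12, 2)),
                    ["x", "y"], validation=rng.integers(0, 50, 12))
        c = select_validation_candidates(b, 0.25)
        z1 = build_zone_table(build_transferred_table(a, b), c)
        perm = rng.permutation(n)
        a2 = Dataset([a.object_ids[i] for i in perm], a.scores[perm], ["x", "y"])
        z2 = build_zone_table(build_transferred_table(a2, b), c)
        for pos, i in enumerate(perm):
            np.testing.assert_array_equal(z2.a_zones[pos], z1.a_zones[i])

    def test_matches_brute_force_pipeline(self, rng):
        for _ in range(300):
            t, c = random_instance(rng)
            z = build_zone_table(t, c)
            a_o, b_o = oracle_zone_table(t.t_scores.tolist(), t.t_ranks.tolist(),
                                         c.cand_scores.tolist(),
                                         c.cand_ranks.tolist())
            np.testing.assert_array_equal(z.a_zones, np.array(a_o))
            np.testing.assert_array_equal(z.b_zones, np.array(b_o))
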