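"""Detection linking, budded phases, parent-bud posterior, bootstrap, t-test."""

import itertools
import math

import numpy as np
import pytest

from budmrna.lineage import (
    Detection,
    ParentCandidate,
    Track,
    assign_parent_bud,
    bootstrap_means,
    budded_phases,
    compare_durations,
    link_detections,
    parent_bud_posterior,
)

from _oracles import brute_force_matching, brute_force_parent_posterior


def det(frame, oid, x, y, kind="neck", **kw):
    return Detection(frame=frame, id=oid, centroid=(x, y), kind=kind, **kw)


class TestLinking:
    def test_two_stationary_objects(self):
        dets = [det(f, i, 1000.0 * i, 0.0) for f in range(5) for i in (0, 1)]
        tracks = link_detections(dets)
        assert len(tracks) == 2
        assert all(len(t) == 5 for t in tracks)

    def test_jump_beyond_threshold_splits_track(self):
        dets = [det(0, 0, 0.0, 0.0), det(1, 0, 250.0, 0.0)]  # 250 px > 200 px
        tracks = link_detections(dets, max_dist=200.0)
        assert [len(t) for t in tracks] == [1, 1]

    def test_jump_within_threshold_continues_track(self):
        dets = [det(0, 0, 0.0, 0.0), det(1, 0, 150.0, 0.0)]
        tracks = link_detections(dets, max_dist=200.0)
        assert [len(t) for t in tracks] == [2]

    def test_gap_frame_terminates_tracks(self):
        dets = [det(0, 0, 0.0, 0.0), det(2, 0, 0.0, 0.0)]  # frame 1 missing
        assert [len(t) for t in tracks] == [1, 1] if (tracks := link_detections(dets)) else False

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_assignment(self, seed):
        rng = np.random.default_rng(seed)
        n_prev, n_next = rng.integers(1, 7, size=2)
        prev_xy = rng.uniform(0, 500, size=(n_prev, 2))
        next_xy = rng.uniform(0, 500, size=(n_next, 2))
        dets = [det(0, i, *p) for i, p in enumerate(prev_xy)]
        dets += [det(1, i, *q) for i, q in enumerate(next_xy)]
        tracks = link_detections(dets, max_dist=200.0)
        got = set()
        for t in tracks:
            if len(t) == 2:
                i = next(k for k, p in enumerate(prev_xy) if tuple(p) == t.detections[0].centroid)
                j = next(k for k, q in enumerate(next_xy) if tuple(q) == t.detections[1].centroid)
                got.add((i, j))
        want = brute_force_matching([tuple(p) for p in prev_xy], [tuple(q) for q in next_xy], 200.0)
        # both are optimal matchings; total distance must agree (ties can differ)
        def cost(pairs):
            return sum(math.dist(prev_xy[i], next_xy[j]) for i, j in pairs) + 200.0 * (
                len(prev_xy) - len(pairs) + len(next_xy) - len(pairs)
            )
        assert cost(got) == pytest.approx(cost(want), abs=1e-9)


class TestBuddedPhases:
    def test_duration_arithmetic(self):
        track = Track([det(f, 0, 0.0, 0.0) for f in range(10, 58)])
        phases = budded_phases([track], frame_interval=1.0)
        assert phases[0].duration_min == 48.0
        assert phases[0].budding_frame == 10

    def test_empty_input(self):
        assert budded_phases([]) == []

    def test_manual_budding_override(self):
        track = Track([det(f, 0, 0.0, 0.0) for f in range(10, 58)])
        phases = budded_phases([track], 1.0, budding_overrides={0: 5})
        assert phases[0].duration_min == 53.0

    def test_zero_length_track_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            assert budded_phases([Track([])]) == []


class TestParentBud:
    def test_size_factor(self):
        cands = [ParentCandidate(1, 300.0, 10.0), ParentCandidate(2, 100.0, 10.0)]
        parent, bud, prob, post = assign_parent_bud(cands)
        assert (parent, bud) == (1, 2)
        assert post[(1, 2)] == pytest.approx(0.75)
        assert post[(2, 1)] == pytest.approx(0.25)

    def test_nucleus_doubles_parent_odds(self):
        cands = [ParentCandidate(1, 200.0, 5.0, nucleus_flag=True), ParentCandidate(2, 200.0, 5.0)]
        parent, _, prob, post = assign_parent_bud(cands)
        assert parent == 1
        assert post[(1, 2)] / post[(2, 1)] == pytest.approx(2.0)
        assert prob == pytest.approx(2.0 / 3.0)

    def test_posterior_normalized_and_symmetric_without_nucleus(self):
        cands = [ParentCandidate(1, 150.0, 8.0), ParentCandidate(2, 150.0, 8.0)]
        post = parent_bud_posterior(cands)
        assert sum(post.values()) == pytest.approx(1.0)
        assert post[(1, 2)] == pytest.approx(post[(2, 1)])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        cands = [
            ParentCandidate(i, float(rng.uniform(50, 400)), float(rng.uniform(0, 20)),
                            bool(rng.random() < 0.4))
            for i in range(n)
        ]
        post = parent_bud_posterior(cands)
        want = brute_force_parent_posterior([(c.id, c.area, c.overlap, c.nucleus_flag) for c in cands])
        assert set(post) == set(want)
        for k in post:
            assert post[k] == pytest.approx(want[k])

    def test_self_pairs_excluded_and_minimum_two(self):
        with pytest.raises(ValueError):
            parent_bud_posterior([ParentCandidate(1, 100.0, 1.0)])


class TestBootstrap:
    def test_constant_input_degenerate(self):
        boots = bootstrap_means([50.0] * 20, n_boot=500, sample_size=250, seed=0)
        assert np.all(boots == 50.0)

    def test_seed_determinism(self):
        d = np.random.default_rng(5).normal(48, 8, size=300)
        a = bootstrap_means(d, n_boot=1000, sample_size=250, seed=42)
        b = bootstrap_means(d, n_boot=1000, sample_size=250, seed=42)
        assert np.array_equal(a, b)

    def test_mean_and_spread_match_theory(self):
        rng = np.random.default_rng(6)
        d = rng.normal(48.2, 8.0, size=600)
        boots = bootstrap_means(d, n_boot=10000, sample_size=250, seed=1)
        # mean of bootstrap means ~ sample mean
        tol = 3.0 * d.std(ddof=1) / math.sqrt(10000 * 250)
        assert abs(boots.mean() - d.mean()) < max(tol, 5e-3 * d.std(ddof=1))
        # bootstrap SD ~ sample SD / sqrt(sample_size), within 10 %
        assert boots.std(ddof=1) == pytest.approx(d.std(ddof=0) / math.sqrt(250), rel=0.10)

    def test_bad_sample_size(self):
        with pytest.raises(ValueError):
            bootstrap_means([1.0], sample_size=0)


class TestCompare:
    def test_identical_groups(self):
        g = [48.0, 50.0, 52.0, 47.0]
        res = compare_durations(g, g)
        assert res.difference == 0.0
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_equal_means_convention(self):
        res = compare_durations([50.0, 50.0], [50.0, 50.0])
        assert res.p == 1.0

    def test_hand_computed_welch(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        res = compare_durations(a, b)
        sa2, sb2 = np.var(a, ddof=1) / 3, np.var(b, ddof=1) / 3
        t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(sa2 + sb2)
        assert res.t == pytest.approx(t_hand)
        assert res.difference == pytest.approx(2.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(7)
        a = rng.normal(48.2, 8.0, size=602)
        b = rng.normal(53.5, 8.0, size=694)
        res = compare_durations(a, b)
        assert res.p < 1e-6
        assert res.difference == pytest.approx(5.3, abs=1.5)
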