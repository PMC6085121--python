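"""Gated distances, tracker consensus, trajectory features and profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quantev.dynamics import (
    TOWARD_CENTER,
    TOWARD_PERIPHERY,
    FeatureHistogram,
    Trajectory,
    classify_direction,
    confinement_ratio,
    consensus_filter,
    direction_proportions,
    feature_density,
    feature_histogram,
    gated_distance,
    lifetime,
    total_path_length,
)


def track(tid, coords, frames=None, dt=1.0):
    coords = np.asarray(coords, float)
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    frames = np.arange(len(coords)) if frames is None else frames
    return Trajectory(id=tid, frames=frames, xyz=coords, dt=dt)


class TestGatedDistance:
    def test_identical_tracks_zero(self):
        a = track("a", [(0, 0), (1, 0), (2, 1)])
        assert gated_distance(a, a, 2.0) == 0.0

    def test_gate_saturation(self):
        a = track("a", [(0, 0), (0, 0), (0, 0)])
        b = track("b", [(10, 0), (10, 0), (10, 0)])
        assert gated_distance(a, b, 2.0) == 3 * 2.0

    def test_hand_worked_example(self):
        """Frames 0,1,2 with gate 2: min(0,2) + min(3,2) + min(0,2) = 2."""
        a = track("a", [(0, 0), (1, 0), (2, 0)])
        b = track("b", [(0, 0), (1, 3), (2, 0)])
        assert gated_distance(a, b, 2.0) == pytest.approx(2.0)

    def test_disjoint_frames_cost_union_times_gate(self):
        a = track("a", [(0, 0), (0, 0)], frames=np.array([0, 1]))
        b = track("b", [(0, 0), (0, 0)], frames=np.array([5, 6]))
        assert gated_distance(a, b, 3.0) == 4 * 3.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_nonnegative_bounded(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 8, 2)
        a = track("a", rng.normal(0, 3, (na, 3)), frames=np.sort(rng.choice(12, na, replace=False)))
        b = track("b", rng.normal(0, 3, (nb, 3)), frames=np.sort(rng.choice(12, nb, replace=False)))
        eps = float(rng.uniform(0.5, 5))
        d1, d2 = gated_distance(a, b, eps), gated_distance(b, a, eps)
        assert d1 == pytest.approx(d2)
        union = len(np.union1d(a.frames, b.frames))
        assert 0 <= d1 <= union * eps + 1e-12


def jittered(tr, rng, sd, tag):
    return Trajectory(
        id=f"{tr.id}-{tag}", frames=tr.frames.copy(), xyz=tr.xyz + rng.normal(0, sd, tr.xyz.shape)
    )


def planted_track_sets(n_planted=10, n_spurious=3, jitter=0.3, seed=0):
    rng = np.random.default_rng(seed)
    planted = []
    for i in range(n_planted):
        start = rng.uniform(10, 40, 3)
        steps = rng.normal(0, 1.0, (15, 3))
        planted.append(track(f"p{i}", start + np.cumsum(steps, axis=0)))
    sets = {}
    for mi, method in enumerate(("mhtrack", "combi", "trackmate")):
        tracks = [jittered(t, rng, jitter, method) for t in planted]
        for si in range(n_spurious):
            start = rng.uniform(100 + 20 * mi, 130 + 20 * mi, 3)  # far apart per method
            steps = rng.normal(0, 1.0, (15, 3))
            tracks.append(track(f"s{method}{si}", start + np.cumsum(steps, axis=0)))
        sets[method] = tracks
    return sets, [t.id for t in sets["mhtrack"][:n_planted]]


class TestConsensusFilter:
    def test_full_agreement_retained(self):
        a = track("a", [(0, 0), (1, 0), (2, 0)])
        sets = {"m1": [a], "m2": [track("b", a.xyz)], "m3": [track("c", a.xyz)]}
        kept = consensus_filter(sets)
        assert [t.id for t in kept] == ["a"]

    def test_unsupported_track_discarded(self):
        lone = track("lone", [(0, 0), (1, 0)])
        far = track("far", [(50, 50), (51, 50)])
        sets = {"m1": [lone], "m2": [far], "m3": [track("far2", far.xyz)]}
        assert consensus_filter(sets) == []

    def test_planted_tracks_recovered_exactly(self):
        sets, planted_ids = planted_track_sets()
        kept = consensus_filter(sets)
        assert sorted(t.id for t in kept) == sorted(planted_ids)

    def test_output_subset_of_reference(self):
        sets, _ = planted_track_sets(seed=3)
        ref_ids = {t.id for t in sets["mhtrack"]}
        assert all(t.id in ref_ids for t in consensus_filter(sets))

    def test_threshold_monotonicity(self):
        sets, _ = planted_track_sets(jitter=1.0, seed=4)
        small = consensus_filter(sets, match_threshold=0.5)
        large = consensus_filter(sets, match_threshold=3.0)
        assert {t.id for t in small} <= {t.id for t in large}

    def test_two_methods_allowed_one_rejected(self):
        a = track("a", [(0, 0), (1, 0)])
        with pytest.raises(ValueError):
            consensus_filter({"only": [a]})
        assert consensus_filter({"m1": [a], "m2": [track("b", a.xyz)]})


class TestFeatures:
    def test_straight_track_ratio_one(self):
        t = track("t", [(0, 0), (1, 0), (2, 0), (5, 0)])
        assert confinement_ratio(t) == pytest.approx(1.0)

    def test_closed_loop_ratio_zero(self):
        t = track("t", [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert confinement_ratio(t) == pytest.approx(0.0)

    def test_half_square_perimeter(self):
        t = track("t", [(0, 0), (1, 0), (1, 1)])
        assert confinement_ratio(t) == pytest.approx(np.sqrt(2) / 2, abs=1e-9)

    def test_stationary_track_warns_ratio_one(self):
        t = track("t", [(3, 3), (3, 3), (3, 3)])
        with pytest.warns(UserWarning, match="stationary"):
            assert confinement_ratio(t) == 1.0

    def test_path_length_voxel_scaling(self):
        t = track("t", [(0, 0), (3, 4)])
        assert total_path_length(t) == pytest.approx(5.0)
        assert total_path_length(t, voxel_size=(0.1, 0.1, 0.3)) == pytest.approx(0.5)

    def test_lifetime_uses_dt(self):
        t = track("t", [(0, 0), (1, 0), (2, 0)], frames=np.array([2, 5, 9]), dt=0.5)
        assert lifetime(t) == pytest.approx(3.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ratio_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        t = track("t", rng.normal(0, 2, (rng.integers(2, 10), 3)))
        assert 0.0 <= confinement_ratio(t) <= 1.0


class TestDirection:
    def test_outward_and_inward(self, disk_cell, disk_frame):
        c = disk_frame.origin
        out = track("o", [(c[0] + 2, c[1]), (c[0] + 10, c[1])])
        inw = track("i", [(c[0] + 10, c[1]), (c[0] + 2, c[1])])
        assert classify_direction(out, disk_frame, disk_cell) == TOWARD_PERIPHERY
        assert classify_direction(inw, disk_frame, disk_cell) == TOWARD_CENTER

    def test_tangential_tie_counted(self, disk_cell, disk_frame):
        c = disk_frame.origin
        r = 10.0
        arc = track(
            "arc",
            [(c[0] + r * np.cos(a), c[1] + r * np.sin(a)) for a in (0.0, np.pi / 2, np.pi)],
        )
        assert classify_direction(arc, disk_frame, disk_cell) == TOWARD_CENTER
        props = direction_proportions([arc], disk_frame, disk_cell)
        assert props["ties"] == 1


class TestFeatureHistogram:
    def test_single_bin_average(self, disk_cell, disk_frame):
        c = disk_frame.origin
        # two tracks whose median points share a radial bin; lifetimes 2 and 4
        t1 = track("a", [(c[0] + 10, c[1]), (c[0] + 10.5, c[1]), (c[0] + 11, c[1])],
                   frames=np.array([0, 1, 2]))
        t2 = track("b", [(c[0] + 10, c[1] + 1), (c[0] + 10.5, c[1] + 1), (c[0] + 11, c[1] + 1)],
                   frames=np.array([0, 2, 4]))
        h = feature_histogram([t1, t2], "lifetime", "radius", disk_frame, disk_cell, bins=10)
        filled = h.mean_feature[h.nonempty]
        assert len(filled) == 1
        assert filled[0] == pytest.approx(3.0)
        assert np.all(np.isnan(h.mean_feature[~h.nonempty]))
        assert h.counts.sum() == 2

    def test_single_track_exact(self, disk_cell, disk_frame):
        c = disk_frame.origin
        t = track("a", [(c[0], c[1]), (c[0] + 3, c[1] + 4)])
        h = feature_histogram([t], "total_path_length", "radius", disk_frame, disk_cell)
        assert h.mean_feature[h.nonempty][0] == pytest.approx(5.0)

    def test_planted_radial_gradient(self, disk_cell, disk_frame):
        """Tracks whose lifetime equals their median r_norm: per-bin means
        land within 0.05 of the bin centers."""
        rng = np.random.default_rng(12)
        c = disk_frame.origin
        tracks = []
        for i in range(200):
            theta = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(1, 18.5)
            x, y = c[0] + r * np.cos(theta), c[1] + r * np.sin(theta)
            r_norm = r / 20.0
            nframes = max(int(round(r_norm * 100)), 2)
            pos = np.tile([x, y, 0.0], (2, 1)) + [[0, 0, 0], [0.2, 0, 0]]
            tracks.append(
                Trajectory(id=f"t{i}", frames=np.array([0, nframes]), xyz=pos, dt=0.01)
            )
        h = feature_histogram(tracks, "lifetime", "radius", disk_frame, disk_cell, bins=10)
        centers = h.centers[h.nonempty]
        means = h.mean_feature[h.nonempty]
        inner = (centers > 0.05) & (centers < 0.95)
        assert np.all(np.abs(means[inner] - centers[inner]) < 0.05)

    def test_all_outside_bins_impossible(self, disk_cell, disk_frame):
        with pytest.raises(ValueError):
            feature_histogram([], "lifetime", "radius", disk_frame, disk_cell)


class TestFeatureDensity:
    def test_constant_feature_flat_density(self):
        edges = np.linspace(0, 1, 21)
        h = FeatureHistogram(
            axis="radius", edges=edges,
            mean_feature=np.full(20, 2.5), counts=np.ones(20, int),
        )
        d = feature_density(h)
        assert d.values.max() / d.values.min() < 1.01

    def test_constant_feature_flat_circular(self):
        edges = np.linspace(0, 2 * np.pi, 37)
        h = FeatureHistogram(
            axis="angle", edges=edges,
            mean_feature=np.full(36, 1.0), counts=np.ones(36, int),
        )
        d = feature_density(h)
        assert d.values.max() / d.values.min() < 1.01

    def test_empty_bins_skipped_exactly(self):
        edges = np.linspace(0, 1, 11)
        means = np.array([1, 2, np.nan, 3, 1, np.nan, 2, 1, 3, 2], float)
        counts = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 1])
        h = FeatureHistogram("radius", edges, means, counts)
        d1 = feature_density(h)
        # drop one empty bin from the histogram: identical density
        keep = np.ones(10, bool)
        keep[5] = False
        h2 = FeatureHistogram(
            "radius", edges, np.where(keep, means, np.nan), np.where(keep, counts, 0)
        )
        d2 = feature_density(h2)
        assert np.allclose(d1.values, d2.values, atol=1e-9)

    def test_gradient_monotone_profile(self):
        edges = np.linspace(0, 1, 11)
        centers = 0.5 * (edges[:-1] + edges[1:])
        h = FeatureHistogram("radius", edges, centers.copy(), np.ones(10, int))
        d = feature_density(h)
        inner = (d.grid >= 0.1) & (d.grid <= 0.9)
        assert np.all(np.diff(d.values[inner]) > -1e-12)

    def test_too_few_bins_rejected(self):
        h = FeatureHistogram(
            "radius", np.linspace(0, 1, 11),
            np.r_[1.0, np.full(9, np.nan)], np.r_[1, np.zeros(9, int)],
        )
        with pytest.raises(ValueError):
            feature_density(h)
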