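import numpy as np
import pytest

from conftest import circular_arc
from ufib.clustering import (
    LabelVolume,
    ParcelInfo,
    TemplateTract,
    assign_endpoint_parcel,
    assign_tract_nodes,
    map_tracts_to_surface,
    mdf_distance,
    propagate_labels,
    select_analysis_tracts,
    ClusterSet,
)
from ufib.geometry import Tractogram
from ufib.synth import SynthConfig, make_template


class TestMDF:
    def test_identity_and_flip(self, rng):
        s = rng.uniform(0, 50, size=(30, 3))
        assert mdf_distance(s, s) == pytest.approx(0.0, abs=1e-9)
        assert mdf_distance(s, s[::-1]) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_translation_offset(self, rng):
        s = rng.uniform(0, 50, size=(25, 3))
        assert mdf_distance(s, s + np.array([3.0, 0, 0])) == pytest.approx(3.0, abs=1e-9)

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(50):
            a, b, c = (rng.uniform(0, 40, size=(rng.integers(5, 25), 3)) for _ in range(3))
            dab, dba = mdf_distance(a, b), mdf_distance(b, a)
            assert dab == pytest.approx(dba, abs=1e-9)
            assert mdf_distance(a, c) <= dab + mdf_distance(b, c) + 1e-9


@pytest.fixture(scope="module")
def template():
    arcs = [
        circular_arc(10.0, 280.0, center=(0, 0, 0)),
        circular_arc(12.0, 275.0, center=(60, 0, 0), plane=("y", "z")),
        circular_arc(9.0, 290.0, center=(0, 60, 0), plane=("x", "z")),
    ]
    return [TemplateTract(tract_id=i + 1, streamlines=[a]) for i, a in enumerate(arcs)]


class TestPropagation:
    def test_prototype_maps_to_own_tract(self, template):
        t = Tractogram([template[1].prototype.copy()])
        cs = propagate_labels(t, template)
        assert cs.clusters.keys() == {2}

    def test_permutation_invariance(self, template, rng):
        streamlines = []
        for tt in template:
            for _ in range(10):
                streamlines.append(tt.prototype + rng.normal(0, 0.5, size=tt.prototype.shape))
        t = Tractogram(streamlines)
        cs1 = propagate_labels(t, template)
        perm = rng.permutation(len(streamlines))
        cs2 = propagate_labels(Tractogram([streamlines[i] for i in perm]), template)
        lab1 = np.empty(len(streamlines), dtype=int)
        for tid in cs1.clusters:
            lab1[cs1.indices[tid]] = tid
        # streamline j of the shuffled tractogram is streamline perm[j] originally
        for tid in cs2.clusters:
            for j in cs2.indices[tid]:
                assert lab1[perm[j]] == tid

    def test_tie_breaks_to_lowest_tract_id(self):
        line = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        template = [
            TemplateTract(tract_id=7, streamlines=[line + np.array([0, 5.0, 0])]),
            TemplateTract(tract_id=3, streamlines=[line - np.array([0, 5.0, 0])]),
        ]
        cs = propagate_labels(Tractogram([line]), template)
        assert cs.clusters.keys() == {3}

    def test_max_dist_leaves_streamlines_unassigned(self, template):
        far = template[0].prototype + np.array([500.0, 0, 0])
        cs = propagate_labels(Tractogram([far]), template, max_dist=100.0)
        assert cs.unassigned == [0] and not cs.clusters

    def test_members_flip_aligned_to_prototype(self, template, rng):
        proto = template[0].prototype
        member = proto + rng.normal(0, 0.1, size=proto.shape)
        cs = propagate_labels(Tractogram([member[::-1].copy()]), template)
        aligned = cs.clusters[1][0]
        assert np.linalg.norm(aligned[0] - proto[0]) < np.linalg.norm(aligned[-1] - proto[0])

    def test_synthetic_bundles_recovered(self):
        cfg = SynthConfig(n_bundles=2, seed=4, grid_shape=(40, 40, 40))
        template = make_template(cfg)
        rng = np.random.default_rng(1)
        streamlines, truth = [], []
        for tt in template.tracts:
            for _ in range(50):
                m = tt.streamlines[rng.integers(len(tt.streamlines))]
                streamlines.append(m + rng.normal(0, 0.3, size=m.shape))
                truth.append(tt.tract_id)
        cs = propagate_labels(Tractogram(streamlines), template.tracts)
        correct = sum(
            1 for tid in cs.clusters for i in cs.indices[tid] if truth[i] == tid
        )
        assert correct / len(streamlines) >= 0.99


@pytest.fixture
def label_volume():
    grid = np.zeros((10, 10, 10), dtype=np.int32)
    grid[2, 2, 2] = 3
    grid[8, 2, 2] = 7
    lookup = {
        3: ParcelInfo("sup_frontal", "frontal", "L"),
        7: ParcelInfo("mid_temporal", "temporal", "L"),
    }
    return LabelVolume(grid=grid, affine=np.diag([2.0, 2.0, 2.0, 1.0]), lookup=lookup)


class TestParcelAssignment:
    def test_point_at_voxel_center(self, label_volume):
        assert assign_endpoint_parcel(np.array([4.0, 4.0, 4.0]), label_volume) == 3

    def test_beyond_radius_unassigned(self, label_volume):
        # 5 mm from the labelled voxel center at (4,4,4), radius 4 mm
        assert assign_endpoint_parcel(np.array([9.0, 4.0, 4.0]), label_volume) is None

    def test_outside_volume_unassigned(self, label_volume):
        assert assign_endpoint_parcel(np.array([500.0, 500.0, 500.0]), label_volume) is None

    def test_equidistant_tie_takes_lowest_label(self):
        grid = np.zeros((11, 1, 1), dtype=np.int32)
        grid[4, 0, 0] = 7
        grid[6, 0, 0] = 3
        lv = LabelVolume(
            grid=grid,
            affine=np.eye(4),
            lookup={3: ParcelInfo("a", "frontal", "L"), 7: ParcelInfo("b", "frontal", "L")},
        )
        assert assign_endpoint_parcel(np.array([5.0, 0.0, 0.0]), lv, radius=2.0) == 3


class TestTractNodes:
    def _streamline(self, a, b):
        return np.stack([np.asarray(a, float), np.asarray(b, float)])

    def test_consistent_endpoints(self, label_volume):
        sl = [self._streamline([4, 4, 4], [16, 4, 4]) for _ in range(5)]
        assert assign_tract_nodes(sl, label_volume) == (3, 7)

    def test_majority_vote(self):
        grid = np.zeros((30, 1, 1), dtype=np.int32)
        grid[0], grid[10], grid[20] = 1, 2, 5
        lv = LabelVolume(
            grid=grid,
            affine=np.eye(4),
            lookup={k: ParcelInfo(f"p{k}", "frontal", "L") for k in (1, 2, 5)},
        )
        a_to_b = [self._streamline([0, 0, 0], [10, 0, 0])] * 8
        a_to_c = [self._streamline([0, 0, 0], [20, 0, 0])] * 2
        assert assign_tract_nodes(a_to_b + a_to_c, lv) == (1, 2)

    def test_single_parcel_gives_self_pair(self, label_volume):
        sl = [self._streamline([4, 4, 4], [4.5, 4, 4]) for _ in range(10)]
        assert assign_tract_nodes(sl, label_volume) == (3, 3)

    def test_all_unassigned_flagged(self, label_volume):
        sl = [self._streamline([15, 15, 15], [16, 15, 15])]
        assert assign_tract_nodes(sl, label_volume) is None


class TestSelection:
    def _cluster_sets(self, counts_per_subject, tract_id=1):
        out = []
        for c in counts_per_subject:
            cs = ClusterSet()
            if c > 0:
                s = np.array([[0.0, 0, 0], [1.0, 0, 0]])
                cs.clusters[tract_id] = [s] * c
                cs.indices[tract_id] = list(range(c))
            out.append(cs)
        return out

    @pytest.fixture
    def frontal_labels(self):
        grid = np.zeros((4, 1, 1), dtype=np.int32)
        grid[0, 0, 0], grid[1, 0, 0], grid[2, 0, 0] = 1, 2, 9
        return LabelVolume(
            grid=grid,
            affine=np.eye(4),
            lookup={
                1: ParcelInfo("f1", "frontal", "L"),
                2: ParcelInfo("f2", "frontal", "L"),
                9: ParcelInfo("t1", "temporal", "L"),
            },
        )

    def test_presence_rule_needs_both_groups(self, frontal_labels):
        # present in 80% of controls but only 60% of patients -> excluded
        controls = self._cluster_sets([5, 5, 5, 5, 0])
        patients = self._cluster_sets([5, 5, 5, 0, 0])
        nodes = {1: (1, 2)}
        kept = select_analysis_tracts(controls, patients, nodes, frontal_labels)
        assert kept == []

    def test_exactly_five_streamlines_everywhere_included(self, frontal_labels):
        controls = self._cluster_sets([5, 5, 5])
        patients = self._cluster_sets([5, 5, 5])
        kept = select_analysis_tracts(controls, patients, {1: (1, 2)}, frontal_labels)
        assert kept == [1]

    def test_non_frontal_node_excluded(self, frontal_labels):
        controls = self._cluster_sets([9, 9, 9])
        patients = self._cluster_sets([9, 9, 9])
        kept = select_analysis_tracts(controls, patients, {1: (1, 9)}, frontal_labels)
        assert kept == []


class TestSurfaceMapping:
    def test_single_tract_owns_all_vertices(self, rng):
        verts = rng.uniform(0, 50, size=(100, 3))
        labels = map_tracts_to_surface({4: np.array([[10.0, 10, 10], [40.0, 40, 40]])}, verts)
        assert np.all(labels == 4)

    def test_two_centroid_example(self):
        centroids = {1: np.array([[0.0, 0, 0]]), 2: np.array([[10.0, 0, 0]])}
        labels = map_tracts_to_surface(centroids, np.array([[2.0, 0, 0]]))
        assert labels.tolist() == [1]

    def test_matches_exhaustive_nearest_scan(self, rng):
        centroids = {tid: rng.uniform(0, 60, size=(2, 3)) for tid in (1, 2, 3, 5)}
        verts = rng.uniform(0, 60, size=(1000, 3))
        labels = map_tracts_to_surface(centroids, verts)
        flat = [(tid, c) for tid in sorted(centroids) for c in centroids[tid]]
        for v, lab in zip(verts, labels):
            best = min(flat, key=lambda tc: (np.linalg.norm(v - tc[1]), tc[0]))
            assert best[0] == lab
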