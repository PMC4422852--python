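"""CCS filtering, superposition and conformer clustering."""

import numpy as np
import pytest

import phosbridge as pb


def blob_structures(rng, centers, sizes, jitter=0.3, n_atoms=9):
    """Clusters of near-identical structures around distinct templates."""
    out = []
    for c, (center, size) in enumerate(zip(centers, sizes)):
        template = rng.normal(scale=4.0, size=(n_atoms, 3)) + center
        for i in range(size):
            coords = template + rng.normal(scale=jitter, size=(n_atoms, 3))
            out.append(
                pb.Structure(
                    np.array(["C"] * n_atoms),
                    coords,
                    np.arange(1, n_atoms + 1),
                    np.array(["ALA"] * n_atoms),
                    np.array(["CA"] * n_atoms),
                    f"blob{c}_{i}",
                )
            )
    return out


class TestFilterByCcs:
    def test_inclusive_boundary(self):
        s = blob_structures(np.random.default_rng(0), [np.zeros(3)], [3])
        records = list(zip(s, [103.0, 103.01, 97.0]))
        kept = pb.filter_by_ccs(pb.ConformerSet(records, 100.0, 0.03))
        assert [c for _, c in kept.records] == [103.0, 97.0]

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(42)
        target = 350.0
        ccs = rng.uniform(0.9 * target, 1.1 * target, size=1000)
        structs = blob_structures(rng, [np.zeros(3)], [1000], jitter=0.0)
        kept = pb.filter_by_ccs(
            pb.ConformerSet(list(zip(structs, ccs)), target, 0.03)
        )
        brute = sum(1 for c in ccs if abs(c - target) / target <= 0.03)
        assert len(kept) == brute

    def test_empty_result_allowed(self):
        s = blob_structures(np.random.default_rng(1), [np.zeros(3)], [2])
        kept = pb.filter_by_ccs(pb.ConformerSet(list(zip(s, [1.0, 2.0])), 100.0))
        assert len(kept) == 0


class TestSuperpose:
    def test_identical_structures(self):
        (s,) = blob_structures(np.random.default_rng(2), [np.zeros(3)], [1])
        _, rmsd = pb.superpose(s, s)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotated_copy_recovered(self):
        (s,) = blob_structures(np.random.default_rng(3), [np.zeros(3)], [1])
        theta = 0.8
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = pb.Structure(
            s.elements, s.coords @ rot.T + 5.0, s.res_ids, s.res_names,
            s.atom_names, "moved",
        )
        _, rmsd = pb.superpose(moved, s)
        assert rmsd < 1e-6

    def test_known_orthogonal_displacement(self):
        # square in the xy-plane, z-displacements with zero net shift and
        # zero net torque: the optimal transform is the identity, so the
        # rmsd equals the displacement magnitude (to first order)
        coords = np.array(
            [[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], dtype=float
        )
        delta = 1e-3
        disp = np.array([+delta, -delta, -delta, +delta])
        moved_coords = coords.copy()
        moved_coords[:, 2] += disp
        mk = lambda c, lab: pb.Structure(
            np.array(["C"] * 4), c, np.arange(1, 5),
            np.array(["ALA"] * 4), np.array(["CA"] * 4), lab,
        )
        _, rmsd = pb.superpose(mk(moved_coords, "m"), mk(coords, "r"))
        assert rmsd == pytest.approx(delta, rel=1e-3)

    def test_mismatched_selection_rejected(self):
        a = blob_structures(np.random.default_rng(4), [np.zeros(3)], [1], n_atoms=5)[0]
        b = blob_structures(np.random.default_rng(4), [np.zeros(3)], [1], n_atoms=6)[0]
        with pytest.raises(ValueError):
            pb.superpose(a, b)


class TestCluster:
    def test_k1_single_cluster(self):
        rng = np.random.default_rng(5)
        s = blob_structures(rng, [np.zeros(3)], [8])
        cs = pb.ConformerSet(list(zip(s, [100.0] * 8)), 100.0)
        c = pb.cluster(cs, k=1, seed=0)
        assert c.populations.tolist() == [100.0]
        assert c.representatives[0] in [x.label for x in s]

    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(6)
        centers = [np.array([0, 0, 0]), np.array([60, 0, 0]), np.array([0, 60, 0])]
        s = blob_structures(rng, centers, [50, 30, 20], jitter=0.5)
        cs = pb.ConformerSet(list(zip(s, [100.0] * 100)), 100.0)
        c = pb.cluster(cs, k=3, seed=1)
        assert sorted(c.populations.tolist(), reverse=True) == [50.0, 30.0, 20.0]
        # exact membership: all structures of one blob share one label
        labels = np.asarray(c.labels)
        for lo, hi in [(0, 50), (50, 80), (80, 100)]:
            assert len(set(labels[lo:hi])) == 1

    def test_n_equals_k_singletons(self):
        rng = np.random.default_rng(7)
        centers = [np.array([40.0 * i, 0, 0]) for i in range(4)]
        s = blob_structures(rng, centers, [1, 1, 1, 1])
        cs = pb.ConformerSet(list(zip(s, [100.0] * 4)), 100.0)
        c = pb.cluster(cs, k=4, seed=0)
        assert sorted(c.populations.tolist()) == [25.0] * 4

    def test_populations_sum_and_representative_membership(self):
        rng = np.random.default_rng(8)
        s = blob_structures(rng, [np.zeros(3), np.array([50, 0, 0])], [6, 4])
        cs = pb.ConformerSet(list(zip(s, [100.0] * 10)), 100.0)
        c = pb.cluster(cs, k=2, seed=3)
        assert c.populations.sum() == pytest.approx(100.0)
        labels = {x.label: l for x, l in zip([r[0] for r in cs.records], c.labels)}
        for cid, rep in enumerate(c.representatives):
            assert labels[rep] == cid

    def test_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(9)
        centers = [np.zeros(3), np.array([80, 0, 0])]
        s = blob_structures(rng, centers, [6, 4], jitter=0.2)
        recs = list(zip(s, [100.0] * 10))
        c1 = pb.cluster(pb.ConformerSet(recs, 100.0), k=2, seed=0)
        perm = list(reversed(recs))
        c2 = pb.cluster(pb.ConformerSet(perm, 100.0), k=2, seed=0)
        assert sorted(c1.populations.tolist()) == sorted(c2.populations.tolist())
        # same partition of structure labels, up to cluster relabeling
        def partition(recs, labels):
            groups = {}
            for (s, _), l in zip(recs, labels):
                groups.setdefault(l, set()).add(s.label)
            return sorted(map(frozenset, groups.values()), key=sorted)

        assert partition(recs, c1.labels) == partition(perm, c2.labels)

    def test_too_few_structures(self):
        rng = np.random.default_rng(10)
        s = blob_structures(rng, [np.zeros(3)], [2])
        cs = pb.ConformerSet(list(zip(s, [100.0] * 2)), 100.0)
        with pytest.raises(ValueError):
            pb.cluster(cs, k=3, seed=0)


class TestTopClusters:
    def _clustering(self, pops):
        return pb.Clustering(
            labels=np.zeros(1, dtype=int),
            k=len(pops),
            populations=np.array(pops, dtype=float),
            representatives=["s"] * len(pops),
            inertia=0.0,
        )

    def test_descending_population_order(self):
        # the published population shape: ~16/13/10% of filtered structures
        pops = [13.0, 16.0, 10.0, 61.0]
        c = self._clustering(pops)
        assert pb.top_clusters(c, 3) == [3, 1, 0]

    def test_ties_broken_by_id(self):
        c = self._clustering([25.0, 25.0, 25.0, 25.0])
        assert pb.top_clusters(c, 4) == [0, 1, 2, 3]

    def test_n_too_large(self):
        c = self._clustering([50.0, 50.0])
        with pytest.raises(ValueError):
            pb.top_clusters(c, 3)
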