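"""Profile fusion, K-means selection, multilevel clustering, subset search."""

from itertools import combinations as itercombos

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from combiscreen.design import Combination
from combiscreen.mining import (
    FusedProfile,
    fuse_profiles,
    group_report,
    kmeans_partition,
    multilevel_cluster,
    nonredundant_subset,
    select_k,
)


class TestFusion:
    def test_length_is_four_blocks(self):
        n = 17
        rng = np.random.default_rng(0)
        prof = fuse_profiles(
            rng.normal(size=n), rng.normal(size=n), rng.normal(size=n), 0.8
        )
        assert prof.x.size == 4 * n

    def test_constant_viability_block_preserved(self):
        prof = fuse_profiles(np.arange(5.0), np.arange(5.0), np.arange(5.0), 0.7)
        assert np.allclose(prof.x[15:], 0.7)

    def test_scale_invariance_of_nonconstant_blocks(self):
        rng = np.random.default_rng(1)
        dC, dM, cnt = rng.normal(size=8), rng.normal(size=8), rng.normal(size=8)
        a = fuse_profiles(dC, dM, cnt, 0.5)
        b = fuse_profiles(10 * dC, dM, cnt, 0.5)
        assert np.allclose(a.x, b.x)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_profiles(np.ones(3), np.ones(4), np.ones(3), 1.0)


class TestKMeans:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 5))
        _, _, sse = kmeans_partition(X, 1)
        assert sse == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_k_equals_n_zero_sse(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        _, _, sse = kmeans_partition(X, 6, repeats=5, seed=0)
        assert sse == pytest.approx(0.0, abs=1e-20)

    def test_small_instance_matches_exhaustive_oracle(self):
        """Best-of-repeats K-means attains the optimum found by enumerating
        every 2-coloring of 8 points."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))

        def sse_of(labels):
            total = 0.0
            for k in (0, 1):
                pts = X[np.array(labels) == k]
                if len(pts):
                    total += ((pts - pts.mean(axis=0)) ** 2).sum()
            return total

        brute = min(
            sse_of([int(b) for b in np.binary_repr(m, 8)]) for m in range(1, 255)
        )
        _, _, sse = kmeans_partition(X, 2, repeats=20, seed=0)
        assert sse == pytest.approx(brute, rel=1e-9)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            kmeans_partition(np.ones((3, 2)), 4)

    def test_sse_nonincreasing_in_k(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        sses = [kmeans_partition(X, k, repeats=5, seed=k)[2] for k in range(1, 8)]
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))


def gaussian_clusters(centers, n_per, sd, dim, seed):
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for i, c in enumerate(centers):
        X.append(c + rng.normal(0, sd, size=(n_per, dim)))
        labels += [i] * n_per
    return np.vstack(X), np.array(labels)


class TestSelectK:
    def test_identical_points(self):
        X = np.ones((10, 4))
        k, _ = select_k(X, repeats=3, seed=0)
        assert k == 1

    def test_two_separated_clusters(self):
        centers = [np.zeros(6), np.full(6, 20.0)]
        X, _ = gaussian_clusters(centers, 15, 0.5, 6, seed=6)
        k, trace = select_k(X, repeats=5, seed=0)
        assert k == 2
        # the drop rule verified directly on the SSE trace
        assert (trace[2] - trace[1]) / trace[1] * 100 <= -20

    def test_isotropic_cloud_stays_single(self):
        """In high dimension a single Gaussian cloud never drops 20% per split."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 40))
        k, trace = select_k(X, repeats=5, seed=0)
        assert k == 1
        drops = [
            (trace[k_] - trace[k_ - 1]) / trace[k_ - 1] * 100
            for k_ in sorted(trace) if k_ > 1
        ]
        assert all(d > -20 for d in drops)


def hierarchical_profiles(seed=0, n_per=8, drugs="ABCDEFG"):
    """2 super-groups x 2 subgroups in fused-profile space, with labels."""
    rng = np.random.default_rng(seed)
    n = 17
    profiles, truth = [], []
    idx = 0
    for g, base in enumerate((0.0, 12.0)):
        for s, offset in enumerate((-1.5, 1.5)):
            for _ in range(n_per):
                x = base + offset + rng.normal(0, 0.35, 4 * n)
                cond = Combination((drugs[idx % len(drugs)],))
                profiles.append(FusedProfile(condition=cond, x=x))
                truth.append((g, s))
                idx += 1
    return profiles, truth


class TestMultilevel:
    def test_recovers_two_by_two_structure(self):
        profiles, truth = hierarchical_profiles(seed=8)
        tree = multilevel_cluster(profiles, min_size=4, seed=0)
        assert tree.selected_k == 2
        assert len(tree.children) == 2
        assert all(len(c.children) == 2 for c in tree.children)
        leaves = tree.leaves()
        assert len(leaves) == 4
        # leaf membership matches planted labels
        pred = np.empty(len(profiles), dtype=int)
        for i, leaf in enumerate(leaves):
            pred[leaf.members] = i
        true = [g * 2 + s for g, s in truth]
        assert adjusted_rand_score(true, pred) >= 0.9

    def test_homogeneous_single_leaf(self):
        rng = np.random.default_rng(9)
        profiles = [
            FusedProfile(condition=Combination(("A",)), x=rng.normal(size=40))
            for _ in range(20)
        ]
        tree = multilevel_cluster(profiles, min_size=4, seed=0)
        assert tree.is_leaf

    def test_seeded_determinism(self):
        profiles, _ = hierarchical_profiles(seed=10)

        def shape(node):
            return (len(node.members), [shape(c) for c in node.children])

        t1 = multilevel_cluster(profiles, min_size=4, seed=3)
        t2 = multilevel_cluster(profiles, min_size=4, seed=3)
        assert shape(t1) == shape(t2)

    def test_children_partition_parent(self):
        profiles, _ = hierarchical_profiles(seed=11)
        tree = multilevel_cluster(profiles, min_size=4, seed=0)

        def check(node):
            if node.children:
                merged = sorted(m for c in node.children for m in c.members)
                assert merged == sorted(node.members)
                for c in node.children:
                    check(c)

        check(tree)


def brute_force_minimal(group):
    """Oracle: members that contain no other member as a subset."""
    sets = [set(c.members) for c in group]
    return sorted(
        {
            c
            for c, s in zip(group, sets)
            if not any(o < s for o in sets)
        },
        key=lambda c: (c.order, c.members),
    )


class TestNonredundantSubset:
    def test_single_driver(self):
        group = [
            Combination(("X",)),
            Combination(("X", "Y")),
            Combination(("X", "Z", "W")),
        ]
        assert nonredundant_subset(group) == [Combination(("X",))]

    def test_two_minimal_elements(self):
        group = [Combination(("X",)), Combination(("X", "Y")), Combination(("Y", "Z"))]
        assert nonredundant_subset(group) == brute_force_minimal(group)

    def test_driver_drug_dominates_its_supersets(self):
        """A drug plus every combination containing it reduces to the drug."""
        drugs = "ABCDEFGHI"
        group = [Combination(("E",))] + [
            Combination(("E",) + c)
            for k in (1, 2, 3)
            for c in itercombos([d for d in drugs if d != "E"], k)
        ]
        assert nonredundant_subset(group) == [Combination(("E",))]

    def test_mixed_orders_can_coexist(self):
        group = [Combination(("A", "B")), Combination(("C", "D", "E", "F"))]
        reps = nonredundant_subset(group)
        assert {r.order for r in reps} == {2, 4}

    @pytest.mark.parametrize("seed", range(25))
    def test_random_families_match_antichain_oracle(self, seed):
        rng = np.random.default_rng(seed)
        drugs = list("ABCDEFGHI")
        group = []
        for _ in range(int(rng.integers(3, 15))):
            k = int(rng.integers(1, 5))
            members = tuple(rng.choice(drugs, size=k, replace=False))
            group.append(Combination(members))
        result = nonredundant_subset(group)
        oracle = brute_force_minimal(list(set(group)))
        assert sorted(result, key=lambda c: (c.order, c.members)) == oracle
        # antichain: no representative contains another
        for a in result:
            for b in result:
                if a != b:
                    assert not a.contains(b)
        # coverage: every member is a superset of some representative
        for c in set(group):
            assert any(c.contains(r) for r in result)

    def test_input_order_independence(self):
        rng = np.random.default_rng(99)
        group = [
            Combination(tuple(rng.choice(list("ABCDE"), size=k, replace=False)))
            for k in (1, 2, 2, 3, 3, 4)
        ]
        a = nonredundant_subset(group)
        b = nonredundant_subset(group[::-1])
        assert a == b


class TestGroupReport:
    def test_leaf_average_is_member_profile(self):
        profiles, _ = hierarchical_profiles(seed=12, n_per=4)
        tree = multilevel_cluster(profiles, min_size=3, seed=0)
        report = group_report(tree, profiles)
        for entry in report:
            node_members = entry["members"]
            if entry["n_members"] == 1:
                i = next(
                    j
                    for j, p in enumerate(profiles)
                    if p.condition.label() == node_members[0]
                )
                got = np.concatenate(
                    [
                        entry["avg_delta_confluence"],
                        entry["avg_delta_morphology"],
                        entry["avg_counts"],
                        entry["avg_viability"],
                    ]
                )
                assert np.allclose(got, profiles[i].x)

    def test_averages_match_recomputation(self):
        profiles, _ = hierarchical_profiles(seed=13, n_per=5)
        tree = multilevel_cluster(profiles, min_size=3, seed=0)
        report = group_report(tree, profiles)
        root_entry = next(e for e in report if e["path"] == "root")
        X = np.vstack([p.x for p in profiles])
        n = 17
        assert np.allclose(root_entry["avg_delta_confluence"], X.mean(axis=0)[:n])
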