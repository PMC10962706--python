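"""Absolute-cosine similarity, batching, agglomerative clustering, refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ssphase.clustering import (
    UNCLUSTERED,
    Clustering,
    ClusteringParams,
    abs_cos,
    cluster_batched,
    cluster_unitigs,
    make_batches,
    refine,
    set_similarity,
)


class TestAbsCos:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 0], [0, 1], 0.0),
            ([1, -1, 0], [-1, 1, 0], 1.0),
            ([1, 1], [1, 0], 0.70711),
        ],
    )
    def test_examples(self, a, b, expected):
        assert abs_cos(a, b) == pytest.approx(expected, abs=1e-5)

    def test_zero_vector_similarity_is_zero(self):
        assert abs_cos([0, 0], [1, 2]) == 0.0

    def test_dimension_mismatch_fatal(self):
        with pytest.raises(ValueError):
            abs_cos([1, 0], [1, 0, 0])

    vectors = hnp.arrays(
        np.float64, 4, elements=st.floats(-1, 1, allow_nan=False, width=32)
    )

    @given(a=vectors, b=vectors, k=st.floats(0.01, 100))
    @settings(deadline=None, max_examples=200)
    def test_symmetry_negation_and_scaling(self, a, b, k):
        s = abs_cos(a, b)
        assert 0.0 <= s <= 1.0 + 1e-12
        assert abs_cos(b, a) == pytest.approx(s)
        assert abs_cos(-a, b) == pytest.approx(s)
        assert abs_cos(k * a, b) == pytest.approx(s, abs=1e-9)
        if np.linalg.norm(a) > 0:
            assert abs_cos(a, -a) == pytest.approx(1.0)


class TestSetSimilarity:
    def test_self_similarity(self):
        v = np.array([1.0, 2.0, 3.0])
        assert set_similarity([v], [v]) == pytest.approx(1.0)

    def test_mean_of_pairs(self):
        A = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        assert set_similarity(A, [np.array([1.0, 0.0])]) == pytest.approx(0.5)

    def test_singletons_equal_abs_cos(self):
        a, b = np.array([1.0, 1.0]), np.array([1.0, 0.0])
        assert set_similarity([a], [b]) == pytest.approx(abs_cos(a, b))

    def test_empty_set_fatal(self):
        with pytest.raises(ValueError):
            set_similarity([], [np.array([1.0])])


class TestMakeBatches:
    def test_plain_chunking(self):
        cov = {f"u{i}": float(10_000 - i) for i in range(10_000)}
        batches = make_batches(cov)
        assert len(batches) == 10
        assert all(len(b) == 1000 for b in batches)
        # descending coverage order: first batch holds highest coverages
        assert batches[0][0] == "u0"

    def test_quantile_fallback(self):
        cov = {f"u{i}": float(i) for i in range(2500)}
        batches = make_batches(cov)
        assert len(batches) == 5
        assert all(len(b) == 500 for b in batches)

    def test_fewer_unitigs_than_batches(self):
        cov = {f"u{i}": float(i) for i in range(4)}
        batches = make_batches(cov)
        assert len(batches) == 4
        assert all(len(b) == 1 for b in batches)


def _ideal_vectors(n_chroms=3, per_chrom=2, n_libs=12, seed=0):
    """Separable instance: per chromosome a random +/-1/0 direction."""
    rng = np.random.default_rng(seed)
    vectors, truth = {}, {}
    for c in range(n_chroms):
        direction = rng.choice([-1.0, 0.0, 1.0], size=n_libs)
        while np.count_nonzero(direction) < n_libs // 2:
            direction = rng.choice([-1.0, 0.0, 1.0], size=n_libs)
        for k in range(per_chrom):
            uid = f"c{c}u{k}"
            sign = 1.0 if k % 2 == 0 else -1.0  # misoriented copies allowed
            vectors[uid] = sign * direction
            truth[uid] = c
    return vectors, truth


def _partition_equal(clustering: Clustering, truth: dict) -> bool:
    groups = {}
    for u, c in clustering.assignment.items():
        if c == UNCLUSTERED:
            return False
        groups.setdefault(c, set()).add(u)
    want = {}
    for u, c in truth.items():
        want.setdefault(c, set()).add(u)
    return set(map(frozenset, groups.values())) == set(map(frozenset, want.values()))


class TestClusterBatched:
    def test_recovers_separable_partition(self):
        vectors, truth = _ideal_vectors(n_chroms=3, per_chrom=2, seed=1)
        params = ClusteringParams(grow_thresh=0.9, create_thresh=0.9, merge_thresh=0.8)
        components = {u: 0 for u in vectors}
        result = cluster_batched(vectors, components, params)
        assert _partition_equal(result, truth)

    def test_zero_vector_stays_unclustered(self):
        vectors = {"a": np.array([1.0, 0.0]), "b": np.array([1.0, 0.0]), "z": np.zeros(2)}
        result = cluster_batched(vectors, {u: 0 for u in vectors}, ClusteringParams())
        assert result.assignment["z"] == UNCLUSTERED

    def test_identical_pair_forms_cluster(self):
        v = np.array([1.0, 2.0, 0.0])
        params = ClusteringParams(create_thresh=0.99)
        result = cluster_batched({"a": v, "b": v.copy()}, {"a": 0, "b": 0}, params)
        assert result.assignment["a"] == result.assignment["b"] != UNCLUSTERED


class TestRefine:
    params = ClusteringParams(min_cluster_size=3, component_cov_thresh=0.02)

    def test_small_cluster_dissolved(self):
        # two clusters survive on the component, so the dissolved singleton
        # is not re-absorbed by the single-cluster rule
        c = Clustering(
            {"a": 0, "b": 1, "c": 1, "d": 1, "e": 2, "f": 2, "g": 2}
        )
        lengths = {u: 100_000 for u in c.assignment}
        comps = {u: 0 for u in c.assignment}
        out = refine(c, lengths, comps, self.params)
        assert out.assignment["a"] == UNCLUSTERED
        assert out.provenance["a"] == "refined"

    def test_low_bp_cluster_dissolved(self):
        # cluster 2 holds ~1% of its component's clustered bp; two other
        # clusters survive so the strays are not re-absorbed
        assignment = {f"b{i}": 0 for i in range(5)}
        assignment.update({f"m{i}": 1 for i in range(5)})
        assignment.update({f"s{i}": 2 for i in range(3)})
        lengths = {f"b{i}": 10_000_000 for i in range(5)}
        lengths.update({f"m{i}": 9_800_000 for i in range(5)})
        lengths.update({f"s{i}": 333_333 for i in range(3)})
        comps = {u: 0 for u in assignment}
        out = refine(Clustering(assignment), lengths, comps, self.params)
        assert all(out.assignment[f"s{i}"] == UNCLUSTERED for i in range(3))
        assert all(out.assignment[f"b{i}"] == 0 for i in range(5))

    def test_single_cluster_component_absorbs_strays(self):
        assignment = {"a": 0, "b": 0, "c": 0, "x": UNCLUSTERED, "y": UNCLUSTERED}
        lengths = {u: 100_000 for u in assignment}
        comps = {u: 0 for u in assignment}
        out = refine(Clustering(assignment), lengths, comps, self.params)
        assert out.assignment["x"] == 0 and out.assignment["y"] == 0
        assert out.provenance["x"] == "absorbed"

    def test_idempotent(self):
        assignment = {"a": 0, "b": 1, "c": 1, "d": 1, "e": UNCLUSTERED}
        lengths = {u: 100_000 for u in assignment}
        comps = {u: 0 for u in assignment}
        once = refine(Clustering(assignment), lengths, comps, self.params)
        twice = refine(once, lengths, comps, self.params)
        assert once.assignment == twice.assignment


class TestClusterUnitigs:
    def test_empty_input(self):
        result, audit = cluster_unitigs({}, {}, {})
        assert result.assignment == {}
        assert audit

    def test_recovery_invariant_to_batch_order(self):
        vectors, truth = _ideal_vectors(n_chroms=4, per_chrom=4, n_libs=16, seed=3)
        params = ClusteringParams(
            grow_thresh=0.9, create_thresh=0.9, merge_thresh=0.8, min_cluster_size=2
        )
        comps = {u: 0 for u in vectors}
        lengths = {u: 1_000_000 for u in vectors}
        ids = sorted(vectors)
        rng = np.random.default_rng(0)
        for _ in range(5):
            order = list(rng.permutation(ids))
            batches = [order[i::4] for i in range(4)]
            result, _ = cluster_unitigs(
                vectors, comps, lengths, params, batches=batches
            )
            assert _partition_equal(result, truth)

    def test_scale_robustness_of_assignment(self):
        # shrinking one unitig's SSF uniformly (degenerate region) changes nothing
        vectors, truth = _ideal_vectors(n_chroms=3, per_chrom=3, seed=5)
        params = ClusteringParams(
            grow_thresh=0.9, create_thresh=0.9, merge_thresh=0.8, min_cluster_size=2
        )
        comps = {u: 0 for u in vectors}
        lengths = {u: 1_000_000 for u in vectors}
        base, _ = cluster_unitigs(vectors, comps, lengths, params)
        for s in (0.5, 0.1, 0.01):
            shrunk = dict(vectors)
            shrunk["c0u0"] = s * vectors["c0u0"]
            result, _ = cluster_unitigs(shrunk, comps, lengths, params)
            assert result.assignment == base.assignment

    def test_library_permutation_invariance(self):
        vectors, _ = _ideal_vectors(n_chroms=3, per_chrom=3, seed=7)
        params = ClusteringParams(
            grow_thresh=0.9, create_thresh=0.9, merge_thresh=0.8, min_cluster_size=2
        )
        comps = {u: 0 for u in vectors}
        lengths = {u: 1_000_000 for u in vectors}
        base, _ = cluster_unitigs(vectors, comps, lengths, params)
        perm = np.random.default_rng(1).permutation(len(next(iter(vectors.values()))))
        permuted = {u: v[perm] for u, v in vectors.items()}
        result, _ = cluster_unitigs(permuted, comps, lengths, params)
        assert result.assignment == base.assignment
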