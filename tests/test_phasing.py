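"""Phase geometry: haploid detection, plane inference, pooling, calls."""

import numpy as np
import pytest

from ssphase.clustering import Clustering
from ssphase.counts import CountMatrix
from ssphase.phasing import (
    Haplotype,
    call_haplotypes,
    chromosome_plane,
    cluster_vector,
    detect_haploid,
    haploid_correction,
    phase_vector,
    pool_markers,
)


class TestClusterVector:
    def test_single_unitig_identity(self):
        v = np.array([0.5, -1.0, 0.0])
        assert cluster_vector({"a": v}, {"a": 1_000_000}) == pytest.approx(v)

    def test_equal_length_mean(self):
        vecs = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        lengths = {"a": 2_000_000, "b": 2_000_000}
        assert cluster_vector(vecs, lengths) == pytest.approx([0.5, 0.5])

    def test_length_weighting(self):
        vecs = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        lengths = {"a": 3_000_000, "b": 1_000_000}
        assert cluster_vector(vecs, lengths) == pytest.approx([0.75, 0.25])

    def test_empty_cluster_fatal(self):
        with pytest.raises(ValueError):
            cluster_vector({}, {})


class TestChromosomePlane:
    def test_exact_subspace_recovered(self):
        rng = np.random.default_rng(0)
        coeffs = rng.normal(size=(6, 2))
        X = np.zeros((6, 5))
        X[:, 0] = coeffs[:, 0]
        X[:, 1] = coeffs[:, 1]
        basis, _, rank1 = chromosome_plane(X)
        assert not rank1
        # basis spans e1,e2: components outside first two dims vanish
        assert np.allclose(basis[:, 2:], 0.0, atol=1e-10)

    def test_rank1_flagged(self):
        a = np.array([1.0, -1.0, 0.0])
        basis, ev, rank1 = chromosome_plane(np.vstack([a, -a]))
        assert rank1
        assert ev[0] == pytest.approx(1.0)
        # completion still orthonormal
        assert basis @ basis.T == pytest.approx(np.eye(2), abs=1e-10)

    def test_diploid_cluster_lies_in_plane(self):
        # maternal/paternal/hom rays: residual energy outside plane ~ 0
        rng = np.random.default_rng(1)
        t = rng.choice([-1.0, 1.0], 20) * (rng.random(20) < 0.5)
        u = rng.choice([-1.0, 1.0], 20) * (t == 0)
        m, p, h = t + u, t - u, t
        X = np.vstack([m, m, p, p, h, h])
        basis, ev, _ = chromosome_plane(X)
        proj = X @ basis.T @ basis
        residual = np.linalg.norm(X - proj) ** 2 / np.linalg.norm(X) ** 2
        assert residual < 0.05
        assert ev[0] + ev[1] > 0.95


class TestPhaseVector:
    def test_coordinate_rotation(self):
        basis = np.eye(5)[:2]
        vp = phase_vector(np.array([1.0, 0, 0, 0, 0]), basis)
        assert np.abs(vp) == pytest.approx([0, 1, 0, 0, 0])

    def test_projection_of_in_plane_vector_is_full_norm(self):
        basis = np.eye(4)[:2]
        v = np.array([0.6, 0.8, 0.0, 0.0])
        xy = basis @ v
        assert np.linalg.norm(xy) == pytest.approx(np.linalg.norm(v))

    def test_orthogonal_to_projected_cluster_vector(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 6))
        basis, _, _ = chromosome_plane(rng.normal(size=(5, 6)))
        for v in A:
            vp = phase_vector(v, basis)
            proj = (basis @ v) @ basis
            assert vp @ proj == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_cluster_vector_fatal(self):
        basis = np.eye(4)[:2]
        with pytest.raises(ValueError, match="orthogonal"):
            phase_vector(np.array([0.0, 0.0, 1.0, 0.0]), basis)


def _angle_vec(theta_deg, basis):
    t = np.radians(theta_deg)
    return np.array([np.cos(t), np.sin(t)]) @ basis


class TestHaploidCorrection:
    basis = np.eye(6)[:2]

    def test_bisector_geometry(self):
        # v_clust along 0 deg; representatives at +40 and -20 -> new v_clust at +10
        v_clust = _angle_vec(0, self.basis)
        v_phase = _angle_vec(90, self.basis)
        vectors = {
            "r_plus": 2.0 * _angle_vec(40, self.basis),
            "r_minus": 1.5 * _angle_vec(-20, self.basis),
            "mid": _angle_vec(5, self.basis),
        }
        new_c, new_p = haploid_correction(v_clust, v_phase, vectors, self.basis)
        ang = np.degrees(np.arctan2((self.basis @ new_c)[1], (self.basis @ new_c)[0]))
        assert ang == pytest.approx(10.0, abs=1e-6)
        assert new_c @ new_p == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_representatives_unchanged(self):
        v_clust = _angle_vec(0, self.basis)
        v_phase = _angle_vec(90, self.basis)
        vectors = {
            "a": _angle_vec(30, self.basis),
            "b": _angle_vec(-30, self.basis),
        }
        new_c, _ = haploid_correction(v_clust, v_phase, vectors, self.basis)
        ang = np.degrees(np.arctan2((self.basis @ new_c)[1], (self.basis @ new_c)[0]))
        assert ang == pytest.approx(0.0, abs=1e-6)

    def test_unequal_haploid_chromosomes_separated(self):
        """Size-biased v_clust corrected so v_phase splits X from Y cleanly."""
        rng = np.random.default_rng(3)
        n_libs = 40
        sx = rng.choice([-1.0, 1.0], n_libs)
        sy = rng.choice([-1.0, 1.0], n_libs)
        vectors = {}
        lengths = {}
        for i in range(8):
            vectors[f"x{i}"] = sx * (1 + rng.normal(0, 0.01, n_libs))
            lengths[f"x{i}"] = 19_000_000  # X ~155 Mb total
        for i in range(4):
            vectors[f"y{i}"] = sy * (1 + rng.normal(0, 0.01, n_libs))
            lengths[f"y{i}"] = 14_000_000  # Y ~57 Mb total
        X = np.vstack(list(vectors.values()))
        basis, _, _ = chromosome_plane(X)
        v_clust = cluster_vector(vectors, lengths)
        v_phase = phase_vector(v_clust, basis)
        v_clust_c, v_phase_c = haploid_correction(v_clust, v_phase, vectors, basis)
        # corrected v_phase assigns X and Y unitigs opposite signs
        scores = {u: float(v @ v_phase_c) for u, v in vectors.items()}
        x_signs = {np.sign(scores[f"x{i}"]) for i in range(8)}
        y_signs = {np.sign(scores[f"y{i}"]) for i in range(4)}
        assert len(x_signs) == 1 and len(y_signs) == 1
        assert x_signs != y_signs


class TestDetectHaploid:
    def test_rank1_cluster_flagged(self):
        rng = np.random.default_rng(4)
        base = rng.choice([-1.0, 1.0], 20)
        vectors = {f"u{i}": base * (1 + rng.normal(0, 0.02)) for i in range(5)}
        clustering = Clustering({u: 0 for u in vectors})
        flags, _ = detect_haploid(clustering, vectors)
        assert flags[0] is True

    def test_diploid_cluster_not_flagged(self):
        rng = np.random.default_rng(5)
        t = rng.choice([-1.0, 1.0], 20) * (rng.random(20) < 0.5)
        u = rng.choice([-1.0, 1.0], 20) * (t == 0)
        vectors = {
            "m1": t + u, "m2": t + u, "p1": t - u, "p2": t - u, "h1": t, "h2": t,
        }
        clustering = Clustering({k: 0 for k in vectors})
        flags, _ = detect_haploid(clustering, vectors)
        assert flags[0] is False

    def test_two_haploid_clusters_merged(self):
        rng = np.random.default_rng(6)
        sx = rng.choice([-1.0, 1.0], 20)
        sy = rng.choice([-1.0, 1.0], 20)
        vectors = {f"x{i}": sx * (1 + 0.01 * i) for i in range(3)}
        vectors.update({f"y{i}": sy * (1 + 0.01 * i) for i in range(3)})
        assignment = {f"x{i}": 0 for i in range(3)}
        assignment.update({f"y{i}": 1 for i in range(3)})
        flags, merged = detect_haploid(Clustering(assignment), vectors)
        labels = {merged.assignment[u] for u in vectors}
        assert len(labels) == 1

    def test_tiny_cluster_unknown(self):
        flags, _ = detect_haploid(
            Clustering({"a": 0}), {"a": np.array([1.0, 0.0])}
        )
        assert flags[0] is None


class TestPoolMarkers:
    def test_swap_and_dot_rule(self):
        cm = CountMatrix(["u"], ["l1", "l2"], np.array([[5, 0]]), np.array([[0, 5]]))
        markers = pool_markers(cm, np.array([1.0, -1.0]))
        assert markers["u"] == pytest.approx((10.0, 0.0))

    def test_zero_phase_vector_gives_zero_markers(self):
        cm = CountMatrix(["u"], ["l1", "l2"], np.array([[5, 3]]), np.array([[2, 5]]))
        markers = pool_markers(cm, np.zeros(2))
        assert markers["u"] == (0.0, 0.0)

    def test_conservation_identity(self):
        rng = np.random.default_rng(7)
        W = rng.integers(0, 100, (10, 8))
        C = rng.integers(0, 100, (10, 8))
        cm = CountMatrix([f"u{i}" for i in range(10)], [f"l{j}" for j in range(8)], W, C)
        v_phase = rng.uniform(-1, 1, 8)
        markers = pool_markers(cm, v_phase)
        for i, u in enumerate(cm.unitigs):
            h1, h2 = markers[u]
            assert h1 + h2 == pytest.approx(np.abs(v_phase) @ (W[i] + C[i]))

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(8)
        W = rng.integers(0, 50, (5, 6))
        C = rng.integers(0, 50, (5, 6))
        cm = CountMatrix([f"u{i}" for i in range(5)], [f"l{j}" for j in range(6)], W, C)
        v_phase = rng.uniform(-1, 1, 6)
        m1 = pool_markers(cm, v_phase)
        m2 = pool_markers(cm, -v_phase)
        for u in cm.unitigs:
            assert m1[u][0] == pytest.approx(m2[u][1])
            assert m1[u][1] == pytest.approx(m2[u][0])


class TestCallHaplotypes:
    @pytest.mark.parametrize(
        "markers,expected",
        [
            ((100.0, 2.0), Haplotype.HAP1),
            ((2.0, 100.0), Haplotype.HAP2),
            ((50.0, 50.0), Haplotype.HOM),
            ((0.0, 0.0), Haplotype.NONE),
            ((4.0, 4.0), Haplotype.NONE),  # below min_total
        ],
    )
    def test_thresholds(self, markers, expected):
        assert call_haplotypes({"u": markers})["u"] is expected


def test_homozygous_unitigs_balanced_and_marker_rich(small_fit, small_bundle):
    """HOM unitigs get balanced markers and more total markers per bp."""
    truth = small_bundle.truth.unitigs.set_index("unitig")
    hom_rates, het_rates = [], []
    for u, (h1, h2) in small_fit.markers.items():
        row = truth.loc[u]
        total = h1 + h2
        if total == 0 or row["chromosome"] in ("chrX", "chrY"):
            continue
        if row["haplotype"] == "HOM":
            assert min(h1, h2) / total > 0.35  # balanced
            hom_rates.append(total / row["length"])
        else:
            het_rates.append(total / row["length"])
    assert np.mean(hom_rates) > 1.5 * np.mean(het_rates)


def test_phase_weights_concentrate_on_unmatched_libraries(small_fit, small_bundle):
    """v_phase components for matched-state libraries are near zero."""
    states = small_bundle.truth.state_matrix()
    libs = small_fit.retained_libraries
    checked = 0
    for cid, pm in small_fit.phase_models.items():
        if pm.haploid:
            continue
        members = small_fit.clustering.members(cid)
        chroms = {
            small_bundle.truth.unitigs.set_index("unitig").loc[u, "chromosome"]
            for u in members
        }
        if len(chroms) != 1:
            continue
        chrom = chroms.pop()
        st = states.loc[chrom, libs].to_numpy()
        matched = np.isin(st, ["WW", "CC"])
        w = np.abs(pm.v_phase)
        if matched.any() and (~matched).any():
            assert w[matched].mean() < 0.1 * w[~matched].mean()
            checked += 1
    assert checked > 0
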