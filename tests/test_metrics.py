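"""Contact classification, dRMSD, clustering, and diffusion analysis."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chromolink.metrics import (
    CONTACT_TYPES,
    DiffusionResult,
    NucleosomeFrame,
    classify_contact,
    classify_contacts,
    drmsd,
    interfiber_valence,
    kmeans_structures,
    msd_curve,
    msd_diffusion,
    zigzag_fraction,
)


def _frame(center, normal, fiber=0, index=0):
    n = np.asarray(normal, dtype=float)
    return NucleosomeFrame(np.asarray(center, float), n / np.linalg.norm(n), fiber, index)


def _brute_force_classify(ca, na, cb, nb, cutoff=120.0, angle=45.0):
    """Independent scalar re-implementation of the contact decision tree."""
    d = np.asarray(cb, float) - np.asarray(ca, float)
    r = float(np.linalg.norm(d))
    if r >= cutoff:
        return None
    u = d / r

    def axis_angle(x, y):
        c = abs(float(np.dot(x, y)))
        return np.degrees(np.arccos(min(1.0, c)))

    if axis_angle(na, nb) < angle:
        return "face_face"
    a_aligned = axis_angle(na, u) < angle
    b_aligned = axis_angle(nb, u) < angle
    if a_aligned != b_aligned:
        return "face_side"
    return "side_side"


class TestClassifyContact:
    def test_coaxial_parallel_discs_are_face_face(self):
        rec = classify_contact(_frame([0, 0, 0], [0, 0, 1]), _frame([0, 0, 60], [0, 0, 1], 0, 1))
        assert rec.type == "face_face"
        assert rec.distance == pytest.approx(60.0)

    def test_beyond_cutoff_is_none(self):
        assert classify_contact(_frame([0, 0, 0], [0, 0, 1]), _frame([0, 0, 130], [0, 0, 1])) is None

    def test_one_axis_along_center_vector_is_face_side(self):
        rec = classify_contact(_frame([0, 0, 0], [1, 0, 0]), _frame([90, 0, 0], [0, 0, 1], 0, 1))
        assert rec.type == "face_side"

    def test_edge_on_perpendicular_discs_are_side_side(self):
        rec = classify_contact(_frame([0, 0, 0], [0, 0, 1]), _frame([110, 0, 0], [0, 1, 0], 0, 1))
        assert rec.type == "side_side"

    def test_face_face_takes_precedence_over_geometry(self):
        # the decision tree tests relative axis alignment first: edge-on
        # discs with parallel axes still classify as face_face
        rec = classify_contact(_frame([0, 0, 0], [0, 0, 1]), _frame([110, 0, 0], [0, 0, 1], 0, 1))
        assert rec.type == "face_face"

    def test_antiparallel_normals_count_as_face_face(self):
        # axes are undirected: a flipped normal is the same disc orientation
        rec = classify_contact(_frame([0, 0, 0], [0, 0, 1]), _frame([0, 0, 60], [0, 0, -1], 0, 1))
        assert rec.type == "face_face"

    def test_symmetric_in_arguments(self, rng):
        for _ in range(50):
            a = _frame(rng.normal(size=3) * 40, rng.normal(size=3), 0, 0)
            b = _frame(rng.normal(size=3) * 40 + 30, rng.normal(size=3), 1, 0)
            ra = classify_contact(a, b)
            rb = classify_contact(b, a)
            assert (ra is None) == (rb is None)
            if ra is not None:
                assert ra.type == rb.type

    def test_degenerate_geometry_raises(self):
        with pytest.raises(ValueError):
            classify_contact(_frame([0, 0, 0], [0, 0, 1]), _frame([0, 0, 0], [1, 0, 0]))

    def test_matches_brute_force_oracle_on_random_geometries(self, rng):
        n = 10_000
        ca = rng.normal(size=(n, 3)) * 60
        cb = ca + rng.normal(size=(n, 3)) * 70
        na = Rotation.random(n, rng=rng).apply([0, 0, 1])
        nb = Rotation.random(n, rng=rng).apply([0, 0, 1])
        keep = np.linalg.norm(cb - ca, axis=1) > 1e-6
        codes = classify_contacts(ca[keep], na[keep], cb[keep], nb[keep])
        for k in range(min(n, len(codes))):
            expected = _brute_force_classify(ca[keep][k], na[keep][k], cb[keep][k], nb[keep][k])
            got = None if codes[k] < 0 else CONTACT_TYPES[codes[k]]
            assert got == expected


class _StubFiber:
    """Minimal object exposing nucleosome_frames() for metric tests."""

    def __init__(self, centers, normals):
        self._c = np.asarray(centers, float)
        n = np.asarray(normals, float)
        self._n = n / np.linalg.norm(n, axis=1, keepdims=True)

    def nucleosome_frames(self):
        return self._c, self._n


def _ideal_zigzag(n_nuc=12, stack=30.0, offset=100.0):
    """Two-start fiber: even nucleosomes in one stack, odd in the other."""
    centers = []
    normals = []
    for i in range(n_nuc):
        col = i % 2
        centers.append([col * offset, 0.0, (i // 2) * stack])
        normals.append([0.0, 0.0, 1.0])
    return _StubFiber(centers, normals)


class TestZigzag:
    def test_ideal_two_start_fixture_fraction(self):
        fiber = _ideal_zigzag()
        out = zigzag_fraction([[fiber]])
        # 10 of the 12 second-neighbor pairs are stacked face-to-face
        assert out["face_face"] == pytest.approx(10.0 / 12.0)
        assert out["total"] == pytest.approx(10.0 / 12.0)

    def test_extended_fiber_has_no_zigzag(self):
        centers = [[0.0, 0.0, 200.0 * i] for i in range(12)]
        fiber = _StubFiber(centers, [[0, 0, 1]] * 12)
        assert zigzag_fraction([[fiber]])["total"] == 0.0

    def test_invariant_under_global_rotation(self, rng):
        fiber = _ideal_zigzag()
        rot = Rotation.random(rng=rng)
        rotated = _StubFiber(rot.apply(fiber._c), rot.apply(fiber._n))
        assert zigzag_fraction([[fiber]]) == zigzag_fraction([[rotated]])

    def test_small_fibers_count_zero(self):
        fiber = _StubFiber([[0, 0, 0], [0, 0, 30]], [[0, 0, 1], [0, 0, 1]])
        assert zigzag_fraction([[fiber]])["total"] == 0.0


class TestValence:
    def _system_of(self, fiber_centers):
        """Build a fake multi-fiber System via stub monkeying of contact_records inputs."""
        from chromolink.fiber import System

        positions = []
        quats = []
        bead_class = []
        fiber_id = []
        nuc_id = []
        for f, centers in enumerate(fiber_centers):
            for k, c in enumerate(centers):
                positions.append(c)
                quats.append([1.0, 0.0, 0.0, 0.0])
                bead_class.append(2)
                fiber_id.append(f)
                nuc_id.append(k)
        n = len(positions)
        return System(
            np.asarray(positions, float),
            np.asarray(quats, float),
            bead_class=bead_class,
            rigid_group=list(range(n)),
            bonded_pairs=np.empty((0, 2)),
            fiber_id=fiber_id,
            nucleosome_id=nuc_id,
            topologies=[None] * len(fiber_centers),
        )

    def test_isolated_fibers_have_zero_valence(self):
        system = self._system_of([[[0, 0, 0]], [[1000, 0, 0]]])
        out = interfiber_valence(system)
        assert np.all(out["counts"] == 0)

    def test_chain_fixture_valences(self):
        system = self._system_of([[[0, 0, 0]], [[100, 0, 0]], [[200, 0, 0]]])
        out = interfiber_valence(system)
        assert out["counts"].tolist() == [1.0, 2.0, 1.0]
        assert out["median"] == 1.0

    def test_valence_symmetric(self):
        system = self._system_of([[[0, 0, 0]], [[90, 0, 0]]])
        out = interfiber_valence(system)
        assert out["counts"].tolist() == [1.0, 1.0]


class TestDrmsd:
    def test_identity_is_zero(self, rng):
        x = rng.normal(size=(8, 3)) * 50
        assert drmsd(x, x) == 0.0

    def test_rigid_transform_invariance(self, rng):
        x = rng.normal(size=(10, 3)) * 50
        rot = Rotation.random(rng=rng)
        y = rot.apply(x) + np.array([100.0, -30.0, 7.0])
        assert drmsd(x, y) < 1e-9

    def test_hand_computed_three_nucleosome_case(self):
        # equilateral 10 A triangle vs one side stretched to 13 A:
        # sqrt(2/6 * 9) = sqrt(3) = 1.732
        a = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [5.0, 5.0 * np.sqrt(3), 0.0]])
        d = 13.0
        b = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        # place third point at distances (10, 13) from the first two
        x = (10.0**2 + 10.0**2 - d**2) / (2 * 10.0)
        y = np.sqrt(10.0**2 - x**2)
        b[2] = [x, y, 0.0]
        assert drmsd(a, b) == pytest.approx(np.sqrt(3.0), abs=1e-9)

    def test_symmetry(self, rng):
        x = rng.normal(size=(6, 3)) * 30
        y = rng.normal(size=(6, 3)) * 30
        assert drmsd(x, y) == pytest.approx(drmsd(y, x), rel=1e-12)

    def test_mismatched_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            drmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestKmeans:
    def _families(self, rng, n_each=12, spread=0.5):
        base_a = rng.normal(size=(6, 3)) * 60
        base_b = rng.normal(size=(6, 3)) * 60
        out = []
        for _ in range(n_each):
            out.append(base_a + rng.normal(size=(6, 3)) * spread)
        for _ in range(n_each):
            out.append(base_b + rng.normal(size=(6, 3)) * spread)
        return out

    def test_planted_partition_recovered(self, rng):
        structures = self._families(rng)
        labels, medoids, _ = kmeans_structures(structures, k=2, seed=3)
        first = labels[:12]
        second = labels[12:]
        assert len(set(first)) == 1
        assert len(set(second)) == 1
        assert first[0] != second[0]

    def test_objective_monotone_nonincreasing(self, rng):
        structures = self._families(rng, spread=5.0)
        _, _, history = kmeans_structures(structures, k=3, seed=1)
        assert np.all(np.diff(history) <= 1e-9)

    def test_single_cluster_objective_is_dispersion(self, rng):
        structures = self._families(rng, n_each=4)
        labels, medoids, history = kmeans_structures(structures, k=1, seed=0)
        assert set(labels) == {0}
        from chromolink.metrics import _drmsd_matrix

        D = _drmsd_matrix(structures)
        best = min(float(np.sum(D[i] ** 2)) for i in range(len(structures)))
        assert history[-1] == pytest.approx(best, rel=1e-9)

    def test_deterministic_given_seed(self, rng):
        structures = self._families(rng)
        a = kmeans_structures(structures, k=2, seed=9)
        b = kmeans_structures(structures, k=2, seed=9)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_duplicates_reduce_effective_k_with_warning(self, rng):
        x = rng.normal(size=(5, 3))
        structures = [x.copy() for _ in range(6)]
        with pytest.warns(RuntimeWarning):
            labels, medoids, _ = kmeans_structures(structures, k=3, seed=0)
        assert len(medoids) == 1

    def test_too_few_structures_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_structures([rng.normal(size=(4, 3))], k=2)


class TestAutocorrelation:
    def test_white_noise_has_unit_correlation_time(self, rng):
        from chromolink.metrics import autocorrelation_time

        tau = autocorrelation_time(rng.standard_normal(20_000))
        assert tau == pytest.approx(1.0, abs=0.3)

    def test_ar1_process_matches_closed_form(self, rng):
        from chromolink.metrics import autocorrelation_time

        phi = 0.9  # AR(1): tau = (1 + phi) / (1 - phi) = 19
        x = np.empty(200_000)
        x[0] = 0.0
        noise = rng.standard_normal(len(x))
        for i in range(1, len(x)):
            x[i] = phi * x[i - 1] + noise[i]
        tau = autocorrelation_time(x, max_lag=500)
        assert tau == pytest.approx((1 + phi) / (1 - phi), rel=0.2)

    def test_short_series_rejected(self):
        from chromolink.metrics import autocorrelation_time

        with pytest.raises(ValueError):
            autocorrelation_time([1.0, 2.0])


class TestDiffusion:
    def test_immobile_tracks_give_zero(self):
        traj = np.zeros((200, 2, 3))
        res = msd_diffusion(traj)
        assert res.D == 0.0

    def test_brownian_walk_recovery(self, rng):
        d_true = 0.05  # A^2 per frame
        n = 10_000
        steps = rng.normal(scale=np.sqrt(2 * d_true), size=(n, 8, 3))
        traj = np.cumsum(steps, axis=0)
        # short lags are well self-averaged; long lags are noise-dominated
        res = msd_diffusion(traj, fit_range=(1, 60))
        assert res.D == pytest.approx(d_true, rel=0.05)
        assert res.uncertainty > 0

    def test_fit_range_validation(self, rng):
        traj = np.cumsum(rng.normal(size=(100, 3)), axis=0)
        with pytest.raises(ValueError):
            msd_diffusion(traj, fit_range=(1, 1000))

    def test_msd_curve_linear_for_brownian(self, rng):
        steps = rng.normal(scale=1.0, size=(5000, 8, 3))
        traj = np.cumsum(steps, axis=0)
        lags, msd = msd_curve(traj, max_lag=100)
        slope = np.polyfit(lags, msd, 1)
        # unit-variance steps per axis: 3D MSD grows by 3 per frame = 6 D
        assert slope[0] == pytest.approx(3.0, rel=0.1)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            msd_curve(np.zeros((1, 3)))

    def test_normalization_helper(self):
        a = DiffusionResult(D=2.0, uncertainty=0.0)
        b = DiffusionResult(D=1.0, uncertainty=0.0)
        assert a.normalized(b) == 2.0
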