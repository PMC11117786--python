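import numpy as np
import pytest

from mrifusion.imaging_io import CohortManifest, PatientRecord, VolumeImage
from mrifusion.registration import (RigidTransform, mutual_information, ncc,
                                    register, resample, select_template)
from mrifusion.synthetic_data import PhantomConfig, make_registration_case


class TestNcc:
    def test_self_correlation(self, rng):
        a = rng.normal(size=(10, 10, 10))
        assert ncc(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelation(self, rng):
        a = rng.normal(size=(10, 10, 10))
        assert ncc(a, -a) == pytest.approx(-1.0, abs=1e-12)

    def test_affine_intensity_invariance(self, rng):
        a = rng.normal(size=(10, 10, 10))
        assert ncc(a, 2 * a + 5) == pytest.approx(1.0, abs=1e-10)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(8, 8, 8)), rng.normal(size=(8, 8, 8))
        assert abs(ncc(a, b) - ncc(b, a)) < 1e-9

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            ncc(rng.normal(size=(4, 4, 4)), rng.normal(size=(4, 4, 5)))

    def test_constant_image(self):
        with pytest.raises(ValueError, match="constant"):
            ncc(np.ones((4, 4, 4)), np.zeros((4, 4, 4)) + 2)


class TestMutualInformation:
    def test_independent_noise_near_zero(self, rng):
        a = rng.random(100_000)
        b = rng.random(100_000)
        assert mutual_information(a, b, bins=16) < 0.01

    def test_self_mi_equals_entropy(self, rng):
        a = rng.normal(size=50_000)
        hist, _ = np.histogram(a, bins=32)
        p = hist / hist.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mutual_information(a, a, bins=32) == pytest.approx(entropy,
                                                                  rel=1e-9)

    def test_monotone_remap_equal_count_binning(self, rng):
        a = rng.normal(size=50_000)
        mi_aa = mutual_information(a, a, bins=16, binning="count")
        mi_ab = mutual_information(a, np.exp(a), bins=16, binning="count")
        assert abs(mi_ab - mi_aa) / mi_aa < 0.05

    def test_symmetry(self, rng):
        a, b = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(mutual_information(a, b) - mutual_information(b, a)) < 1e-9

    def test_nonnegative(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=5000), rng.normal(size=5000)
            assert mutual_information(a, b) >= 0

    def test_bad_bins(self, rng):
        with pytest.raises(ValueError):
            mutual_information(rng.normal(size=10), rng.normal(size=10), bins=1)


class TestSelectTemplate:
    def _manifest(self, n, with_t1=None):
        with_t1 = with_t1 if with_t1 is not None else [True] * n
        recs = []
        for i in range(n):
            seqs = {"T2": "x.nii"}
            if with_t1[i]:
                seqs["T1"] = "y.nii"
            recs.append(PatientRecord(f"P{i}", 0, seqs))
        return CohortManifest(recs)

    def test_singleton(self):
        assert select_template(self._manifest(1), 0) == "P0"

    def test_deterministic(self):
        m = self._manifest(10)
        assert select_template(m, 7) == select_template(m, 7)

    def test_only_t1_bearing_selected(self):
        m = self._manifest(4, [False, True, False, False])
        for seed in range(10):
            assert select_template(m, seed) == "P1"

    def test_no_t1_errors(self):
        with pytest.raises(ValueError, match="T1"):
            select_template(self._manifest(3, [False] * 3), 0)

    def test_uniformity_chi2(self):
        from scipy.stats import chisquare
        m = self._manifest(4)
        counts = {f"P{i}": 0 for i in range(4)}
        n = 10_000
        for seed in range(n):
            counts[select_template(m, seed)] += 1
        freqs = np.array(list(counts.values())) / n
        assert np.all(np.abs(freqs - 0.25) <= 0.02)
        assert chisquare(list(counts.values())).pvalue > 0.01


class TestRigidTransform:
    def test_compose_matches_sequential_application(self, rng):
        for _ in range(20):
            a = RigidTransform.from_params(rng.uniform(-5, 5, 3),
                                           rng.uniform(-20, 20, 3),
                                           center=rng.uniform(-10, 10, 3))
            b = RigidTransform.from_params(rng.uniform(-5, 5, 3),
                                           rng.uniform(-20, 20, 3),
                                           center=rng.uniform(-10, 10, 3))
            pts = rng.uniform(-30, 30, (5, 3))
            np.testing.assert_allclose(a.compose(b).apply(pts),
                                       a.apply(b.apply(pts)), atol=1e-9)

    def test_inverse_composes_to_identity(self, rng):
        t = RigidTransform.from_params([1, -2, 3], [10, -5, 20], center=[4, 4, 4])
        pts = rng.uniform(-30, 30, (10, 3))
        np.testing.assert_allclose(t.compose(t.inverse()).apply(pts), pts,
                                   atol=1e-6)

    def test_nonorthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(rotation=np.eye(3) * 2)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]))


class TestResample:
    def test_identity_transform(self, rng):
        v = VolumeImage(rng.normal(size=(12, 12, 12)).astype(np.float32))
        out = resample(v, RigidTransform(), v)
        np.testing.assert_allclose(out.voxels, v.voxels, atol=1e-6)

    def test_integer_shift_equals_array_shift(self, rng):
        v = VolumeImage(rng.normal(size=(16, 16, 16)).astype(np.float32))
        t = RigidTransform(translation=[2.0, 0.0, 0.0])
        out = resample(v, t, v)
        # out(x) = v(x + 2): interior rows shift by two voxels exactly
        np.testing.assert_allclose(out.voxels[:14], v.voxels[2:], atol=1e-5)

    def test_fully_outside_gives_zeros(self, rng):
        v = VolumeImage(rng.normal(size=(8, 8, 8)).astype(np.float32) + 10)
        t = RigidTransform(translation=[100.0, 0.0, 0.0])
        out = resample(v, t, v)
        assert np.all(out.voxels == 0)

    def test_round_trip_interior(self, iso_phantom_config):
        mov, fix, true = make_registration_case(iso_phantom_config,
                                                (3, -2, 4), (5, -3, 2), seed=6)
        fwd = resample(fix, true.inverse(), fix)
        back = resample(fwd, true, fix)
        interior = np.zeros(fix.shape, bool)
        interior[12:-12, 12:-12, 12:-12] = True
        rmse = np.sqrt(np.mean((back.voxels[interior]
                                - fix.voxels[interior]) ** 2))
        assert rmse < 0.02 * np.ptp(fix.voxels)


class TestRegister:
    def test_identity_recovery(self, iso_phantom_config):
        mov, fix, _ = make_registration_case(iso_phantom_config, (0, 0, 0),
                                             (0, 0, 0), seed=11)
        res = register(mov, fix, "NCC")
        c = np.array(fix.shape) / 2.0
        assert np.linalg.norm(res.transform.apply(c) - c) < 0.1
        assert res.transform.rotation_angle_deg() < 0.1

    def test_known_shift_ncc(self, iso_phantom_config):
        mov, fix, true = make_registration_case(iso_phantom_config,
                                                (5, -3, 2), (0, 0, 0), seed=12)
        res = register(mov, fix, "NCC")
        err = res.transform.compose(true.inverse())
        c = np.array(fix.shape) / 2.0
        assert np.all(np.abs(err.apply(c) - c) < 0.5)
        assert res.final_metric >= res.initial_metric

    def test_cross_modal_shift_mi(self, iso_phantom_config):
        mov, fix, true = make_registration_case(iso_phantom_config,
                                                (4, 0, 0), (0, 0, 0),
                                                cross_modal=True, seed=13)
        res = register(mov, fix, "MI")
        err = res.transform.compose(true.inverse())
        c = np.array(fix.shape) / 2.0
        assert np.all(np.abs(err.apply(c) - c) < 0.5)
        assert res.metric_kind == "MI"
        assert res.final_metric >= res.initial_metric

    def test_constant_image_rejected(self):
        v = VolumeImage(np.ones((8, 8, 8), np.float32))
        with pytest.raises(ValueError, match="constant"):
            register(v, v, "NCC")

    def test_bad_metric_kind(self, small_volume):
        with pytest.raises(ValueError, match="metric_kind"):
            register(small_volume, small_volume, "SSD")
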