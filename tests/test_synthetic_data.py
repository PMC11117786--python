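import numpy as np
import pytest
from scipy import stats

from mrifusion.evaluation import ScoredCohort, roc_auc
from mrifusion.registration import mutual_information
from mrifusion.synthetic_data import (PhantomConfig, generate_cohort,
                                      generate_patient, make_registration_case,
                                      _anatomy)

SMALL = dict(volume_shape=(32, 32, 16), spacing=(1.0, 1.0, 2.0),
             lesion_radius_range=(6.0, 9.0), lesion_z_radius_range=(3.0, 5.0))


class TestGeneratePatient:
    def test_same_seed_identical(self):
        cfg = PhantomConfig(**SMALL, seed=1)
        a, ta = generate_patient(1, cfg, np.random.default_rng(9))
        b, tb = generate_patient(1, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a.volume("T1").voxels,
                                      b.volume("T1").voxels)
        np.testing.assert_array_equal(a.volume("T2").voxels,
                                      b.volume("T2").voxels)
        assert ta == tb

    def test_null_effect_classes_indistinguishable(self):
        """With zero effects the class intensity distributions coincide."""
        cfg = PhantomConfig(**SMALL, effect_t1=0.0, effect_t2=0.0,
                            t2_misalignment=(0, 0))
        means0, means1 = [], []
        streams = np.random.SeedSequence(11).spawn(50)
        for i, ss in enumerate(streams):
            rec, _ = generate_patient(i % 2, cfg, np.random.default_rng(ss))
            (means1 if i % 2 else means0).append(
                float(rec.volume("T1").voxels.mean()))
        assert stats.ks_2samp(means0, means1).pvalue > 0.01

    def test_rim_effect_matches_configuration(self):
        """Mean class-1 vs class-0 rim difference reproduces effect_t1."""
        effect, sigma = 4.0, 10.0
        cfg = PhantomConfig(**SMALL, effect_t1=effect, effect_t2=0.0,
                            noise_sigma=sigma, t2_misalignment=(0, 0))
        diffs = []
        streams = np.random.SeedSequence(13).spawn(100)
        for i, ss in enumerate(streams):
            rec, _ = generate_patient(i % 2, cfg, np.random.default_rng(ss))
            # identical stream prefix reproduces the anatomy and rim mask
            _, base, _, rim, _, _ = _anatomy(cfg, np.random.default_rng(ss))
            t1 = rec.volume("T1").voxels
            diffs.append((i % 2, float((t1 - base)[rim].mean())))
        d1 = np.mean([d for c, d in diffs if c == 1])
        d0 = np.mean([d for c, d in diffs if c == 0])
        assert abs((d1 - d0) - effect * sigma) < 0.1 * effect * sigma

    def test_lesion_volume_matches_analytic_ellipsoid(self):
        cfg = PhantomConfig(seed=3)
        for i in range(5):
            rec, truth = generate_patient(0, cfg, np.random.default_rng(20 + i))
            rx, ry, rz = truth["radii"]
            analytic = 4.0 / 3.0 * np.pi * rx * ry * rz
            assert abs(truth["lesion_voxels"] - analytic) / analytic < 0.05

    def test_bad_label(self):
        with pytest.raises(ValueError):
            generate_patient(2, PhantomConfig(), np.random.default_rng(0))

    def test_oversized_lesion_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            PhantomConfig(volume_shape=(16, 16, 8),
                          lesion_radius_range=(8.0, 14.0))


class TestGenerateCohort:
    def test_reference_class_balance(self):
        cfg = PhantomConfig(**SMALL, seed=2)
        manifest, _ = generate_cohort(20, 212 / 311, cfg)
        assert manifest.class_counts == {1: 14, 0: 6}

    def test_even_split(self):
        cfg = PhantomConfig(**SMALL, seed=2)
        manifest, _ = generate_cohort(10, 0.5, cfg)
        assert manifest.class_counts == {1: 5, 0: 5}

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_cohort(4, 0.95, PhantomConfig(**SMALL))

    def test_regeneration_byte_identical(self, tmp_path):
        cfg = PhantomConfig(**SMALL, seed=8)
        generate_cohort(4, 0.5, cfg, out_dir=tmp_path / "a")
        generate_cohort(4, 0.5, cfg, out_dir=tmp_path / "b")
        for name in ("manifest.csv", "ground_truth.json"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_written_cohort_loadable(self, tmp_path):
        from mrifusion.imaging_io import load_manifest
        cfg = PhantomConfig(**SMALL, seed=8)
        generate_cohort(4, 0.5, cfg, out_dir=tmp_path)
        m = load_manifest(tmp_path / "manifest.csv")
        assert len(m) == 4
        assert m.records[0].volume("T1").shape == SMALL["volume_shape"]

    def test_complementarity_of_modalities(self):
        """Zero T1 effect: T1 carries no class signal, T2 does.

        Uses a simple lesion-contrast readout per modality rather than a
        trained model, so the property is attributable to the generator.
        """
        cfg = PhantomConfig(**SMALL, effect_t1=0.0, effect_t2=3.0,
                            t2_misalignment=(0, 0), seed=21)
        manifest, truths = generate_cohort(60, 0.5, cfg)
        feats = {"T1": [], "T2": []}
        labels = []
        for rec in manifest.records:
            t = truths[rec.patient_id]
            c = np.array(t["center"])
            for seq in ("T1", "T2"):
                v = rec.volume(seq).voxels
                cx, cy, cz = np.round(c).astype(int)
                lesion_mean = v[cx - 2:cx + 3, cy - 2:cy + 3, cz - 1:cz + 2].mean()
                feats[seq].append(lesion_mean - np.median(v))
            labels.append(rec.label)
        auc_t1 = roc_auc(ScoredCohort(_rank01(feats["T1"]), labels, "T1"))
        auc_t2 = roc_auc(ScoredCohort(_rank01(feats["T2"]), labels, "T2"))
        assert abs(auc_t1 - 0.5) < 0.2      # no class signal in T1
        assert auc_t2 > 0.8                  # strong class signal in T2


def _rank01(x):
    x = np.asarray(x, dtype=float)
    order = x.argsort().argsort()
    return order / (len(x) - 1)


class TestRegistrationCase:
    def test_zero_transform_identity(self, iso_phantom_config):
        mov, fix, true = make_registration_case(iso_phantom_config,
                                                (0, 0, 0), (0, 0, 0), seed=1)
        np.testing.assert_allclose(mov.voxels, fix.voxels, atol=1e-4)
        assert true.rotation_angle_deg() < 1e-9

    def test_cross_modal_dependence(self, iso_phantom_config):
        mov, fix, _ = make_registration_case(iso_phantom_config, (0, 0, 0),
                                             (0, 0, 0), cross_modal=True,
                                             seed=2)
        rng = np.random.default_rng(0)
        shuffled = fix.voxels.ravel().copy()
        rng.shuffle(shuffled)
        mi_true = mutual_information(mov.voxels, fix.voxels)
        mi_null = mutual_information(mov.voxels, shuffled.reshape(fix.shape))
        assert mi_true > mi_null

    def test_out_of_field_shift_rejected(self, iso_phantom_config):
        with pytest.raises(ValueError, match="outside"):
            make_registration_case(iso_phantom_config, (100, 0, 0), (0, 0, 0))
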