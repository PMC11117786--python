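import numpy as np
import pytest

from mrifusion.imaging_io import CohortManifest, PatientRecord, VolumeImage
from mrifusion.synthetic_data import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_volume(rng):
    return VolumeImage(rng.normal(50, 10, (8, 8, 8)).astype(np.float32),
                       spacing=(1.0, 1.0, 3.0))


@pytest.fixture
def iso_phantom_config():
    """Isotropic 64-cube phantom used by registration tests."""
    return PhantomConfig(volume_shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def labelled_manifest():
    """A 12-patient manifest with dummy paths (no volumes on disk)."""
    records = [PatientRecord(patient_id=f"P{i:02d}", label=int(i < 8),
                             sequences={"T1": f"p{i}_t1.nii", "T2": f"p{i}_t2.nii"})
               for i in range(12)]
    return CohortManifest(records)


def make_labelled_manifest(n: int, n_pos: int) -> CohortManifest:
    records = [PatientRecord(patient_id=f"P{i:03d}", label=int(i < n_pos),
                             sequences={"T1": f"p{i}_t1.nii"})
               for i in range(n)]
    return CohortManifest(records)
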