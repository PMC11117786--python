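"""NIfTI volume I/O, cohort manifests, and 2D slice selection.

Volumes are held as float32 voxel grids with physical metadata
(spacing, origin, direction cosines).  Cohorts are described by a CSV
manifest with one row per patient: ``patient_id, label, t1_path,
t2_path``; an empty path marks a missing sequence, which is retained so
that single-branch prediction still works for that patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["VolumeImage", "PatientRecord", "CohortManifest", "read_volume",
           "write_volume", "load_manifest", "save_manifest", "slice_select",
           "SEQUENCE_NAMES"]

SEQUENCE_NAMES = ("T1", "T2")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """A 3D intensity grid with physical-space metadata.

    Voxel indices are 0-based; world coordinates follow the NIfTI
    affine ``direction @ diag(spacing)`` with translation ``origin``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.voxels.ndim} dimensions")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def allclose(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxels, other.voxels, atol=atol)
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol)
                and np.allclose(self.direction, other.direction, atol=atol))


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1/2 file into a :class:`VolumeImage`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) != 3:
        raise ValueError(f"expected a 3D volume, got {len(shape)}D image "
                         f"of shape {shape} in {path}")
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains non-finite voxels")
    affine = img.affine
    m = affine[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise ValueError(f"volume {path} has degenerate spacing {spacing}")
    direction = m / spacing[None, :]
    return VolumeImage(voxels=data, spacing=tuple(spacing),
                       origin=tuple(affine[:3, 3]), direction=direction)


def write_volume(volume: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI; validation precedes any file output."""
    if not isinstance(volume, VolumeImage):
        volume = VolumeImage(volume)
    if not np.all(np.isfinite(volume.voxels)):
        raise ValueError("volume contains non-finite intensities")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), volume.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# cohort manifests
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """Labelled per-patient map of sequence name to volume or file path."""

    patient_id: str
    label: int | None
    sequences: dict[str, VolumeImage | str | Path]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError(f"patient {self.patient_id} has no sequences")
        unknown = set(self.sequences) - set(SEQUENCE_NAMES)
        if unknown:
            raise ValueError(f"patient {self.patient_id}: unknown sequence "
                             f"names {sorted(unknown)}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"patient {self.patient_id}: label must be 0/1/absent, "
                             f"got {self.label!r}")

    def has(self, name: str) -> bool:
        return name in self.sequences

    def volume(self, name: str) -> VolumeImage:
        """The named sequence, loading from disk on first access."""
        v = self.sequences[name]
        if not isinstance(v, VolumeImage):
            v = read_volume(v)
            self.sequences[name] = v
        return v


@dataclass
class CohortManifest:
    records: list[PatientRecord]

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate patient_id(s) in manifest: {dupes}")

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.records:
            if r.label is not None:
                counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, ids: list[str]) -> "CohortManifest":
        by_id = {r.patient_id: r for r in self.records}
        return CohortManifest([by_id[i] for i in ids])


def load_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest (CSV or TSV with a header row).

    Required columns: patient_id, label, t1_path, t2_path.  Empty paths
    mark missing sequences; relative paths are resolved against the
    manifest's directory.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    required = {"patient_id", "label", "t1_path", "t2_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        label = row["label"]
        if pd.isna(label) or label == "":
            label = None
        else:
            label = float(label)
            if label not in (0.0, 1.0):
                raise ValueError(f"patient {row['patient_id']}: label must be "
                                 f"0, 1, or empty, got {row['label']!r}")
            label = int(label)
        sequences: dict[str, VolumeImage | str | Path] = {}
        for name, col in (("T1", "t1_path"), ("T2", "t2_path")):
            p = row[col]
            if pd.isna(p) or str(p).strip() == "":
                continue
            p = Path(str(p))
            if not p.is_absolute():
                p = path.parent / p
            sequences[name] = p
        if not sequences:
            raise ValueError(f"patient {row['patient_id']}: both sequence "
                             f"paths are empty")
        records.append(PatientRecord(patient_id=str(row["patient_id"]),
                                     label=label, sequences=sequences))
    return CohortManifest(records)


def save_manifest(manifest: CohortManifest, path: str | Path,
                  paths_by_id: dict[str, dict[str, str]] | None = None) -> None:
    """Write a manifest CSV; volume paths taken from records or `paths_by_id`."""
    path = Path(path)
    rows = []
    for r in manifest.records:
        entry = {"patient_id": r.patient_id,
                 "label": "" if r.label is None else r.label}
        for name, col in (("T1", "t1_path"), ("T2", "t2_path")):
            if paths_by_id is not None:
                entry[col] = paths_by_id.get(r.patient_id, {}).get(name, "")
            else:
                v = r.sequences.get(name)
                entry[col] = str(v) if isinstance(v, (str, Path)) else ""
        rows.append(entry)
    pd.DataFrame(rows, columns=["patient_id", "label", "t1_path", "t2_path"]
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# slice selection
# ---------------------------------------------------------------------------

def slice_select(volume: VolumeImage, policy: str = "central", k: int = 3
                 ) -> tuple[list[np.ndarray], list[int]]:
    """Select axial 2D slices (third array axis) from a volume.

    ``central`` returns the middle slice (lower median for even counts);
    ``top_k_mean`` returns the k slices with the highest intensity
    variance, in ascending index order.  Returns (images, indices).
    """
    vox = volume.voxels
    n = vox.shape[2]
    if n < 1:
        raise ValueError("volume has no axial slices")
    if policy == "central":
        idx = [(n - 1) // 2]
    elif policy == "top_k_mean":
        variances = vox.reshape(-1, n).var(axis=0)
        k = min(k, n)
        idx = sorted(np.argsort(variances)[::-1][:k].tolist())
    else:
        raise ValueError(f"unknown slice policy {policy!r}")
    return [np.ascontiguousarray(vox[:, :, i]) for i in idx], [int(i) for i in idx]
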