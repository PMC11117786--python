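"""Phantom mpMRI cohorts with class signal split across two sequences.

Each phantom patient shares one anatomy — a smooth background gradient,
a few random soft-tissue blobs, and an ellipsoidal lesion — rendered
into two volumes with different contrast.  The class label modulates
the lesion's *rim* intensity in the T1-like volume and the lesion's
*core* intensity in the T2-like volume (after a fixed monotone
intensity remap), so each modality carries only its own share of the
class signal and fusion is required to see both.  The T2 volume can be
rigidly misaligned by a recorded random transform, and both volumes
receive additive Gaussian noise.  Effect sizes are expressed in units
of the noise standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .imaging_io import (CohortManifest, PatientRecord, VolumeImage,
                         save_manifest, write_volume)
from .registration import RigidTransform

__all__ = ["PhantomConfig", "generate_patient", "generate_cohort",
           "make_registration_case", "default_remap"]


def default_remap(v: np.ndarray) -> np.ndarray:
    """Fixed monotone nonlinear map giving the T2-like contrast."""
    return 30.0 * np.exp(np.asarray(v, dtype=np.float64) / 80.0)


@dataclass
class PhantomConfig:
    volume_shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    lesion_radius_range: tuple[float, float] = (8.0, 14.0)   # in-plane, voxels
    lesion_z_radius_range: tuple[float, float] = (4.0, 7.0)  # axial, voxels
    rim_fraction: float = 0.7        # core is r < rim_fraction of the radius
    effect_t1: float = 3.0           # rim offset between classes, noise-sigma units
    effect_t2: float = 3.0           # core offset between classes, noise-sigma units
    noise_sigma: float = 10.0        # intensity units
    t2_misalignment: tuple[float, float] = (3.0, 3.0)  # max |shift| vox, |angle| deg
    n_blobs: int = 3                 # random soft-tissue blobs
    blob_sigma_range: tuple[float, float] = (4.0, 10.0)   # voxels
    blob_amp: float = 20.0           # intensity units
    background_range: tuple[float, float] = (40.0, 80.0)
    lesion_core: float = 60.0        # core contrast over background
    lesion_rim: float = 30.0         # rim contrast over background
    seed: int = 0

    def __post_init__(self):
        if self.effect_t1 < 0 or self.effect_t2 < 0:
            raise ValueError("effect sizes must be non-negative")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume shape must be positive")
        nx, ny, nz = self.volume_shape
        if (2 * self.lesion_radius_range[1] >= min(nx, ny)
                or 2 * self.lesion_z_radius_range[1] >= nz):
            raise ValueError("largest lesion does not fit in the volume")


def _sample_params(config: PhantomConfig, rng: np.random.Generator) -> dict:
    """Draw the random anatomy parameters for one patient."""
    nx, ny, nz = config.volume_shape
    blobs = []
    for _ in range(config.n_blobs):
        blobs.append({"center": rng.uniform([0, 0, 0], [nx, ny, nz]),
                      "sigma": rng.uniform(*config.blob_sigma_range, size=3),
                      "amp": rng.uniform(-config.blob_amp, config.blob_amp)})
    rx = rng.uniform(*config.lesion_radius_range)
    ry = rng.uniform(*config.lesion_radius_range)
    rz = rng.uniform(*config.lesion_z_radius_range)
    margin = 2.0
    center = rng.uniform([rx + margin, ry + margin, rz + margin],
                         [nx - rx - margin, ny - ry - margin, nz - rz - margin])
    return {"blobs": blobs, "lesion_center": center, "lesion_radii": (rx, ry, rz)}


def _render(params: dict, config: PhantomConfig, x, y, z):
    """Evaluate the analytic anatomy at (possibly transformed) voxel coords.

    Because the phantom is a closed-form field, a rigidly displaced
    copy can be rendered exactly at transformed coordinates — no
    interpolation and no out-of-field fill.  Returns (base, core, rim).
    """
    nx, ny, nz = config.volume_shape
    lo, hi = config.background_range
    base = lo + (hi - lo) * (x + y) / max(1, (nx + ny - 2))
    for b in params["blobs"]:
        c, sig = b["center"], b["sigma"]
        base = base + b["amp"] * np.exp(-(((x - c[0]) / sig[0]) ** 2
                                          + ((y - c[1]) / sig[1]) ** 2
                                          + ((z - c[2]) / sig[2]) ** 2) / 2.0)
    cx, cy, cz = params["lesion_center"]
    rx, ry, rz = params["lesion_radii"]
    r = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
                + ((z - cz) / rz) ** 2)
    core = r < config.rim_fraction
    rim = (r < 1.0) & ~core
    base = base + config.lesion_core * core + config.lesion_rim * rim
    return base, core, rim


def _grid(config: PhantomConfig, transform: RigidTransform | None = None):
    """Voxel-coordinate grid, optionally pushed through a rigid transform."""
    nx, ny, nz = config.volume_shape
    x, y, z = np.meshgrid(np.arange(nx, dtype=float),
                          np.arange(ny, dtype=float),
                          np.arange(nz, dtype=float), indexing="ij")
    if transform is not None:
        spacing = np.asarray(config.spacing)
        pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1) * spacing
        pts = transform.apply(pts) / spacing
        x = pts[:, 0].reshape(x.shape)
        y = pts[:, 1].reshape(y.shape)
        z = pts[:, 2].reshape(z.shape)
    return x, y, z


def _anatomy(config: PhantomConfig, rng: np.random.Generator):
    """Shared anatomy and lesion masks for one patient."""
    params = _sample_params(config, rng)
    x, y, z = _grid(config)
    base, core, rim = _render(params, config, x, y, z)
    lesion = core | rim
    truth = {"center": params["lesion_center"].tolist(),
             "radii": list(params["lesion_radii"])}
    return params, base, core, rim, lesion, truth


def generate_patient(class_label: int, config: PhantomConfig,
                     rng: np.random.Generator
                     ) -> tuple[PatientRecord, dict]:
    """One phantom patient: paired T1/T2 volumes plus a ground-truth sidecar.

    Class 1 raises the T1 rim by ``effect_t1 * noise_sigma`` and the T2
    core by ``effect_t2 * noise_sigma``; class 0 leaves both at the
    anatomy's baseline.  The T2 volume is perturbed by a recorded
    random rigid transform bounded by ``t2_misalignment``.
    """
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    params, base, core, rim, lesion, truth = _anatomy(config, rng)
    sigma = config.noise_sigma
    spacing = config.spacing
    t1 = base + (config.effect_t1 * sigma * rim if class_label == 1 else 0.0)
    max_shift, max_angle = config.t2_misalignment
    shift_vox = rng.uniform(-max_shift, max_shift, size=3)
    angles = rng.uniform(-max_angle, max_angle, size=3)
    shift_mm = shift_vox * np.asarray(spacing)
    center_mm = (np.asarray(config.volume_shape) - 1) / 2.0 * np.asarray(spacing)
    t2_transform = RigidTransform.from_params(shift_mm, angles, center=center_mm)
    if max_shift > 0 or max_angle > 0:
        # render the displaced anatomy exactly at transformed coordinates
        base2, core2, _ = _render(params, config, *_grid(config, t2_transform))
    else:
        base2, core2 = base, core
    t2 = default_remap(base2) + (config.effect_t2 * sigma * core2
                                 if class_label == 1 else 0.0)
    t1_noisy = t1 + rng.normal(0.0, sigma, t1.shape)
    t2_noisy = t2 + rng.normal(0.0, sigma, t2.shape)
    record = PatientRecord(
        patient_id="", label=class_label,
        sequences={"T1": VolumeImage(t1_noisy.astype(np.float32), spacing=spacing),
                   "T2": VolumeImage(t2_noisy.astype(np.float32), spacing=spacing)})
    truth.update({
        "label": class_label,
        "lesion_voxels": int(lesion.sum()),
        "t2_shift_vox": shift_vox.tolist(),
        "t2_angles_deg": angles.tolist(),
    })
    return record, truth


def generate_cohort(n: int, class1_fraction: float, config: PhantomConfig,
                    out_dir: str | Path | None = None
                    ) -> tuple[CohortManifest, dict]:
    """A phantom cohort of `n` patients with the given class-1 fraction.

    Returns the manifest (volumes in memory) and a ground-truth sidecar.
    When `out_dir` is given, NIfTI files, a manifest CSV, and the
    sidecar JSON are also written there.  Fully deterministic per
    ``config.seed``.
    """
    if n < 2:
        raise ValueError("cohort needs at least two patients")
    if not 0.0 < class1_fraction < 1.0:
        raise ValueError("class1_fraction must be in (0, 1)")
    n1 = round(n * class1_fraction)
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError(f"cohort of {n} at fraction {class1_fraction} leaves "
                         f"a class empty")
    labels = [1] * n1 + [0] * n0
    streams = np.random.SeedSequence(config.seed).spawn(n)
    records, truths = [], {}
    for i, (label, ss) in enumerate(zip(labels, streams)):
        rec, truth = generate_patient(label, config, np.random.default_rng(ss))
        rec.patient_id = f"P{i:04d}"
        records.append(rec)
        truths[rec.patient_id] = truth
    manifest = CohortManifest(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths_by_id: dict[str, dict[str, str]] = {}
        for rec in records:
            paths_by_id[rec.patient_id] = {}
            for seq in ("T1", "T2"):
                fname = f"{rec.patient_id}_{seq.lower()}.nii"
                write_volume(rec.sequences[seq], out_dir / fname)
                paths_by_id[rec.patient_id][seq] = fname
        save_manifest(manifest, out_dir / "manifest.csv", paths_by_id=paths_by_id)
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(truths, fh, indent=1, sort_keys=True)
    return manifest, truths


def make_registration_case(config: PhantomConfig, shift_vox, angles_deg,
                           cross_modal: bool = False, seed: int = 0,
                           rich_texture: bool = True
                           ) -> tuple[VolumeImage, VolumeImage, RigidTransform]:
    """A (moving, fixed, true transform) triple for registration tests.

    The fixed image is a clean phantom; the moving image is the same
    anatomy (intensity-remapped for cross-modal cases) displaced by the
    requested rigid perturbation.  ``resample(moving, true, fixed)``
    realigns the moving image with the fixed one.

    With ``rich_texture`` (default) the anatomy gets more and sharper
    blobs than a classification phantom: a smooth ramp plus a
    near-ellipsoidal lesion is almost rotation-symmetric about some
    axes, which would make rigid recovery ill-posed rather than testing
    the optimizer.
    """
    if rich_texture:
        config = replace(config, n_blobs=8, blob_sigma_range=(3.0, 8.0),
                         blob_amp=25.0)
    rng = np.random.default_rng(seed)
    params, base, _, _, _, _ = _anatomy(config, rng)
    spacing = np.asarray(config.spacing)
    shift_mm = np.asarray(shift_vox, float) * spacing
    extent = np.asarray(config.volume_shape) * spacing
    if np.any(np.abs(shift_mm) > extent / 2):
        raise ValueError("shift would push the lesion outside the volume")
    fixed = VolumeImage(base.astype(np.float32), spacing=tuple(spacing))
    center_mm = (np.asarray(config.volume_shape) - 1) / 2.0 * spacing
    g = RigidTransform.from_params(shift_mm, angles_deg, center=center_mm)
    mov_base, _, _ = _render(params, config, *_grid(config, g))
    if cross_modal:
        mov_base = default_remap(mov_base)
    moving = VolumeImage(mov_base.astype(np.float32), spacing=tuple(spacing))
    return moving, fixed, g.inverse()
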