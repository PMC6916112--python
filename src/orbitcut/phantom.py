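"""Synthetic orbital CT phantom with known ground truth.

Emulates the physical validation phantom of orbital-volumetry studies: a
skull-like bone shell enclosing an orbital cavity with an anterior opening,
a centered hydroxyapatite (HA) sphere prosthesis, four tapered muscle
strips diverging from the orbital apex (total volume calibrated to a
requested figure, 3.8 cm^3 by default), and a fat fill grown outward from
the apex so that a series of phantoms with increasing fat volumes has
strictly nested fat masks. The remaining space is air.

HU values are textbook CT tissue means plus i.i.d. Gaussian noise; the
ground-truth label map carries the noiseless assignment. Muscle and fat
voxel counts are calibrated by rank-selecting voxels of a continuous
priority field, so ground-truth volumes match the request to within one
voxel volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_io import CTVolume, LabelMap, DEFAULT_LABEL_NAMES, write_dicom_series, write_nifti
from .quantify import compute_volumes

__all__ = ["PhantomSpec", "generate_phantom", "generate_phantom_series",
           "write_phantom_dataset", "DEFAULT_FAT_SERIES"]

#: six-phantom fat series with 0.1 cm^3 ground-truth increments, ending at
#: the 2.5 cm^3 endpoint of the studied range
DEFAULT_FAT_SERIES = [2.0, 2.1, 2.2, 2.3, 2.4, 2.5]

DEFAULT_HU_MEANS = {
    "air": -1000.0,
    "fat": -100.0,
    "muscle": 55.0,
    "bone": 1000.0,
    "prosthesis": 700.0,
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic orbit phantom.

    The default grid (64 x 128 x 128 voxels at 1.0 x 0.5 x 0.5 mm) is close
    to a unilateral orbital ROI while keeping desk-scale runtimes; tissue HU
    means are textbook values and fully configurable.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 0.5, 0.5)
    muscle_total_cm3: float = 3.8
    fat_cm3: float = 2.5
    hu_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    noise_sigma: float = 15.0
    rng_seed: int = 0
    # geometry knobs (mm); the exact strip/sphere shapes are free parameters
    cavity_semiaxes: tuple[float, float, float] = (24.0, 22.0, 22.0)
    shell_thickness: float = 3.0
    sphere_radius: float = 6.0

    def __post_init__(self) -> None:
        if self.muscle_total_cm3 < 0 or self.fat_cm3 < 0:
            raise ValueError("tissue volumes must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        missing = set(DEFAULT_HU_MEANS) - set(self.hu_means)
        if missing:
            raise ValueError(f"hu_means missing tissues: {sorted(missing)}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _geometry(spec: PhantomSpec) -> dict:
    """Rasterise the fixed phantom geometry (everything except the fat fill)."""
    ns, nr, nc = spec.shape
    dz, dx, dy = spec.spacing
    z = (np.arange(ns) + 0.5) * dz
    x = (np.arange(nr) + 0.5) * dx
    y = (np.arange(nc) + 0.5) * dy
    Z, X, Y = np.meshgrid(z, x, y, indexing="ij")

    cz, cx, cy = ns * dz / 2.0, nr * dx / 2.0, nc * dy / 2.0
    az, ax, ay = spec.cavity_semiaxes
    t = spec.shell_thickness

    def inside(sa_z, sa_x, sa_y):
        return ((Z - cz) / sa_z) ** 2 + ((X - cx) / sa_x) ** 2 + ((Y - cy) / sa_y) ** 2 <= 1.0

    cavity = inside(az, ax, ay)
    outer = inside(az + t, ax + t, ay + t)
    # anterior opening: no bone cap beyond 70% of the axis toward high z
    shell = outer & ~cavity & (Z <= cz + 0.7 * az)

    sphere = (Z - cz) ** 2 + (X - cx) ** 2 + (Y - cy) ** 2 <= spec.sphere_radius ** 2
    sphere &= cavity

    # four muscle strips diverging from the apex (low z) toward the opening
    apex_z = cz - az
    z0, z1 = apex_z + 2.0, cz + 0.6 * az
    span = z1 - z0
    frac = np.clip((Z - z0) / span, 0.0, 1.0)
    offset = 5.0 + 0.45 * az * frac          # strip axis distance from center
    taper = 3.2 - 1.0 * frac                 # strip radius shrinks anteriorly
    in_band = (Z >= z0) & (Z <= z1)
    priority = np.full(spec.shape, np.inf)
    for ux, uy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        axis_x = cx + ux * offset
        axis_y = cy + uy * offset
        r = np.sqrt((X - axis_x) ** 2 + (Y - axis_y) ** 2)
        priority = np.minimum(priority, r / taper)
    candidates = cavity & ~sphere & in_band

    vox_cm3 = spec.voxel_volume_mm3 / 1000.0
    n_muscle = int(round(spec.muscle_total_cm3 / vox_cm3))
    cand_idx = np.flatnonzero(candidates.ravel())
    if n_muscle > cand_idx.size:
        raise ValueError(f"requested muscle volume {spec.muscle_total_cm3} cm^3 "
                         f"({n_muscle} voxels) exceeds strip capacity "
                         f"({cand_idx.size} voxels, {cand_idx.size * vox_cm3:.3f} cm^3)")
    order = np.lexsort((cand_idx, priority.ravel()[cand_idx]))
    muscle_flat = cand_idx[order[:n_muscle]]
    muscle = np.zeros(spec.shape, dtype=bool)
    muscle.ravel()[muscle_flat] = True

    # fat growth order: distance from the apex, ties broken by flat index
    fat_space = cavity & ~sphere & ~muscle
    dist_apex = (Z - apex_z) ** 2 + (X - cx) ** 2 + (Y - cy) ** 2
    fat_idx = np.flatnonzero(fat_space.ravel())
    fat_order = fat_idx[np.lexsort((fat_idx, dist_apex.ravel()[fat_idx]))]

    return {"shell": shell, "sphere": sphere, "muscle": muscle, "fat_order": fat_order}


def _assemble(spec: PhantomSpec, geo: dict, fat_cm3: float,
              rng: np.random.Generator) -> tuple[CTVolume, LabelMap]:
    vox_cm3 = spec.voxel_volume_mm3 / 1000.0
    n_fat = int(round(fat_cm3 / vox_cm3))
    fat_order = geo["fat_order"]
    if n_fat > fat_order.size:
        raise ValueError(f"requested fat volume {fat_cm3} cm^3 ({n_fat} voxels) exceeds "
                         f"cavity capacity ({fat_order.size} voxels, "
                         f"{fat_order.size * vox_cm3:.3f} cm^3)")
    fat = np.zeros(spec.shape, dtype=bool)
    fat.ravel()[fat_order[:n_fat]] = True

    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[geo["muscle"]] = 1
    labels[fat] = 2
    labels[geo["shell"]] = 3
    labels[geo["sphere"]] = 3

    hu = np.full(spec.shape, spec.hu_means["air"], dtype=np.float64)
    hu[geo["muscle"]] = spec.hu_means["muscle"]
    hu[fat] = spec.hu_means["fat"]
    hu[geo["shell"]] = spec.hu_means["bone"]
    hu[geo["sphere"]] = spec.hu_means["prosthesis"]
    if spec.noise_sigma > 0:
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    vol = CTVolume(data=hu, spacing=spec.spacing)
    truth = LabelMap(labels=labels, label_names=dict(DEFAULT_LABEL_NAMES))
    return vol, truth


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LabelMap]:
    """Generate one phantom volume and its ground-truth label map.

    Deterministic given the spec (including ``rng_seed``). Ground-truth
    muscle and fat volumes match the request to within one voxel volume.
    """
    geo = _geometry(spec)
    rng = np.random.default_rng(spec.rng_seed)
    return _assemble(spec, geo, spec.fat_cm3, rng)


def generate_phantom_series(spec: PhantomSpec,
                            fat_volumes: list[float] | None = None
                            ) -> list[tuple[CTVolume, LabelMap]]:
    """Generate a series of phantoms with fixed geometry and growing fat.

    The fat region grows in a deterministic apex-outward order, so every
    truth fat mask is a superset of the previous one; successive ground
    truth fat volumes reproduce the requested increments within one voxel
    volume. Noise is drawn independently per phantom, seeded from
    ``spec.rng_seed`` and the phantom index.
    """
    fat_volumes = DEFAULT_FAT_SERIES if fat_volumes is None else list(fat_volumes)
    if not fat_volumes:
        raise ValueError("fat volume series must be non-empty")
    if any(b < a for a, b in zip(fat_volumes, fat_volumes[1:])):
        raise ValueError(f"fat volumes must be non-decreasing, got {fat_volumes}")
    geo = _geometry(spec)
    out = []
    for i, fv in enumerate(fat_volumes):
        rng = np.random.default_rng([spec.rng_seed, i])
        out.append(_assemble(spec, geo, fv, rng))
    return out


def write_phantom_dataset(directory: str | Path,
                          series: list[tuple[CTVolume, LabelMap]],
                          format: str = "nifti",
                          spec: PhantomSpec | None = None) -> dict:
    """Write phantom volumes, truth label maps and a manifest to disk.

    CT volumes go out as NIfTI or as a minimal single-frame DICOM series;
    truth label maps always as NIfTI. The manifest echoes the spec and the
    ground-truth per-tissue volumes of every phantom (computed with
    :func:`orbitcut.quantify.compute_volumes`, so manifest and reloaded
    truth always agree).
    """
    if not series:
        raise ValueError("phantom series is empty")
    if format not in ("nifti", "dicom"):
        raise ValueError(f"unknown format {format!r}; use 'nifti' or 'dicom'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"format": format, "phantoms": []}
    if spec is not None:
        manifest["spec"] = {
            "shape": list(spec.shape), "spacing": list(spec.spacing),
            "muscle_total_cm3": spec.muscle_total_cm3, "fat_cm3": spec.fat_cm3,
            "hu_means": spec.hu_means, "noise_sigma": spec.noise_sigma,
            "rng_seed": spec.rng_seed,
        }
    for i, (vol, truth) in enumerate(series):
        stem = f"phantom_{i:02d}"
        if format == "nifti":
            ct_path = directory / f"{stem}_ct.nii.gz"
            write_nifti(vol, ct_path)
        else:
            ct_path = directory / f"{stem}_ct"
            write_dicom_series(vol, ct_path)
        truth_path = directory / f"{stem}_truth.nii.gz"
        write_nifti(truth, truth_path, spacing=vol.spacing, origin=vol.origin)
        report = compute_volumes(truth, vol.spacing)
        manifest["phantoms"].append({
            "ct": ct_path.name, "truth": truth_path.name,
            "truth_volumes_cm3": {truth.label_names[l]: round(v, 6)
                                  for l, v in sorted(report.volumes_cm3.items())},
        })
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
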