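"""Per-tissue volumetry and 3-D surface reconstruction.

Volumes are pure voxel counts times the voxel volume, reported in cm^3 to
4 decimal places; partial-volume effects are deliberately ignored. Surfaces
are marching-cubes isosurfaces of the binary tissue mask at level 0.5, with
vertex coordinates in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .volume_io import CTVolume, LabelMap

__all__ = ["VolumeReport", "compute_volumes", "volume_series_deltas", "extract_surface",
           "save_mesh"]

MUSCLE_LABEL = 1
FAT_LABEL = 2


@dataclass
class VolumeReport:
    """Per-tissue voxel counts and volumes for one segmentation."""

    voxel_counts: dict[int, int]
    volumes_cm3: dict[int, float]
    spacing: tuple[float, float, float]
    label_names: dict[int, str] = field(default_factory=dict)

    @property
    def MV(self) -> float:
        """Extraocular muscle volume (cm^3)."""
        return self.volumes_cm3.get(MUSCLE_LABEL, 0.0)

    @property
    def FV(self) -> float:
        """Intraorbital fat volume (cm^3)."""
        return self.volumes_cm3.get(FAT_LABEL, 0.0)

    @property
    def total_voxels(self) -> int:
        return sum(self.voxel_counts.values())

    def to_json(self, path: str | Path) -> None:
        obj = {
            "spacing_mm": list(self.spacing),
            "tissues": {
                self.label_names.get(lab, f"label_{lab}"): {
                    "label": lab,
                    "voxels": self.voxel_counts[lab],
                    "volume_cm3": round(self.volumes_cm3[lab], 4),
                }
                for lab in sorted(self.voxel_counts)
            },
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    def to_csv_row(self) -> str:
        """One CSV row 'label,name,voxels,volume_cm3' block for batch runs."""
        lines = ["label,name,voxels,volume_cm3"]
        for lab in sorted(self.voxel_counts):
            lines.append(f"{lab},{self.label_names.get(lab, f'label_{lab}')},"
                         f"{self.voxel_counts[lab]},{self.volumes_cm3[lab]:.4f}")
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        parts = [f"{self.label_names.get(l, f'label_{l}')}: {v:.4f} cm^3"
                 for l, v in sorted(self.volumes_cm3.items())]
        return "VolumeReport(" + ", ".join(parts) + ")"


def compute_volumes(labels: LabelMap, spacing: tuple[float, float, float],
                    companion: CTVolume | None = None) -> VolumeReport:
    """Voxel-count volumes per tissue label.

    ``volume = count * dx*dy*dz / 1000`` (cm^3), exactly; the per-label
    counts sum to the total number of ROI voxels. If the companion CT volume
    is given, its shape and spacing must match.
    """
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing}")
    if companion is not None:
        if companion.shape != labels.shape:
            raise ValueError(f"label map shape {labels.shape} != volume shape {companion.shape}")
        if not np.allclose(companion.spacing, spacing):
            raise ValueError(f"spacing {spacing} mismatches companion volume {companion.spacing}")
    vox_mm3 = float(np.prod(spacing))
    counts = np.bincount(labels.labels.ravel())
    voxel_counts = {int(l): int(c) for l, c in enumerate(counts) if c > 0}
    # report zero for named but absent tissues, so series align
    for lab in labels.label_names:
        voxel_counts.setdefault(int(lab), 0)
    volumes = {l: c * vox_mm3 / 1000.0 for l, c in voxel_counts.items()}
    return VolumeReport(voxel_counts=voxel_counts, volumes_cm3=volumes,
                        spacing=spacing, label_names=dict(labels.label_names))


def volume_series_deltas(reports: list[VolumeReport], label: int) -> list[float]:
    """Successive volume differences (cm^3) of one tissue across a series."""
    if len(reports) < 2:
        raise ValueError("need >= 2 reports to form deltas")
    for i, rep in enumerate(reports):
        if label not in rep.volumes_cm3:
            raise ValueError(f"label {label} absent from report {i}")
    vols = [rep.volumes_cm3[label] for rep in reports]
    return [b - a for a, b in zip(vols, vols[1:])]


def extract_surface(labels: LabelMap, label: int,
                    spacing: tuple[float, float, float]) -> trimesh.Trimesh:
    """Marching-cubes surface of one tissue, vertices in mm.

    The mask is padded by one background voxel on every face so masks
    touching the ROI boundary still close; the resulting mesh is watertight
    for connected solid tissues.
    """
    mask = labels.mask(label)
    if not mask.any():
        raise ValueError(f"empty tissue: label {label} has no voxels")
    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    verts = verts - np.asarray(spacing)  # undo the one-voxel pad offset
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Export a surface as STL (binary) or PLY, by file extension."""
    path = Path(path)
    if path.suffix.lower() not in {".stl", ".ply"}:
        raise ValueError(f"unsupported mesh format {path.suffix}; use .stl or .ply")
    mesh.export(str(path))
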