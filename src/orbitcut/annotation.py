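"""Seed strokes: the interactive three-brush input, without the GUI.

Users of the original workflow draw coloured polylines on one or several
axial slices (red = muscle, blue = fat, maroon = bone/dense). Here a stroke
is a per-slice 2-D polyline with a brush radius; rasterisation draws a
Bresenham path between consecutive points and dilates it by an in-plane
Euclidean disc. Conflicting seeds (two labels on one voxel) are a hard
error — silent override would corrupt the hard constraints fed to the
segmentation energy.

``auto_seeds_from_truth`` emulates the interactive user for unattended runs
by sampling interior voxels of a ground-truth label map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import line as bresenham_line

from .volume_io import CTVolume, LabelMap, DEFAULT_LABEL_NAMES

__all__ = ["SeedStroke", "SeedSet", "rasterize_seeds", "save_seeds", "load_seeds",
           "auto_seeds_from_truth", "SeedConflictError"]

SEED_FILE_VERSION = 1


class SeedConflictError(ValueError):
    """Two strokes of different labels painted the same voxel."""

    def __init__(self, voxel: tuple[int, int, int], labels: tuple[int, int]):
        self.voxel = voxel
        self.labels = labels
        super().__init__(
            f"conflicting seed labels {labels[0]} and {labels[1]} at voxel {voxel}; "
            "strokes of different tissues must not overlap"
        )


@dataclass
class SeedStroke:
    """One brush stroke: a polyline on a single slice, dilated by a disc."""

    label: int
    slice_index: int
    polyline: list[tuple[int, int]]   # (row, col) voxel coordinates
    brush_radius: int = 1

    def __post_init__(self) -> None:
        self.label = int(self.label)
        self.slice_index = int(self.slice_index)
        self.polyline = [(int(r), int(c)) for r, c in self.polyline]
        self.brush_radius = int(self.brush_radius)
        if not self.polyline:
            raise ValueError("stroke polyline must contain at least one point")
        if self.brush_radius < 0:
            raise ValueError("brush radius must be non-negative")


@dataclass
class SeedSet:
    """A collection of strokes plus the label vocabulary they draw from."""

    strokes: list[SeedStroke] = field(default_factory=list)
    label_names: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_NAMES))

    def __post_init__(self) -> None:
        self.label_names = {int(k): str(v) for k, v in self.label_names.items()}
        for s in self.strokes:
            if s.label not in self.label_names:
                raise ValueError(f"stroke label {s.label} not in label_names {sorted(self.label_names)}")

    @property
    def labels_present(self) -> set[int]:
        return {s.label for s in self.strokes}

    def digest(self) -> str:
        """Stable content digest, echoed into segmentation results."""
        import hashlib
        payload = json.dumps(_seeds_to_obj(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _disc_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dr * dr + dc * dc <= r * r
    return np.stack([dr[keep], dc[keep]], axis=1)


def rasterize_seeds(seeds: SeedSet, vol: CTVolume) -> dict[tuple[int, int, int], int]:
    """Rasterise strokes into a sparse voxel -> label assignment.

    Each polyline is drawn as a connected discrete path (Bresenham between
    consecutive points), dilated by its brush radius within the slice, and
    clipped against nothing: points outside the volume are an error.

    Raises
    ------
    SeedConflictError
        If strokes of two different labels paint the same voxel.
    """
    ns, nr, nc = vol.shape
    painted: dict[tuple[int, int, int], int] = {}
    for stroke in seeds.strokes:
        if not (0 <= stroke.slice_index < ns):
            raise ValueError(f"stroke slice {stroke.slice_index} outside volume ({ns} slices)")
        for r, c in stroke.polyline:
            if not (0 <= r < nr and 0 <= c < nc):
                raise ValueError(f"stroke point {(r, c)} outside slice bounds {(nr, nc)}")
        rows, cols = [], []
        pts = stroke.polyline
        for (r0, c0), (r1, c1) in zip(pts, pts[1:] or pts):
            rr, cc = bresenham_line(r0, c0, r1, c1)
            rows.append(rr)
            cols.append(cc)
        rr = np.concatenate(rows)
        cc = np.concatenate(cols)
        offs = _disc_offsets(stroke.brush_radius)
        rr = (rr[:, None] + offs[:, 0]).ravel()
        cc = (cc[:, None] + offs[:, 1]).ravel()
        keep = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
        for r, c in zip(rr[keep].tolist(), cc[keep].tolist()):
            vox = (stroke.slice_index, r, c)
            prev = painted.get(vox)
            if prev is not None and prev != stroke.label:
                raise SeedConflictError(vox, (prev, stroke.label))
            painted[vox] = stroke.label
    return painted


# ---------------------------------------------------------------------------
# Serialisation (JSON seed files)

def _seeds_to_obj(seeds: SeedSet) -> dict:
    return {
        "version": SEED_FILE_VERSION,
        "label_names": {str(k): v for k, v in seeds.label_names.items()},
        "strokes": [
            {"label": s.label, "slice": s.slice_index,
             "points": [[r, c] for r, c in s.polyline], "radius": s.brush_radius}
            for s in seeds.strokes
        ],
    }


def save_seeds(seeds: SeedSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_seeds_to_obj(seeds), indent=2))


def load_seeds(path: str | Path) -> SeedSet:
    obj = json.loads(Path(path).read_text())
    label_names = {int(k): str(v) for k, v in obj["label_names"].items()}
    strokes = []
    for s in obj["strokes"]:
        if int(s["label"]) not in label_names:
            raise ValueError(f"seed file stroke label {s['label']} absent from label_names")
        strokes.append(SeedStroke(label=s["label"], slice_index=s["slice"],
                                  polyline=[tuple(p) for p in s["points"]],
                                  brush_radius=s["radius"]))
    return SeedSet(strokes=strokes, label_names=label_names)


# ---------------------------------------------------------------------------
# Simulated user

def auto_seeds_from_truth(truth: LabelMap, per_label_count: int, rng_seed: int,
                          include_background: bool = False,
                          max_slices_per_label: int = 3) -> SeedSet:
    """Sample single-voxel seed strokes from a ground-truth label map.

    Emulates a user marking a few voxels of each tissue on at most
    ``max_slices_per_label`` distinct slices. Voxels are drawn from the
    interior of each region (binary erosion by one voxel) so seeds avoid
    partial-volume boundaries; a region with empty interior falls back to
    its full extent with a warning. Deterministic given ``rng_seed``.
    """
    if per_label_count < 1:
        raise ValueError("per_label_count must be >= 1")
    rng = np.random.default_rng(rng_seed)
    labels = sorted(int(v) for v in np.unique(truth.labels))
    if not include_background:
        labels = [l for l in labels if l != 0]
    strokes: list[SeedStroke] = []
    for lab in labels:
        mask = truth.mask(lab)
        interior = ndimage.binary_erosion(mask)
        if not interior.any():
            warnings.warn(f"label {lab} has empty interior; sampling from non-eroded voxels", stacklevel=2)
            interior = mask
        slice_counts = interior.sum(axis=(1, 2))
        candidate_slices = np.argsort(slice_counts, kind="stable")[::-1]
        chosen = [int(s) for s in candidate_slices[:max_slices_per_label] if slice_counts[s] > 0]
        sl_mask = np.zeros_like(interior)
        sl_mask[chosen] = interior[chosen]
        idx = np.argwhere(sl_mask)
        if len(idx) < per_label_count:
            warnings.warn(f"label {lab}: only {len(idx)} interior voxels available on "
                          f"{len(chosen)} slices; emitting that many seeds", stacklevel=2)
        take = min(per_label_count, len(idx))
        sel = idx[rng.choice(len(idx), size=take, replace=False)]
        sel = sel[np.lexsort((sel[:, 2], sel[:, 1], sel[:, 0]))]
        for s, r, c in sel.tolist():
            strokes.append(SeedStroke(label=lab, slice_index=s, polyline=[(r, c)], brush_radius=0))
    return SeedSet(strokes=strokes, label_names=dict(truth.label_names))
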