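"""Labeled atlas volumes, stereotactic coordinate conversion, toy atlases.

Volumes use axis order (AP, DV, ML) with isotropic voxels.  Stereotactic
coordinates are bregma-relative millimeters: bregma sits at atlas AP
5.4 mm from the volume front, at the midsagittal ML plane and the brain
surface (DV index 0).  Positive AP is anterior, positive ML is the left
hemisphere, and deeper positions carry more negative DV values.

Real atlases (e.g. a 20 um isotropic labeled mouse atlas) can be adapted by
saving their annotation as the NPZ + JSON contract of :func:`save_atlas`;
downloading them is outside the scope of this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "AtlasVolume",
    "stereo_to_voxel",
    "voxel_to_stereo",
    "merge_labels",
    "build_toy_atlas",
    "save_atlas",
    "load_atlas",
    "BREGMA_AP_MM",
]

#: Atlas AP position of bregma, mm from the volume front.
BREGMA_AP_MM = 5.4

OUTSIDE_LABEL = 0


@dataclass
class AtlasVolume:
    """3-D integer label volume with stereotactic anchoring metadata."""

    labels: np.ndarray
    voxel_um: float
    midline_ml_index: int
    name_map: dict
    bregma_ap_mm: float = BREGMA_AP_MM
    rgb_map: dict | None = None
    surface_dv_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D (AP, DV, ML) volume")
        if self.voxel_um <= 0:
            raise ValueError("voxel size must be positive")
        ap_idx = int(round(self.bregma_ap_mm * 1000.0 / self.voxel_um))
        if not (0 <= ap_idx < self.labels.shape[0]):
            raise ValueError("bregma anchor falls outside the volume along AP")
        if not (0 <= self.midline_ml_index < self.labels.shape[2]):
            raise ValueError("midline index outside the volume")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def label_at(self, voxel) -> int:
        """Label at a voxel index triple; 0 for out-of-volume indices."""
        i, j, k = voxel
        if not self.contains(voxel):
            return OUTSIDE_LABEL
        return int(self.labels[i, j, k])

    def contains(self, voxel) -> bool:
        i, j, k = voxel
        sh = self.labels.shape
        return 0 <= i < sh[0] and 0 <= j < sh[1] and 0 <= k < sh[2]


def stereo_to_voxel(atlas: AtlasVolume, ap_mm: float, ml_mm: float, dv_mm: float):
    """Bregma-relative millimeters -> (AP, DV, ML) voxel indices + inside flag.

    Out-of-volume indices are returned unclamped with ``inside=False``.
    """
    if not np.all(np.isfinite([ap_mm, ml_mm, dv_mm])):
        raise ValueError("stereotactic coordinates must be finite")
    scale = 1000.0 / atlas.voxel_um
    ap_index = int(round((atlas.bregma_ap_mm - ap_mm) * scale))
    dv_index = int(round(-dv_mm * scale))
    ml_index = atlas.midline_ml_index + int(round(ml_mm * scale))
    voxel = (ap_index, dv_index, ml_index)
    return voxel, atlas.contains(voxel)


def voxel_to_stereo(atlas: AtlasVolume, voxel) -> tuple:
    """Inverse of :func:`stereo_to_voxel` (to within half a voxel per axis)."""
    i, j, k = voxel
    scale = atlas.voxel_um / 1000.0
    ap_mm = atlas.bregma_ap_mm - i * scale
    dv_mm = -j * scale
    ml_mm = (k - atlas.midline_ml_index) * scale
    return ap_mm, ml_mm, dv_mm


def merge_labels(atlas: AtlasVolume, merge_spec: dict) -> AtlasVolume:
    """Consolidate labels, e.g. collapsing subregions into one parent label.

    ``merge_spec`` maps a tuple of old labels to the new label they become.
    Groups must be disjoint, label 0 cannot be remapped, and a new label may
    not collide with an untouched existing label (it may equal one of its
    own old labels).
    """
    all_old: list[int] = []
    for olds in merge_spec:
        all_old.extend(int(o) for o in olds)
    if len(set(all_old)) != len(all_old):
        raise ValueError("merge groups must be disjoint")
    if OUTSIDE_LABEL in all_old:
        raise ValueError("label 0 (outside brain) cannot be merged")
    untouched = set(np.unique(atlas.labels).tolist()) - set(all_old)
    labels = atlas.labels.copy()
    name_map = dict(atlas.name_map)
    for olds, new in merge_spec.items():
        new = int(new)
        if new in untouched and new not in olds:
            raise ValueError(f"new label {new} collides with an untouched label")
        labels[np.isin(atlas.labels, list(olds))] = new
        for o in olds:
            name_map.pop(int(o), None)
        names = [atlas.name_map[int(o)] for o in olds if int(o) in atlas.name_map]
        name_map[new] = atlas.name_map.get(new) or "+".join(names) or str(new)
    return replace(atlas, labels=labels, name_map=name_map)


def build_toy_atlas(
    layers,
    *,
    voxel_um: float = 50.0,
    ap_extent_mm: float = 10.8,
    ml_extent_mm: float = 4.0,
    margin_mm: float = 0.3,
    surface_depth_um: float = 300.0,
    boundary_tilt_um_per_mm=None,
    dv_margin_um: float = 500.0,
    dv_extent_mm: float | None = None,
    seed: int = 0,
    first_label: int = 1,
) -> AtlasVolume:
    """Layered toy brain for testing: labels stacked along DV in a block.

    ``layers`` is a list of ``(name, thickness_um)`` stacked beneath a flat
    surface at ``surface_depth_um``; everything above the surface, below the
    deepest layer, or outside the AP/ML margins is label 0.  Optional
    ``boundary_tilt_um_per_mm`` gives each internal boundary (including the
    bottom of the last layer) AP and ML slopes, producing laterally varying
    layer depths; boundaries are kept ordered by a running maximum.  The
    construction is deterministic; ``seed`` only matters when
    ``boundary_tilt_um_per_mm="random"`` draws slopes.
    """
    names = [n for n, _ in layers]
    thick = np.asarray([t for _, t in layers], dtype=float)
    if np.any(thick <= 0):
        raise ValueError("layer thicknesses must be positive")
    n_layers = len(layers)

    ap_n = int(round(ap_extent_mm * 1000.0 / voxel_um))
    ml_n = int(round(ml_extent_mm * 1000.0 / voxel_um)) | 1  # odd: midline voxel
    depth_total = surface_depth_um + thick.sum() + dv_margin_um
    if dv_extent_mm is not None and depth_total > dv_extent_mm * 1000.0:
        raise ValueError("layers exceed the requested DV volume extent")
    dv_n = int(np.ceil(depth_total / voxel_um))
    if ap_n * ml_n * dv_n > 2e8:
        raise ValueError("toy atlas volume too large; increase voxel_um")
    midline = ml_n // 2

    # boundary base depths below the surface: [surface, b1 .. b_{L-1}, bottom]
    base = surface_depth_um + np.concatenate(([0.0], np.cumsum(thick)))
    if boundary_tilt_um_per_mm is None:
        tilt = np.zeros((n_layers + 1, 2))
    elif isinstance(boundary_tilt_um_per_mm, str) and boundary_tilt_um_per_mm == "random":
        rng = np.random.default_rng(seed)
        tilt = np.zeros((n_layers + 1, 2))
        tilt[1:] = rng.uniform(-250.0, 250.0, size=(n_layers, 2))
    else:
        tilt = np.asarray(boundary_tilt_um_per_mm, dtype=float)
        if tilt.shape != (n_layers + 1, 2):
            raise ValueError(
                "boundary_tilt_um_per_mm must be (n_layers + 1) x 2 "
                "(AP slope, ML slope) including the surface row"
            )

    ap_mm_rel = (np.arange(ap_n) - ap_n / 2.0) * voxel_um / 1000.0
    ml_mm_rel = (np.arange(ml_n) - midline) * voxel_um / 1000.0
    # boundary depth field, (ap, ml, n_layers + 1)
    depth = (
        base[None, None, :]
        + tilt[None, None, :, 0] * ap_mm_rel[:, None, None]
        + tilt[None, None, :, 1] * ml_mm_rel[None, :, None]
    )
    depth = np.maximum.accumulate(depth, axis=2)

    dv_centers = (np.arange(dv_n) + 0.5) * voxel_um
    # count of boundaries above each voxel center: 0 = above surface,
    # 1..L = inside layer, L+1 = below the deepest layer.
    count = (dv_centers[None, None, :, None] >= depth[:, :, None, :]).sum(axis=3)
    labels = np.where(
        (count >= 1) & (count <= n_layers), first_label + count - 1, OUTSIDE_LABEL
    ).astype(np.int32)
    labels = labels.transpose(0, 2, 1)  # (ap, ml, dv) -> (AP, DV, ML)

    margin_vox = int(round(margin_mm * 1000.0 / voxel_um))
    if margin_vox:
        labels[:margin_vox] = OUTSIDE_LABEL
        labels[-margin_vox:] = OUTSIDE_LABEL
        labels[:, :, :margin_vox] = OUTSIDE_LABEL
        labels[:, :, -margin_vox:] = OUTSIDE_LABEL

    name_map = {OUTSIDE_LABEL: "outside"}
    name_map.update({first_label + i: names[i] for i in range(n_layers)})
    return AtlasVolume(
        labels=labels,
        voxel_um=float(voxel_um),
        midline_ml_index=midline,
        name_map=name_map,
    )


def save_atlas(atlas: AtlasVolume, npz_path, json_path=None) -> None:
    """Write the NPZ (array ``labels``) + JSON metadata pair."""
    np.savez_compressed(npz_path, labels=atlas.labels.astype(np.int32))
    if json_path is None:
        json_path = Path(npz_path).with_suffix(".json")
    meta = {
        "voxel_um": atlas.voxel_um,
        "bregma_ap_mm": atlas.bregma_ap_mm,
        "midline_ml_index": int(atlas.midline_ml_index),
        "name_map": {str(k): v for k, v in atlas.name_map.items()},
    }
    if atlas.rgb_map is not None:
        meta["rgb_map"] = {str(k): list(v) for k, v in atlas.rgb_map.items()}
    with open(json_path, "w") as fh:
        json.dump(meta, fh)


def load_atlas(npz_path, json_path=None) -> AtlasVolume:
    if json_path is None:
        json_path = Path(npz_path).with_suffix(".json")
    with np.load(npz_path) as data:
        labels = data["labels"]
    with open(json_path) as fh:
        meta = json.load(fh)
    rgb = meta.get("rgb_map")
    return AtlasVolume(
        labels=labels,
        voxel_um=float(meta["voxel_um"]),
        midline_ml_index=int(meta["midline_ml_index"]),
        name_map={int(k): v for k, v in meta["name_map"].items()},
        bregma_ap_mm=float(meta.get("bregma_ap_mm", BREGMA_AP_MM)),
        rgb_map={int(k): tuple(v) for k, v in rgb.items()} if rgb else None,
    )
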