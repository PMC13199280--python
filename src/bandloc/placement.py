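"""Atlas placement of the probe and local refinement of its position.

The probe is dropped into the coronal slice selected by the user's AP
coordinate, with the tip of the first shank anchored at the requested
ML/DV position.  Each electrode cluster is assigned the modal atlas label
of its electrodes, and the placement is then refined by exhaustively
shifting the probe across neighboring coronal slices (+/-8 by default) and
ML/DV displacements (+/-600 um) and keeping the shift that maximizes the
number of electrodes landing in their cluster's assigned region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .atlas import OUTSIDE_LABEL, AtlasVolume, stereo_to_voxel
from .probe_geometry import ProbeLayout
from .reduce_cluster import ClusterResult
from .signal_io import PipelineConfig

__all__ = [
    "StereoCoords",
    "PlacementResult",
    "electrode_voxels",
    "electrode_labels",
    "assign_cluster_regions",
    "refine_placement",
    "plot_overlay",
]


class StereoCoords(NamedTuple):
    """Bregma-relative stereotactic coordinates, mm."""

    ap_mm: float
    ml_mm: float
    dv_mm: float


@dataclass
class PlacementResult:
    initial: StereoCoords
    refined: StereoCoords
    best_offset: tuple          # (AP slices, ML um, DV um)
    ap_offsets: np.ndarray      # slices
    ml_offsets_um: np.ndarray
    dv_offsets_um: np.ndarray
    match_counts: np.ndarray    # (n_ap, n_ml, n_dv)
    cluster_regions: dict       # cluster label -> atlas label
    matched_fraction_initial: float
    matched_fraction_refined: float
    step_um: float


def electrode_voxels(layout: ProbeLayout, placement, atlas: AtlasVolume):
    """Voxel index triple per electrode plus an inside-volume flag.

    All electrodes share the coronal (AP) slice of the placement; the tip
    electrode of shank 0 (x=0, z=0) maps exactly to the placement's ML/DV
    voxel; positive ``x_um`` displaces toward positive ML and ``z_um``
    moves electrodes up (shallower) from the tip.
    """
    ap_mm, ml_mm, dv_mm = placement
    (ap_idx, dv_tip, ml_tip), _ = stereo_to_voxel(atlas, ap_mm, ml_mm, dv_mm)
    x = np.asarray(layout.x_um)
    z = np.asarray(layout.z_um)
    dv_idx = np.round((-dv_mm * 1000.0 - z) / atlas.voxel_um).astype(int)
    ml_idx = atlas.midline_ml_index + np.round(
        (ml_mm * 1000.0 + x) / atlas.voxel_um
    ).astype(int)
    voxels = np.column_stack(
        (np.full(layout.n_electrodes, ap_idx, dtype=int), dv_idx, ml_idx)
    )
    sh = atlas.labels.shape
    inside = (
        (voxels[:, 0] >= 0) & (voxels[:, 0] < sh[0])
        & (voxels[:, 1] >= 0) & (voxels[:, 1] < sh[1])
        & (voxels[:, 2] >= 0) & (voxels[:, 2] < sh[2])
    )
    if not inside.any():
        raise ValueError("entire probe lies outside the atlas volume")
    return voxels, inside


def electrode_labels(layout: ProbeLayout, placement, atlas: AtlasVolume) -> np.ndarray:
    """Atlas label per electrode (0 for electrodes outside the volume)."""
    voxels, inside = electrode_voxels(layout, placement, atlas)
    labels = np.full(layout.n_electrodes, OUTSIDE_LABEL, dtype=int)
    v = voxels[inside]
    labels[inside] = atlas.labels[v[:, 0], v[:, 1], v[:, 2]]
    return labels


def assign_cluster_regions(labels_at_electrodes, clusters: ClusterResult) -> dict:
    """Modal atlas label per cluster; ties broken by the smaller label id.

    Excluded electrodes (cluster -1) are ignored; label 0 is a legitimate
    mode for clusters of electrodes outside brain tissue.
    """
    atlas_labels = np.asarray(labels_at_electrodes)
    out: dict[int, int] = {}
    for c in np.unique(clusters.labels):
        if c < 0:
            continue
        members = atlas_labels[clusters.labels == c]
        if members.size == 0:
            raise ValueError(f"cluster {c} has no electrodes")
        vals, counts = np.unique(members, return_counts=True)
        out[int(c)] = int(vals[np.argmax(counts)])  # vals sorted: ties -> smaller id
    return out


def _count_matches(
    atlas: AtlasVolume,
    base_voxels: np.ndarray,
    expected: np.ndarray,
    clustered: np.ndarray,
    ap_offs: np.ndarray,
    ml_offs_vox: np.ndarray,
    dv_offs_vox: np.ndarray,
) -> np.ndarray:
    """Match counts over the (AP, ML, DV) offset grid, vectorized per slice.

    Electrodes shifted outside the volume read label 0, so they still match
    clusters whose assigned region is 0.
    """
    sh = atlas.labels.shape
    exp = expected[clustered]
    dv0 = base_voxels[clustered, 1]
    ml0 = base_voxels[clustered, 2]
    counts = np.empty((ap_offs.size, ml_offs_vox.size, dv_offs_vox.size), dtype=int)
    dv = dv0[None, None, :] + dv_offs_vox[None, :, None]   # (1, n_dv, n_el)
    ml = ml0[None, None, :] + ml_offs_vox[:, None, None]   # (n_ml, 1, n_el)
    dv_ok = (dv >= 0) & (dv < sh[1])
    ml_ok = (ml >= 0) & (ml < sh[2])
    dv_c = np.clip(dv, 0, sh[1] - 1)
    ml_c = np.clip(ml, 0, sh[2] - 1)
    for i, da in enumerate(ap_offs):
        ap = base_voxels[clustered, 0] + da
        ap_ok = (ap >= 0) & (ap < sh[0])
        ap_c = np.clip(ap, 0, sh[0] - 1)
        labels = atlas.labels[ap_c[None, None, :], dv_c, ml_c]
        inside = ap_ok[None, None, :] & dv_ok & ml_ok
        labels = np.where(inside, labels, OUTSIDE_LABEL)
        counts[i] = (labels == exp[None, None, :]).sum(axis=2)
    return counts


def refine_placement(
    layout: ProbeLayout,
    clusters: ClusterResult,
    atlas: AtlasVolume,
    initial,
    cfg: PipelineConfig,
    *,
    step_um: float | None = None,
    reassign_modes: bool = False,
) -> PlacementResult:
    """Exhaustive local search for the probe shift maximizing cluster-atlas agreement.

    Cluster regions are assigned once at the initial placement (mode of the
    electrode labels) and then held fixed while the probe is shifted; with
    ``reassign_modes=True`` the modes are recomputed at every candidate
    offset instead.  Ties in match count are broken by the smaller Euclidean
    offset norm, then the smaller AP offset.
    """
    initial = StereoCoords(*initial)
    if step_um is None:
        step_um = atlas.voxel_um
    base_voxels, _ = electrode_voxels(layout, initial, atlas)
    labels0 = electrode_labels(layout, initial, atlas)
    regions = assign_cluster_regions(labels0, clusters)

    clustered = clusters.labels >= 0
    expected = np.full(layout.n_electrodes, -9999, dtype=int)
    for c, r in regions.items():
        expected[clusters.labels == c] = r

    ap_offs = np.arange(-cfg.ap_search_slices, cfg.ap_search_slices + 1)
    n_steps = int(np.floor(cfg.mldv_search_um / step_um))
    offs_um = np.arange(-n_steps, n_steps + 1) * step_um
    offs_vox = np.round(offs_um / atlas.voxel_um).astype(int)

    if reassign_modes:
        counts = np.empty((ap_offs.size, offs_um.size, offs_um.size), dtype=int)
        for i, da in enumerate(ap_offs):
            for j, dm in enumerate(offs_um):
                for k, dd in enumerate(offs_um):
                    cand = StereoCoords(
                        initial.ap_mm - da * atlas.voxel_um / 1000.0,
                        initial.ml_mm + dm / 1000.0,
                        initial.dv_mm - dd / 1000.0,
                    )
                    lab = electrode_labels(layout, cand, atlas)
                    reg = assign_cluster_regions(lab, clusters)
                    exp = np.array(
                        [reg[c] if c >= 0 else -9999 for c in clusters.labels]
                    )
                    counts[i, j, k] = int((lab[clustered] == exp[clustered]).sum())
    else:
        counts = _count_matches(
            atlas, base_voxels, expected, clustered, ap_offs, offs_vox, offs_vox
        )

    if counts.max() == 0:
        raise ValueError(
            "no candidate offset matches any electrode to its cluster region; "
            "check the atlas labels and the initial placement"
        )

    da_g, dm_g, dd_g = np.meshgrid(ap_offs, offs_um, offs_um, indexing="ij")
    flat = counts.ravel()
    norm = np.sqrt(
        (da_g.ravel() * atlas.voxel_um) ** 2 + dm_g.ravel() ** 2 + dd_g.ravel() ** 2
    )
    order = np.lexsort((dd_g.ravel(), dm_g.ravel(), da_g.ravel(), norm, -flat))
    best = order[0]
    da = int(da_g.ravel()[best])
    dm = float(dm_g.ravel()[best])
    dd = float(dd_g.ravel()[best])

    refined = StereoCoords(
        initial.ap_mm - da * atlas.voxel_um / 1000.0,
        initial.ml_mm + dm / 1000.0,
        initial.dv_mm - dd / 1000.0,
    )
    n_clustered = int(clustered.sum())
    i0 = cfg.ap_search_slices
    j0 = n_steps
    return PlacementResult(
        initial=initial,
        refined=refined,
        best_offset=(da, dm, dd),
        ap_offsets=ap_offs,
        ml_offsets_um=offs_um,
        dv_offsets_um=offs_um,
        match_counts=counts,
        cluster_regions=regions,
        matched_fraction_initial=float(counts[i0, j0, j0]) / n_clustered,
        matched_fraction_refined=float(counts.max()) / n_clustered,
        step_um=float(step_um),
    )


def plot_overlay(
    atlas: AtlasVolume,
    layout: ProbeLayout,
    placement,
    cluster_labels,
    path,
    title: str = "",
) -> None:
    """Coronal-slice overlay of the probe and its clusters, written as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    placement = StereoCoords(*placement)
    (ap_idx, _, _), _ = stereo_to_voxel(atlas, *placement)
    ap_idx = int(np.clip(ap_idx, 0, atlas.labels.shape[0] - 1))
    fig, ax = plt.subplots(figsize=(6, 5))
    extent_ml = np.array([0, atlas.labels.shape[2]]) * atlas.voxel_um / 1000.0
    extent_dv = np.array([atlas.labels.shape[1], 0]) * atlas.voxel_um / 1000.0
    ax.imshow(
        atlas.labels[ap_idx],
        cmap="tab20",
        interpolation="nearest",
        origin="upper",
        extent=(extent_ml[0], extent_ml[1], extent_dv[0], extent_dv[1]),
        alpha=0.6,
    )
    voxels, inside = electrode_voxels(layout, placement, atlas)
    labels = np.asarray(cluster_labels)
    scale = atlas.voxel_um / 1000.0
    ax.scatter(
        voxels[:, 2] * scale,
        voxels[:, 1] * scale,
        c=np.where(labels >= 0, labels, -1),
        cmap="tab10",
        s=4,
        linewidths=0,
    )
    ax.set_xlabel("ML (mm, volume frame)")
    ax.set_ylabel("depth below surface (mm)")
    ax.invert_yaxis()
    ax.set_title(title or f"coronal slice {ap_idx} (AP {placement.ap_mm:+.2f} mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
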