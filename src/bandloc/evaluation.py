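"""Methodological studies: spatial decimation and feature convergence.

The decimation study asks how sparse an electrode grid can get before the
spatial cluster structure of the band-power maps degrades: features are
recomputed from decimated layouts, linearly interpolated onto a common grid
spanning the probe, re-clustered, and compared with the full-resolution
clustering through a grid-point matching score.  The convergence study asks
how much data is needed for stable power maps: features from growing prefix
segments are compared pixel-by-pixel with the full-duration reference,
normalized by the reference map's pixel standard deviation per band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .probe_geometry import ProbeLayout, decimate_layout
from .reduce_cluster import cluster_electrodes, standardize_and_pca
from .signal_io import PipelineConfig, Recording, subset_recording
from .spectral_features import (
    BandPowerMatrix,
    band_powers,
    remove_local_outliers,
    smooth_features,
    welch_psd,
    welch_window_length,
)

__all__ = [
    "FeatureGrid",
    "ConvergenceCurve",
    "interpolate_feature_grid",
    "cluster_matching_score",
    "decimation_study",
    "convergence_study",
]


@dataclass
class FeatureGrid:
    """Band features interpolated onto a uniform depth grid, one profile per shank."""

    shank_ids: np.ndarray
    z_um: np.ndarray                 # shared depth grid
    values: np.ndarray               # (n_shanks, n_z, n_bands)
    band_names: list
    labels: np.ndarray | None = None  # (n_shanks, n_z) cluster label per grid point

    @property
    def n_points(self) -> int:
        return self.values.shape[0] * self.values.shape[1]

    def flat_values(self) -> np.ndarray:
        return self.values.reshape(-1, self.values.shape[2])


@dataclass
class ConvergenceCurve:
    durations_s: np.ndarray
    diff_by_band: np.ndarray   # (n_durations, n_bands)
    diff_avg: np.ndarray
    band_names: list
    plateau_threshold: float
    time_to_convergence_s: float


def interpolate_feature_grid(
    bp: BandPowerMatrix,
    layout: ProbeLayout,
    grid_res_um: float = 10.0,
    z_um: np.ndarray | None = None,
) -> FeatureGrid:
    """Per-shank 1-D linear interpolation of retained band values onto a depth grid.

    Grid points beyond the first/last retained electrode of a shank hold the
    edge value (no extrapolation).  Electrodes of a two-column shank sharing
    a depth are averaged before interpolation.
    """
    if z_um is None:
        z_max = float(np.max(layout.z_um))
        z_um = np.arange(0.0, z_max + grid_res_um / 2, grid_res_um)
    shanks = np.unique(np.asarray(layout.shank_index))
    id_to_row = {int(e): i for i, e in enumerate(bp.electrode_ids)}
    values = np.empty((shanks.size, z_um.size, len(bp.band_names)))
    for si, shank in enumerate(shanks):
        idx = layout.shank_electrodes(shank)
        rows = np.asarray([id_to_row[int(layout.electrode_id[i])] for i in idx])
        keep = ~bp.excluded[rows]
        if not keep.any():
            raise ValueError(f"shank {shank} has no retained electrodes")
        z = np.asarray(layout.z_um)[idx][keep]
        v = bp.values[rows][keep]
        zu = np.unique(z)
        if zu.size < z.size:  # average the two columns at equal depth
            v = np.vstack([v[z == depth].mean(axis=0) for depth in zu])
            z = zu
        else:
            order = np.argsort(z)
            z, v = z[order], v[order]
        for b in range(v.shape[1]):
            values[si, :, b] = np.interp(z_um, z, v[:, b])
    return FeatureGrid(
        shank_ids=shanks, z_um=z_um, values=values, band_names=list(bp.band_names)
    )


def cluster_matching_score(reference: np.ndarray, test: np.ndarray) -> float:
    """Fraction of grid points whose mapped test cluster equals the reference cluster.

    Each test cluster is mapped to the reference cluster with which it
    overlaps on most grid points (many-to-one allowed), so the score is
    invariant to label permutation and equals 1.0 iff the partitions are
    identical up to renaming.
    """
    ref = np.asarray(reference).ravel()
    tst = np.asarray(test).ravel()
    if ref.shape != tst.shape:
        raise ValueError("reference and test label grids differ in size")
    mapped = np.empty_like(tst)
    for t in np.unique(tst):
        members = tst == t
        vals, counts = np.unique(ref[members], return_counts=True)
        mapped[members] = vals[np.argmax(counts)]
    return float(np.mean(mapped == ref))


def _grid_band_powers(
    rec: Recording, layout: ProbeLayout, cfg: PipelineConfig, z_um: np.ndarray
) -> FeatureGrid:
    sub = subset_recording(rec, layout.electrode_id)
    psd = welch_psd(sub, cfg)
    bp = band_powers(psd, cfg)
    bp = remove_local_outliers(bp, layout, cfg)
    bp = smooth_features(bp, layout, cfg)
    return interpolate_feature_grid(bp, layout, z_um=z_um)


def _cluster_grid(grid: FeatureGrid, cfg: PipelineConfig, method: str) -> FeatureGrid:
    flat = grid.flat_values()
    bp = BandPowerMatrix(
        values=flat,
        band_names=list(grid.band_names),
        band_edges=np.zeros((len(grid.band_names), 2)),
        electrode_ids=np.arange(flat.shape[0]),
        excluded=np.zeros(flat.shape[0], dtype=bool),
        smoothed=True,
    )
    fs = standardize_and_pca(bp, cfg)
    res = cluster_electrodes(fs, cfg, method=method)
    labels = res.labels.reshape(grid.values.shape[0], grid.values.shape[1])
    return replace(grid, labels=labels)


def decimation_study(
    rec: Recording,
    layout: ProbeLayout,
    cfg: PipelineConfig,
    dfs=(1, 2, 4, 8, 16),
    grid_res_um: float = 10.0,
    method: str = "hierarchical",
) -> pd.DataFrame:
    """Cluster matching score against the full-resolution reference per decimation factor.

    For every df the layout is decimated, band powers are recomputed from
    the retained electrodes only, interpolated to the common grid, and the
    grid points are re-clustered; the df=1 condition is the reference and
    scores 1.0 by construction.
    """
    dfs = list(dfs)
    if dfs[0] != 1:
        raise ValueError("dfs must start with 1 (the full-resolution reference)")
    z_max = float(np.max(layout.z_um))
    z_um = np.arange(0.0, z_max + grid_res_um / 2, grid_res_um)
    rows = []
    reference = None
    for df in dfs:
        sub_layout = decimate_layout(layout, df)
        grid = _grid_band_powers(rec, sub_layout, cfg, z_um)
        grid = _cluster_grid(grid, cfg, method)
        if reference is None:
            reference = grid
        score = cluster_matching_score(reference.labels, grid.labels)
        rows.append(
            {"df": df, "score": score, "n_clusters": int(grid.labels.max() + 1)}
        )
    return pd.DataFrame(rows)


def convergence_study(
    rec: Recording,
    layout: ProbeLayout,
    cfg: PipelineConfig,
    durations_s: np.ndarray | None = None,
    step_s: float = 5.0,
    plateau_tail: int = 6,
) -> ConvergenceCurve:
    """Normalized difference of band-power maps vs prefix duration.

    Pixels are the (smoothed, imputed) per-electrode band values.  For each
    band, diff(d) = mean_pixels |P_d - P_full| / std_pixels(P_full); the
    curve averaged over bands defines the plateau threshold (mean of the
    final ``plateau_tail`` points plus three standard deviations of those
    points) and the time to convergence is the earliest duration at or
    below it.
    """
    full_s = rec.duration_s
    min_s = welch_window_length(rec.fs_hz, cfg.welch_window_s) / rec.fs_hz
    if durations_s is None:
        first = step_s * np.ceil(min_s / step_s)
        durations_s = np.arange(first, full_s + step_s / 2, step_s)
        if durations_s.size == 0 or durations_s[-1] < full_s:
            durations_s = np.append(durations_s, full_s)
    durations_s = np.asarray(durations_s, dtype=float)
    if np.any(np.diff(durations_s) <= 0):
        raise ValueError("durations must be strictly increasing")
    if not np.isclose(durations_s[-1], full_s):
        raise ValueError("the last duration must equal the full recording length")
    if durations_s.size < plateau_tail + 1:
        raise ValueError(
            f"need more than {plateau_tail} durations to define the plateau"
        )
    if durations_s[0] < min_s:
        raise ValueError("shortest duration is below one Welch window")

    def _pixel_map(n_samples: int) -> np.ndarray:
        prefix = Recording(
            data=rec.data[:n_samples], fs_hz=rec.fs_hz, channel_ids=rec.channel_ids
        )
        psd = welch_psd(prefix, cfg)
        bp = band_powers(psd, cfg)
        bp = remove_local_outliers(bp, layout, cfg)
        bp = smooth_features(bp, layout, cfg)
        return bp.values

    ref = _pixel_map(rec.n_samples)
    std = ref.std(axis=0)
    if np.any(std == 0):
        raise ValueError("degenerate normalizer: a reference band map has zero pixel std")

    diffs = np.empty((durations_s.size, ref.shape[1]))
    for i, d in enumerate(durations_s):
        n = min(rec.n_samples, int(round(d * rec.fs_hz)))
        part = _pixel_map(n)
        diffs[i] = np.abs(part - ref).mean(axis=0) / std
    avg = diffs.mean(axis=1)

    tail = avg[-plateau_tail:]
    plateau = float(tail.mean() + 3.0 * tail.std(ddof=1))
    below = np.flatnonzero(avg <= plateau)
    t_conv = float(durations_s[below[0]])
    return ConvergenceCurve(
        durations_s=durations_s,
        diff_by_band=diffs,
        diff_avg=avg,
        band_names=list(cfg.bands),
        plateau_threshold=plateau,
        time_to_convergence_s=t_conv,
    )
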