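"""Per-electrode Welch spectra, normalized band powers, outlier removal, smoothing.

Band powers are integrals of the one-sided PSD over the canonical band
edges, normalized by the total power in the LFP band (1-300 Hz), so each
feature is a unitless fraction in [0, 1] and the six bands jointly cover
1-250 Hz of the normalizer.  Outlier electrodes are detected per shank
within adjacent 20-electrode depth windows (|z| > 2.5 in any band) and
spatial smoothing is an 8-electrode moving average along each shank.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .probe_geometry import ProbeLayout, depth_order_indices
from .signal_io import PipelineConfig, Recording

__all__ = [
    "PSDMatrix",
    "BandPowerMatrix",
    "welch_psd",
    "band_powers",
    "remove_local_outliers",
    "smooth_features",
    "band_power_frame",
    "compute_band_powers",
]


@dataclass
class PSDMatrix:
    """One-sided power spectral densities, electrodes x frequencies (uV^2/Hz)."""

    freqs_hz: np.ndarray
    psd: np.ndarray
    electrode_ids: np.ndarray
    fs_hz: float
    window_length: int
    overlap: float
    taper: str = "hann"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.psd.shape != (self.electrode_ids.size, self.freqs_hz.size):
            raise ValueError("psd must be electrodes x frequencies")


@dataclass
class BandPowerMatrix:
    """Normalized band powers, electrodes x bands, with an exclusion mask.

    ``excluded`` electrodes keep their values for audit (and, after
    smoothing, hold imputed values for map display) but never enter
    clustering.
    """

    values: np.ndarray
    band_names: list
    band_edges: np.ndarray
    electrode_ids: np.ndarray
    excluded: np.ndarray
    smoothed: bool = False

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    def retained(self) -> np.ndarray:
        """Row indices of electrodes that survive exclusion."""
        return np.flatnonzero(~self.excluded)


def welch_window_length(fs_hz: float, welch_window_s: float) -> int:
    """Power of two closest (in log2) to ``welch_window_s * fs``."""
    return int(2 ** round(np.log2(welch_window_s * fs_hz)))


def welch_psd(rec: Recording, cfg: PipelineConfig) -> PSDMatrix:
    """Welch PSD per electrode (Hann taper, 50% overlap, density scaling)."""
    nperseg = welch_window_length(rec.fs_hz, cfg.welch_window_s)
    if rec.n_samples < nperseg:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one Welch "
            f"window ({nperseg} samples)"
        )
    noverlap = int(nperseg * cfg.welch_overlap)
    freqs, pxx = signal.welch(
        rec.data,
        fs=rec.fs_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        axis=0,
        scaling="density",
    )
    return PSDMatrix(
        freqs_hz=freqs,
        psd=pxx.T,
        electrode_ids=np.asarray(rec.channel_ids),
        fs_hz=rec.fs_hz,
        window_length=nperseg,
        overlap=cfg.welch_overlap,
    )


def _integrate_band(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Integral over [lo, hi] of the piecewise-linear interpolant of each PSD row."""
    p_lo = np.array([np.interp(lo, freqs, row) for row in psd])
    p_hi = np.array([np.interp(hi, freqs, row) for row in psd])
    inner = (freqs > lo) & (freqs < hi)
    grid = np.concatenate(([lo], freqs[inner], [hi]))
    vals = np.concatenate((p_lo[:, None], psd[:, inner], p_hi[:, None]), axis=1)
    return np.trapezoid(vals, grid, axis=1)


def band_powers(psd: PSDMatrix, cfg: PipelineConfig) -> BandPowerMatrix:
    """Integrate the PSD in each band and normalize by total 1-300 Hz power.

    Electrodes with non-positive total LFP power (dead channels) are marked
    excluded with all-zero features.
    """
    lo_norm, hi_norm = cfg.lfp_band_hz
    if psd.freqs_hz[0] > lo_norm or psd.freqs_hz[-1] < hi_norm:
        raise ValueError("frequency grid does not cover the LFP normalizer band")
    total = _integrate_band(psd.freqs_hz, psd.psd, lo_norm, hi_norm)
    names = list(cfg.bands)
    edges = np.asarray([cfg.bands[b] for b in names], dtype=float)
    values = np.zeros((psd.psd.shape[0], len(names)))
    dead = total <= 0
    ok = ~dead
    for j, (a, b) in enumerate(edges):
        values[ok, j] = _integrate_band(psd.freqs_hz, psd.psd[ok], a, b) / total[ok]
    return BandPowerMatrix(
        values=values,
        band_names=names,
        band_edges=edges,
        electrode_ids=psd.electrode_ids,
        excluded=dead.copy(),
    )


def _tiles(n: int, width: int) -> list:
    """Adjacent (non-overlapping) index tiles; the last tile absorbs the remainder."""
    if n <= width:
        return [np.arange(n)] if n else []
    n_full = n // width
    bounds = [i * width for i in range(n_full)] + [n]
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(n_full)]


def remove_local_outliers(
    bp: BandPowerMatrix, layout: ProbeLayout, cfg: PipelineConfig
) -> BandPowerMatrix:
    """Exclude electrodes deviating locally from their shank neighbors.

    Per shank, the currently retained electrodes are tiled in depth order
    into adjacent windows of ``outlier_window_n``; an electrode with
    |z-score| strictly greater than ``z_threshold`` in any band (window
    mean/std, sample denominator) is excluded in all bands.  Zero-variance
    windows mark no outliers.
    """
    excluded = bp.excluded.copy()
    id_to_row = {int(e): i for i, e in enumerate(bp.electrode_ids)}
    for shank in np.unique(np.asarray(layout.shank_index)):
        ordered = depth_order_indices(layout, shank)
        rows = np.asarray(
            [id_to_row[int(layout.electrode_id[i])] for i in ordered], dtype=int
        )
        rows = rows[~excluded[rows]]
        for tile in _tiles(rows.size, cfg.outlier_window_n):
            members = rows[tile]
            vals = bp.values[members]
            if members.size < 2:
                continue
            mean = vals.mean(axis=0)
            std = vals.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.abs(vals - mean) / std
            z[:, std == 0] = 0.0
            excluded[members[np.any(z > cfg.z_threshold, axis=1)]] = True
    return replace(bp, excluded=excluded)


def smooth_features(
    bp: BandPowerMatrix, layout: ProbeLayout, cfg: PipelineConfig
) -> BandPowerMatrix:
    """Centered moving average along each shank over retained electrodes.

    The window covers ``smooth_window_n`` consecutive depth-ordered
    electrodes (positions i-w//2 .. i+w-w//2-1, truncated at shank ends);
    excluded electrodes contribute nothing and receive the average of the
    retained electrodes in their window (imputation for map display; their
    exclusion mask is preserved).
    """
    w = cfg.smooth_window_n
    values = bp.values.copy()
    id_to_row = {int(e): i for i, e in enumerate(bp.electrode_ids)}
    for shank in np.unique(np.asarray(layout.shank_index)):
        ordered = depth_order_indices(layout, shank)
        rows = np.asarray(
            [id_to_row[int(layout.electrode_id[i])] for i in ordered], dtype=int
        )
        retained = ~bp.excluded[rows]
        vals = bp.values[rows]
        n = rows.size
        for i in range(n):
            lo = max(0, i - w // 2)
            hi = min(n, i + (w - w // 2))
            sel = np.arange(lo, hi)[retained[lo:hi]]
            if sel.size:
                values[rows[i]] = vals[sel].mean(axis=0)
    return replace(bp, values=values, smoothed=True)


def band_power_frame(bp: BandPowerMatrix, layout: ProbeLayout) -> pd.DataFrame:
    """Tabular export: electrode_id, shank, z_um, one column per band, excluded."""
    id_to_pos = {int(e): i for i, e in enumerate(np.asarray(layout.electrode_id))}
    pos = np.asarray([id_to_pos[int(e)] for e in bp.electrode_ids])
    frame = pd.DataFrame(
        {
            "electrode_id": np.asarray(bp.electrode_ids, dtype=int),
            "shank": np.asarray(layout.shank_index)[pos],
            "z_um": np.asarray(layout.z_um)[pos],
        }
    )
    for j, name in enumerate(bp.band_names):
        frame[name] = bp.values[:, j]
    frame["excluded"] = bp.excluded
    return frame


def compute_band_powers(
    rec: Recording, layout: ProbeLayout, cfg: PipelineConfig
) -> BandPowerMatrix:
    """Welch PSD -> normalized band powers -> outlier removal -> smoothing."""
    psd = welch_psd(rec, cfg)
    bp = band_powers(psd, cfg)
    bp = remove_local_outliers(bp, layout, cfg)
    return smooth_features(bp, layout, cfg)
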