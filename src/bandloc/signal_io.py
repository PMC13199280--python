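"""Recording container, binary I/O, and LFP preprocessing.

Preprocessing mirrors the first stage of the localization pipeline: band-pass
filtering to the LFP band (1-300 Hz), downsampling to the common 1,250 Hz
rate, and an optional common average reference (CAR) that is disabled by
default because it can remove shared physiological components and promote
over-splitting of clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "PipelineConfig",
    "DEFAULT_BANDS",
    "read_recording",
    "write_recording",
    "bandpass_lfp",
    "resample_lfp",
    "apply_car",
    "subset_recording",
]

#: Canonical LFP bands plus the ripple band, Hz.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
    "ripple": (100.0, 250.0),
}


@dataclass
class Recording:
    """Multichannel extracellular recording, time x channels, in microvolts."""

    data: np.ndarray
    fs_hz: float
    channel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x channels)")
        self.channel_ids = np.asarray(self.channel_ids)
        if self.channel_ids.size != self.data.shape[1]:
            raise ValueError("channel_ids length must match channel count")
        if len(np.unique(self.channel_ids)) != self.channel_ids.size:
            raise ValueError("channel_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class PipelineConfig:
    """All scalar parameters of the localization pipeline.

    Defaults: LFP band 1-300 Hz, common rate 1,250 Hz, Welch windows of 6 s
    (Hann, 50% overlap), six canonical bands, outlier z threshold 2.5 within
    20-electrode windows, 8-electrode spatial smoothing, PCA at 95%
    cumulative explained variance, 3-12 clusters, atlas search of +/-8
    coronal slices and +/-600 um in ML/DV.
    """

    lfp_band_hz: tuple[float, float] = (1.0, 300.0)
    fs_target_hz: float = 1250.0
    welch_window_s: float = 6.0
    welch_overlap: float = 0.5
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    z_threshold: float = 2.5
    outlier_window_n: int = 20
    smooth_window_n: int = 8
    pca_var: float = 0.95
    k_range: tuple[int, int] = (3, 12)
    ap_search_slices: int = 8
    mldv_search_um: float = 600.0
    car_enabled: bool = False
    random_state: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lfp_band_hz
        if not 0 < lo < hi:
            raise ValueError("LFP band edges must be strictly increasing and positive")
        for name, (a, b) in self.bands.items():
            if not a < b:
                raise ValueError(f"band {name!r} edges must be strictly increasing")
        for attr in ("fs_target_hz", "welch_window_s", "z_threshold", "mldv_search_um"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if self.outlier_window_n < 2 or self.smooth_window_n < 1:
            raise ValueError("window sizes must be positive")
        if self.k_range[0] < 2 or self.k_range[0] > self.k_range[1]:
            raise ValueError("k_range must satisfy 2 <= kmin <= kmax")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["lfp_band_hz"] = list(self.lfp_band_hz)
        d["k_range"] = list(self.k_range)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "lfp_band_hz" in d:
            d["lfp_band_hz"] = tuple(d["lfp_band_hz"])
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        return cls(**d)


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_recording(
    rec: Recording,
    path,
    dtype: str = "int16",
    gain_uV_per_bit: float = 0.195,
) -> None:
    """Write a flat little-endian binary (channel-interleaved) plus JSON sidecar.

    Integer dtypes store rounded counts of ``data / gain``; float dtypes
    store microvolts directly (gain 1.0 recommended).
    """
    dt = np.dtype(dtype).newbyteorder("<")
    if np.issubdtype(dt, np.integer):
        counts = np.round(rec.data / gain_uV_per_bit)
        info = np.iinfo(dt)
        counts = np.clip(counts, info.min, info.max)
        raw = counts.astype(dt)
    else:
        raw = (rec.data / gain_uV_per_bit).astype(dt)
    raw.tofile(path)
    sidecar = {
        "fs_hz": rec.fs_hz,
        "n_channels": rec.n_channels,
        "dtype": dtype,
        "gain_uV_per_bit": gain_uV_per_bit,
        "channel_ids": [int(c) for c in rec.channel_ids],
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh)


def read_recording(path, sidecar=None, layout=None) -> Recording:
    """Read a flat binary recording; returns data in microvolts.

    ``sidecar`` may be a path or a pre-parsed dict; defaults to
    ``<path>.json``.  If ``layout`` is given, channel ids are checked
    against the layout's electrode ids.
    """
    if sidecar is None:
        sidecar = _sidecar_path(path)
    if not isinstance(sidecar, dict):
        with open(sidecar) as fh:
            sidecar = json.load(fh)
    for key in ("fs_hz", "n_channels", "dtype", "gain_uV_per_bit"):
        if key not in sidecar:
            raise ValueError(f"sidecar missing required field {key!r}")
    n_channels = int(sidecar["n_channels"])
    dt = np.dtype(sidecar["dtype"]).newbyteorder("<")
    nbytes = Path(path).stat().st_size
    frame = n_channels * dt.itemsize
    if nbytes % frame:
        raise ValueError(
            f"truncated recording: {nbytes} bytes is not a multiple of "
            f"{n_channels} channels x {dt.itemsize} bytes"
        )
    raw = np.fromfile(path, dtype=dt).reshape(-1, n_channels)
    channel_ids = np.asarray(sidecar.get("channel_ids", np.arange(n_channels)))
    if layout is not None:
        missing = np.setdiff1d(channel_ids, np.asarray(layout.electrode_id))
        if missing.size:
            raise ValueError(f"channel ids {missing.tolist()} absent from layout")
        if n_channels != layout.n_electrodes:
            raise ValueError("channel count does not match probe layout")
    data = raw.astype(np.float64) * float(sidecar["gain_uV_per_bit"])
    return Recording(data=data, fs_hz=float(sidecar["fs_hz"]), channel_ids=channel_ids)


def bandpass_lfp(rec: Recording, band: tuple[float, float] = (1.0, 300.0)) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass (applied forward-backward)."""
    lo, hi = band
    if not 0 < lo < hi < rec.fs_hz / 2:
        raise ValueError(f"band {band} infeasible at fs={rec.fs_hz}")
    sos = signal.butter(4, band, btype="bandpass", fs=rec.fs_hz, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=0)
    return Recording(data=out, fs_hz=rec.fs_hz, channel_ids=rec.channel_ids)


def resample_lfp(rec: Recording, fs_target: float) -> Recording:
    """Polyphase anti-aliased downsampling to ``fs_target``.

    Output length is ``floor(n_in * fs_target / fs_in)``; requesting a rate
    above the input rate is an error, an equal rate is the identity.
    """
    if fs_target > rec.fs_hz:
        raise ValueError("upsampling is not supported")
    if fs_target == rec.fs_hz:
        return rec
    frac = Fraction(fs_target / rec.fs_hz).limit_denominator(10000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=0)
    n_out = int(rec.n_samples * fs_target / rec.fs_hz)
    out = out[:n_out]
    return Recording(data=out, fs_hz=float(fs_target), channel_ids=rec.channel_ids)


def apply_car(rec: Recording) -> Recording:
    """Common average reference: subtract the across-channel mean per sample."""
    if rec.n_channels < 2:
        raise ValueError("CAR requires at least 2 channels")
    out = rec.data - rec.data.mean(axis=1, keepdims=True)
    return Recording(data=out, fs_hz=rec.fs_hz, channel_ids=rec.channel_ids)


def subset_recording(rec: Recording, channel_ids) -> Recording:
    """Restrict a recording to the given channel ids (layout order preserved)."""
    wanted = np.asarray(channel_ids)
    pos = {int(c): i for i, c in enumerate(rec.channel_ids)}
    try:
        cols = [pos[int(c)] for c in wanted]
    except KeyError as exc:
        raise ValueError(f"channel id {exc.args[0]} not in recording") from exc
    return Recording(data=rec.data[:, cols], fs_hz=rec.fs_hz, channel_ids=wanted)


def preprocess(rec: Recording, cfg: PipelineConfig) -> Recording:
    """Band-pass, resample to the common rate, and optionally CAR."""
    out = bandpass_lfp(rec, cfg.lfp_band_hz)
    if cfg.fs_target_hz < out.fs_hz:
        out = resample_lfp(out, cfg.fs_target_hz)
    if cfg.car_enabled:
        out = apply_car(out)
    return out
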