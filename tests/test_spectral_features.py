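"""Welch spectra, normalized band powers, local outlier removal, smoothing."""

import numpy as np
import pytest

from bandloc.probe_geometry import build_layout, depth_ordering
from bandloc.signal_io import PipelineConfig, Recording
from bandloc.spectral_features import (
    BandPowerMatrix,
    band_power_frame,
    band_powers,
    remove_local_outliers,
    smooth_features,
    welch_psd,
    welch_window_length,
)


def _bp(values, layout, excluded=None):
    values = np.asarray(values, dtype=float)
    cfg = PipelineConfig()
    return BandPowerMatrix(
        values=values,
        band_names=list(cfg.bands),
        band_edges=np.asarray(list(cfg.bands.values())),
        electrode_ids=np.asarray(layout.electrode_id),
        excluded=np.zeros(values.shape[0], bool) if excluded is None else np.asarray(excluded),
    )


class TestWelch:
    def test_window_length_selection(self):
        assert welch_window_length(1250.0, 6.0) == 8192

    def test_white_noise_parseval(self, cfg):
        rng = np.random.default_rng(0)
        rec = Recording(rng.normal(size=(200_000, 1)), 1250.0, [0])
        psd = welch_psd(rec, cfg)
        integral = np.trapezoid(psd.psd[0], psd.freqs_hz)
        assert integral == pytest.approx(1.0, rel=0.05)

    def test_sinusoid_power(self, cfg):
        amp = 3.0
        t = np.arange(100_000) / 1250.0
        rec = Recording((amp * np.sin(2 * np.pi * 10 * t))[:, None], 1250.0, [0])
        psd = welch_psd(rec, cfg)
        near = (psd.freqs_hz >= 9) & (psd.freqs_hz <= 11)
        power = np.trapezoid(psd.psd[0, near], psd.freqs_hz[near])
        assert power == pytest.approx(amp**2 / 2, rel=0.05)

    def test_too_short_recording(self, cfg):
        rec = Recording(np.zeros((1000, 1)), 1250.0, [0])
        with pytest.raises(ValueError, match="shorter than one Welch window"):
            welch_psd(rec, cfg)


class TestBandPowers:
    def test_flat_psd_fractions(self, cfg):
        freqs = np.linspace(0, 625, 4097)
        psd = welch_psd(
            Recording(np.random.default_rng(1).normal(size=(9000, 1)), 1250.0, [0]), cfg
        )
        psd.psd = np.ones((1, psd.freqs_hz.size))
        bp = band_powers(psd, cfg)
        by_name = dict(zip(bp.band_names, bp.values[0]))
        assert by_name["delta"] == pytest.approx(3 / 299, rel=1e-9)
        assert by_name["gamma"] == pytest.approx(70 / 299, rel=1e-9)
        assert by_name["ripple"] == pytest.approx(150 / 299, rel=1e-9)

    def test_pure_tone_lands_in_its_band(self, cfg):
        t = np.arange(60_000) / 1250.0
        rng = np.random.default_rng(2)
        data = 10 * np.sin(2 * np.pi * 6 * t) + 0.05 * rng.normal(size=t.size)
        bp = band_powers(welch_psd(Recording(data[:, None], 1250.0, [0]), cfg), cfg)
        by_name = dict(zip(bp.band_names, bp.values[0]))
        assert by_name["theta"] > 0.9
        assert all(v < 0.05 for k, v in by_name.items() if k != "theta")

    def test_dead_channel_marked_excluded(self, cfg):
        rng = np.random.default_rng(3)
        data = np.column_stack([rng.normal(size=9000), np.zeros(9000)])
        bp = band_powers(welch_psd(Recording(data, 1250.0, [0, 1]), cfg), cfg)
        assert not bp.excluded[0]
        assert bp.excluded[1]
        assert np.all(bp.values[1] == 0)

    def test_normalization_bounds(self, cfg, mini_sim):
        bp = band_powers(welch_psd(mini_sim["recording"], cfg), cfg)
        ok = ~bp.excluded
        assert np.all(bp.values[ok] >= 0)
        assert np.all(bp.values[ok] <= 1)
        assert np.all(bp.values[ok].sum(axis=1) <= 1 + 1e-6)


def brute_force_outliers(values, ordered_rows, window, threshold):
    """Independent oracle: plain-python tiling + z-scores."""
    flagged = set()
    n = len(ordered_rows)
    n_full = max(1, n // window) if n else 0
    bounds = [i * window for i in range(n_full)] + [n]
    for t in range(len(bounds) - 1):
        members = ordered_rows[bounds[t]:bounds[t + 1]]
        if len(members) < 2:
            continue
        vals = values[members]
        for b in range(vals.shape[1]):
            col = vals[:, b]
            std = col.std(ddof=1)
            if std == 0:
                continue
            for i, m in enumerate(members):
                if abs(col[i] - col.mean()) / std > threshold:
                    flagged.add(m)
    return flagged


class TestOutlierRemoval:
    def test_constant_window_no_exclusions(self, mini_layout, cfg):
        bp = _bp(np.full((64, 6), 0.1), mini_layout)
        out = remove_local_outliers(bp, mini_layout, cfg)
        assert not out.excluded.any()

    def test_single_deviant_excluded(self, mini_layout, cfg):
        values = np.full((64, 6), 0.1)
        values[10, 2] = 10.0  # |z| ~ 4.2 in its 20-electrode window
        out = remove_local_outliers(_bp(values, mini_layout), mini_layout, cfg)
        assert out.excluded[10]
        assert out.excluded.sum() == 1
        # values retained for audit
        assert out.values[10, 2] == 10.0

    @pytest.mark.parametrize("z_target, flagged", [(2.4995, False), (2.5005, True)])
    def test_threshold_is_strict(self, cfg, z_target, flagged):
        """Exclusion requires |z| strictly greater than 2.5: a value whose
        z-score sits just below the threshold is retained, just above is
        excluded."""
        layout20 = build_layout(
            dict(n_shanks=1, n_columns=1, n_rows=20,
                 vertical_pitch_um=30, horizontal_pitch_um=27, shank_pitch_um=0)
        )
        # window [a, -a, b, -b, 0...] has z(a) = a / sqrt((2a^2 + 2b^2)/19);
        # solving for b places the extreme value exactly at z_target
        a = 1.0
        b = a * np.sqrt((19 / z_target**2 - 2) / 2)
        base = np.zeros(20)
        base[:4] = [a, -a, b, -b]
        values = np.tile(base[:, None], (1, 6))
        z_realized = np.abs(base - base.mean()).max() / base.std(ddof=1)
        assert z_realized == pytest.approx(z_target, abs=1e-9)
        out = remove_local_outliers(_bp(values, layout20), layout20, cfg)
        assert bool(out.excluded[:2].any()) is flagged

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, mini_layout, cfg, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 0.2, size=(64, 6))
        spikes = rng.choice(64, size=4, replace=False)
        values[spikes] += rng.uniform(0.5, 2.0, size=(4, 6))
        bp = _bp(values, mini_layout)
        out = remove_local_outliers(bp, mini_layout, cfg)
        id_to_row = {int(e): i for i, e in enumerate(bp.electrode_ids)}
        ordered = [id_to_row[int(e)] for e in depth_ordering(mini_layout, 0)]
        expected = brute_force_outliers(values, ordered, cfg.outlier_window_n, cfg.z_threshold)
        assert set(np.flatnonzero(out.excluded)) == expected


def brute_force_smooth(values, ordered_rows, retained, window):
    """Independent oracle: centered moving average over retained electrodes."""
    n = len(ordered_rows)
    out = values.copy()
    for i in range(n):
        lo = max(0, i - window // 2)
        hi = min(n, i + window - window // 2)
        sel = [ordered_rows[j] for j in range(lo, hi) if retained[ordered_rows[j]]]
        if sel:
            out[ordered_rows[i]] = values[sel].mean(axis=0)
    return out


class TestSmoothing:
    def test_constant_profile_unchanged(self, mini_layout, cfg):
        bp = _bp(np.full((64, 6), 0.3), mini_layout)
        out = smooth_features(bp, mini_layout, cfg)
        np.testing.assert_allclose(out.values, 0.3)
        assert out.smoothed

    def test_step_becomes_ramp(self, mini_layout, cfg):
        values = np.zeros((64, 6))
        order = depth_ordering(mini_layout, 0)
        id_to_row = {int(e): i for i, e in enumerate(mini_layout.electrode_id)}
        rows = [id_to_row[int(e)] for e in order]
        values[rows[32:]] = 1.0  # unit step at mid-shank
        out = smooth_features(_bp(values, mini_layout), mini_layout, cfg)
        profile = out.values[rows, 0]
        ramp = np.flatnonzero((profile > 0) & (profile < 1))
        assert ramp.size == cfg.smooth_window_n - 1  # transition spans the window
        assert np.all(np.diff(profile) >= 0)

    def test_excluded_imputed_to_local_value(self, mini_layout, cfg):
        values = np.full((64, 6), 0.4)
        values[20] = 99.0
        excluded = np.zeros(64, bool)
        excluded[20] = True
        out = smooth_features(_bp(values, mini_layout, excluded), mini_layout, cfg)
        assert out.values[20, 0] == pytest.approx(0.4)
        assert out.excluded[20]  # mask preserved

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, mini_layout, cfg, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(size=(64, 6))
        excluded = rng.random(64) < 0.15
        bp = _bp(values, mini_layout, excluded)
        out = smooth_features(bp, mini_layout, cfg)
        id_to_row = {int(e): i for i, e in enumerate(bp.electrode_ids)}
        rows = [id_to_row[int(e)] for e in depth_ordering(mini_layout, 0)]
        expected = brute_force_smooth(values, rows, ~excluded, cfg.smooth_window_n)
        np.testing.assert_allclose(out.values, expected)

    def test_interior_mean_preserved(self, mini_layout, cfg):
        rng = np.random.default_rng(5)
        values = rng.uniform(0.2, 0.8, size=(64, 6))
        out = smooth_features(_bp(values, mini_layout), mini_layout, cfg)
        interior = slice(8, 56)
        before = values[interior].mean()
        after = out.values[interior].mean()
        assert after == pytest.approx(before, rel=0.01)


def test_band_power_frame_export(mini_layout, cfg):
    bp = _bp(np.random.default_rng(0).uniform(size=(64, 6)), mini_layout)
    frame = band_power_frame(bp, mini_layout)
    assert list(frame.columns) == (
        ["electrode_id", "shank", "z_um"] + list(cfg.bands) + ["excluded"]
    )
    assert len(frame) == 64
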