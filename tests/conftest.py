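"""Shared fixtures: probe layouts, toy atlases, and seeded synthetic recordings.

Heavier simulation bundles are session-scoped so several test modules can
share one simulation instead of regenerating it.
"""

from __future__ import annotations

import pytest

from bandloc.atlas import build_toy_atlas
from bandloc.placement import StereoCoords
from bandloc.probe_geometry import build_layout
from bandloc.signal_io import PipelineConfig
from bandloc.synthetic import default_profiles, simulate_recording

#: Frozen recovery fixture: boundary tilts (AP, ML slopes, um/mm) give the
#: three boundaries crossed by the probe linearly independent orientations,
#: which is what makes the injected stereotactic offset identifiable.
RECOVERY_TILT = [[0, 0], [500, 250], [-450, 900], [300, 150]]
RECOVERY_LAYERS = [("upper", 600.0), ("middle", 600.0), ("deep", 1200.0)]
RECOVERY_TRUTH = StereoCoords(0.1, -0.465, -2.22)


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def single_shank():
    return build_layout("sinaps_single_256")


@pytest.fixture(scope="session")
def eight_shank():
    return build_layout("sinaps_eight_1024")


@pytest.fixture(scope="session")
def mini_layout():
    """Small single-shank layout (1 shank x 2 columns x 32 rows, 64 electrodes)."""
    return build_layout(
        dict(
            name="mini_64",
            n_shanks=1,
            n_columns=2,
            n_rows=32,
            vertical_pitch_um=30.0,
            horizontal_pitch_um=27.0,
            shank_pitch_um=0.0,
        )
    )


@pytest.fixture(scope="session")
def layered_atlas():
    """Flat three-layer toy brain (600 um layers, 50 um voxels)."""
    return build_toy_atlas([("a", 600.0), ("b", 600.0), ("c", 600.0)])


@pytest.fixture(scope="session")
def recovery_layout():
    """4-shank x 2-column x 80-row probe straddling the midline (640 electrodes)."""
    return build_layout(
        dict(
            name="quad_640",
            n_shanks=4,
            n_columns=2,
            n_rows=80,
            vertical_pitch_um=30.0,
            horizontal_pitch_um=27.0,
            shank_pitch_um=300.0,
        )
    )


@pytest.fixture(scope="session")
def recovery_atlas():
    return build_toy_atlas(RECOVERY_LAYERS, boundary_tilt_um_per_mm=RECOVERY_TILT)


@pytest.fixture(scope="session")
def mini_sim(mini_layout, layered_atlas):
    """30 s recording on the 64-electrode shank through three flat layers."""
    profiles = default_profiles(3, seed=7)
    truth = StereoCoords(0.1, 0.3, -2.0)
    rec, regions = simulate_recording(
        layered_atlas, mini_layout, truth, profiles, duration_s=30.0, seed=7
    )
    return {
        "recording": rec,
        "regions": regions,
        "layout": mini_layout,
        "atlas": layered_atlas,
        "truth": truth,
        "profiles": profiles,
    }


@pytest.fixture(scope="session")
def e2e_sim(single_shank):
    """60 s recording on the 256-electrode shank through three 1.3 mm layers."""
    atlas = build_toy_atlas([("l1", 1300.0), ("l2", 1300.0), ("l3", 1300.0)])
    profiles = default_profiles(3, seed=1)
    truth = StereoCoords(-2.0, 0.3, -4.2)
    rec, regions = simulate_recording(
        atlas, single_shank, truth, profiles, duration_s=60.0, seed=1
    )
    return {
        "recording": rec,
        "regions": regions,
        "layout": single_shank,
        "atlas": atlas,
        "truth": truth,
        "profiles": profiles,
    }
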