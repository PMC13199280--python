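"""Probe electrode layouts and geometric helpers.

A layout describes every electrode by shank / column / row index and by its
physical position: ``x_um`` runs laterally across columns and shanks, and
``z_um`` runs along the shank with 0 at the tip, increasing toward the probe
base.  Three named fixtures cover the high-density devices the pipeline is
designed around (single- and eight-shank 256/1,024-channel CMOS probes with
a two-column, 30 x 27 um grid per shank, and a four-shank probe with one
retained column per shank at 15 um vertical pitch).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ProbeLayout",
    "build_layout",
    "decimate_layout",
    "depth_ordering",
    "window_vertical_span",
    "write_layout_json",
    "read_layout_json",
    "FIXTURES",
]

SUPPORTED_DECIMATION_FACTORS = (1, 2, 4, 8, 16, 32)

#: Named device fixtures: (n_shanks, n_columns, n_rows, vertical, horizontal, shank pitch), um.
FIXTURES: Mapping[str, tuple[int, int, int, float, float, float]] = {
    "sinaps_single_256": (1, 2, 128, 30.0, 27.0, 0.0),
    "sinaps_eight_1024": (8, 2, 64, 30.0, 27.0, 300.0),
    "np2_four_384_single_column": (4, 1, 96, 15.0, 32.0, 250.0),
}


@dataclass(frozen=True)
class ProbeLayout:
    """Electrode geometry of a multi-shank probe.

    Electrodes are stored shank-major and, within a shank, in depth order
    from the tip (increasing ``z_um``; ties between columns of the same row
    broken by increasing column index).
    """

    name: str
    electrode_id: np.ndarray
    shank_index: np.ndarray
    column_index: np.ndarray
    row_index: np.ndarray
    x_um: np.ndarray
    z_um: np.ndarray
    vertical_pitch_um: float
    horizontal_pitch_um: float
    shank_pitch_um: float
    n_shanks: int
    n_columns_per_shank: int

    def __post_init__(self) -> None:
        ids = np.asarray(self.electrode_id)
        if len(np.unique(ids)) != ids.size:
            raise ValueError("electrode_id values must be unique")
        if self.vertical_pitch_um <= 0:
            raise ValueError("vertical pitch must be positive")
        if self.n_columns_per_shank > 1 and self.horizontal_pitch_um <= 0:
            raise ValueError("horizontal pitch must be positive for multi-column shanks")
        if self.n_shanks > 1 and self.shank_pitch_um <= 0:
            raise ValueError("shank pitch must be positive for multi-shank probes")

    @property
    def n_electrodes(self) -> int:
        return int(np.asarray(self.electrode_id).size)

    def shank_electrodes(self, shank: int) -> np.ndarray:
        """Row indices (into the layout arrays) of a shank, in stored order."""
        if shank not in np.asarray(self.shank_index):
            raise IndexError(f"shank {shank} not present in layout {self.name!r}")
        return np.flatnonzero(np.asarray(self.shank_index) == shank)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeLayout):
            return NotImplemented
        scalars = (
            self.name == other.name
            and self.vertical_pitch_um == other.vertical_pitch_um
            and self.horizontal_pitch_um == other.horizontal_pitch_um
            and self.shank_pitch_um == other.shank_pitch_um
            and self.n_shanks == other.n_shanks
            and self.n_columns_per_shank == other.n_columns_per_shank
        )
        if not scalars:
            return False
        for attr in ("electrode_id", "shank_index", "column_index", "row_index", "x_um", "z_um"):
            if not np.array_equal(getattr(self, attr), getattr(other, attr)):
                return False
        return True


def _grid_layout(
    name: str,
    n_shanks: int,
    n_columns: int,
    n_rows: int,
    vertical_pitch_um: float,
    horizontal_pitch_um: float,
    shank_pitch_um: float,
) -> ProbeLayout:
    shank, row, col = np.meshgrid(
        np.arange(n_shanks), np.arange(n_rows), np.arange(n_columns), indexing="ij"
    )
    shank = shank.ravel()
    row = row.ravel()
    col = col.ravel()
    return ProbeLayout(
        name=name,
        electrode_id=np.arange(shank.size),
        shank_index=shank,
        column_index=col,
        row_index=row,
        x_um=shank * shank_pitch_um + col * horizontal_pitch_um,
        z_um=row * float(vertical_pitch_um),
        vertical_pitch_um=float(vertical_pitch_um),
        horizontal_pitch_um=float(horizontal_pitch_um),
        shank_pitch_um=float(shank_pitch_um),
        n_shanks=n_shanks,
        n_columns_per_shank=n_columns,
    )


def build_layout(spec_name: str | Mapping) -> ProbeLayout:
    """Build a :class:`ProbeLayout` from a fixture name or a geometry record.

    A geometry record is a mapping with keys ``name``, ``n_shanks``,
    ``n_columns``, ``n_rows`` (or an explicit ``electrodes`` table),
    ``vertical_pitch_um``, ``horizontal_pitch_um``, ``shank_pitch_um``.
    """
    if isinstance(spec_name, str):
        if spec_name not in FIXTURES:
            raise ValueError(
                f"unknown probe fixture {spec_name!r}; known: {sorted(FIXTURES)}"
            )
        return _grid_layout(spec_name, *FIXTURES[spec_name])

    rec = dict(spec_name)
    if "electrodes" in rec:
        elec = rec["electrodes"]
        return ProbeLayout(
            name=rec.get("name", "custom"),
            electrode_id=np.asarray([e["id"] for e in elec], dtype=int),
            shank_index=np.asarray([e["shank"] for e in elec], dtype=int),
            column_index=np.asarray([e["column"] for e in elec], dtype=int),
            row_index=np.asarray([e["row"] for e in elec], dtype=int),
            x_um=np.asarray([e["x_um"] for e in elec], dtype=float),
            z_um=np.asarray([e["z_um"] for e in elec], dtype=float),
            vertical_pitch_um=float(rec["vertical_pitch_um"]),
            horizontal_pitch_um=float(rec["horizontal_pitch_um"]),
            shank_pitch_um=float(rec["shank_pitch_um"]),
            n_shanks=int(rec["n_shanks"]),
            n_columns_per_shank=int(rec["n_columns"]),
        )
    n_total = rec.get("n_electrodes")
    n_shanks = int(rec["n_shanks"])
    n_columns = int(rec["n_columns"])
    if "n_rows" in rec:
        n_rows = int(rec["n_rows"])
    else:
        if n_total is None:
            raise ValueError("geometry record needs n_rows or n_electrodes")
        if n_total % (n_shanks * n_columns):
            raise ValueError("electrode count not divisible by shanks x columns")
        n_rows = n_total // (n_shanks * n_columns)
    return _grid_layout(
        rec.get("name", "custom"),
        n_shanks,
        n_columns,
        n_rows,
        float(rec["vertical_pitch_um"]),
        float(rec["horizontal_pitch_um"]),
        float(rec.get("shank_pitch_um", 0.0)),
    )


def decimate_layout(layout: ProbeLayout, df: int) -> ProbeLayout:
    """Spatially subsample a layout by a decimation factor.

    ``df`` is the ratio of original to retained electrode density.  On a
    two-column shank, df=2 retains a single column at the original vertical
    pitch; df=4 additionally keeps one electrode every two rows (doubling
    the effective vertical pitch), and each further doubling of df doubles
    the row skipping again.
    """
    if df not in SUPPORTED_DECIMATION_FACTORS:
        raise ValueError(f"decimation factor {df} not in {SUPPORTED_DECIMATION_FACTORS}")
    if df == 1:
        return layout

    per_shank = layout.n_electrodes // layout.n_shanks
    if per_shank % df:
        raise ValueError(f"per-shank electrode count {per_shank} not divisible by df={df}")

    col = np.asarray(layout.column_index)
    row = np.asarray(layout.row_index)
    if layout.n_columns_per_shank == 2:
        row_step = df // 2
        keep = col == col.min()
        n_columns = 1
    elif layout.n_columns_per_shank == 1:
        row_step = df
        keep = np.ones(layout.n_electrodes, dtype=bool)
        n_columns = 1
    else:
        raise ValueError("decimation supports one- or two-column shanks only")
    if row_step > 1:
        keep &= row % row_step == 0
    else:
        row_step = 1

    idx = np.flatnonzero(keep)
    return ProbeLayout(
        name=f"{layout.name}_df{df}",
        electrode_id=np.asarray(layout.electrode_id)[idx],
        shank_index=np.asarray(layout.shank_index)[idx],
        column_index=np.zeros(idx.size, dtype=int),
        row_index=row[idx] // row_step,
        x_um=np.asarray(layout.x_um)[idx],
        z_um=np.asarray(layout.z_um)[idx],
        vertical_pitch_um=layout.vertical_pitch_um * row_step,
        horizontal_pitch_um=layout.horizontal_pitch_um,
        shank_pitch_um=layout.shank_pitch_um,
        n_shanks=layout.n_shanks,
        n_columns_per_shank=n_columns,
    )


def depth_ordering(layout: ProbeLayout, shank: int) -> np.ndarray:
    """Electrode ids of one shank ordered tip-to-base.

    Sorted by increasing ``z_um``; electrodes sharing a row (the two columns
    of a two-column shank) are interleaved, tie-broken by column index.
    The result is independent of the storage order of the input.
    """
    idx = layout.shank_electrodes(shank)
    order = np.lexsort(
        (np.asarray(layout.column_index)[idx], np.asarray(layout.z_um)[idx])
    )
    return np.asarray(layout.electrode_id)[idx[order]]


def depth_order_indices(layout: ProbeLayout, shank: int) -> np.ndarray:
    """Like :func:`depth_ordering` but returning row indices into the layout arrays."""
    idx = layout.shank_electrodes(shank)
    order = np.lexsort(
        (np.asarray(layout.column_index)[idx], np.asarray(layout.z_um)[idx])
    )
    return idx[order]


def window_vertical_span(layout: ProbeLayout, n_electrodes: int) -> float:
    """Vertical span (um) covered by ``n`` consecutive depth-ordered electrodes.

    With ``c`` columns per shank, ``n`` consecutive electrodes cover
    ``ceil(n / c)`` rows, i.e. a span of ``ceil(n / c) * vertical_pitch``.
    """
    if n_electrodes < 1:
        raise ValueError("n_electrodes must be >= 1")
    rows = math.ceil(n_electrodes / layout.n_columns_per_shank)
    return rows * layout.vertical_pitch_um


def write_layout_json(layout: ProbeLayout, path) -> None:
    record = {
        "name": layout.name,
        "n_shanks": layout.n_shanks,
        "n_columns": layout.n_columns_per_shank,
        "vertical_pitch_um": layout.vertical_pitch_um,
        "horizontal_pitch_um": layout.horizontal_pitch_um,
        "shank_pitch_um": layout.shank_pitch_um,
        "electrodes": [
            {
                "id": int(layout.electrode_id[i]),
                "shank": int(layout.shank_index[i]),
                "column": int(layout.column_index[i]),
                "row": int(layout.row_index[i]),
                "x_um": float(layout.x_um[i]),
                "z_um": float(layout.z_um[i]),
            }
            for i in range(layout.n_electrodes)
        ],
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1)


def read_layout_json(path) -> ProbeLayout:
    with open(path) as fh:
        return build_layout(json.load(fh))
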