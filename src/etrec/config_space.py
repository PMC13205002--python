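"""Candidate electrode geometries for the 3 x 2 fingertip stimulation array.

A candidate configuration is a pair (D, Q): disc diameter D and
edge-to-edge gap Q between adjacent discs, both in millimetres.  The
candidate space is the Cartesian product of six diameters (2.0-4.5 mm)
and six gaps (0.5-3.0 mm) on a 0.5 mm lattice, 36 configurations in
total, written ``DxQy`` (e.g. ``D3.5Q1``).

The array itself is 3 rows x 2 columns of circular electrodes on a
uniform grid with centre-to-centre pitch D + Q in both axes, centred on
the origin of the skin-surface plane.  The 3-electrode axis is y, the
2-electrode axis is x.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: Allowed disc diameters in mm, ascending.
DIAMETERS_MM: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5)
#: Allowed edge-to-edge gaps in mm, ascending.
SPACINGS_MM: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

N_ROWS = 3
N_COLS = 2


def _snap(value: float, allowed: tuple[float, ...], what: str) -> float:
    for a in allowed:
        if math.isclose(value, a, rel_tol=0.0, abs_tol=1e-9):
            return a
    raise ValueError(f"{what}={value} is not on the candidate lattice {allowed}")


@dataclass(frozen=True)
class ElectrodeConfig:
    """One diameter-gap candidate with the fixed 3 x 2 array shape."""

    diameter_mm: float
    spacing_mm: float
    rows: int = N_ROWS
    cols: int = N_COLS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "diameter_mm", _snap(self.diameter_mm, DIAMETERS_MM, "diameter_mm")
        )
        object.__setattr__(
            self, "spacing_mm", _snap(self.spacing_mm, SPACINGS_MM, "spacing_mm")
        )
        if (self.rows, self.cols) != (N_ROWS, N_COLS):
            raise ValueError("only the 3 x 2 array layout is supported")

    @property
    def pitch_mm(self) -> float:
        """Centre-to-centre pitch D + Q (mm), identical in both axes."""
        return self.diameter_mm + self.spacing_mm

    @property
    def label(self) -> str:
        return config_label(self)


@dataclass(frozen=True)
class ArrayLayout:
    """Planar disc-centre coordinates of a 3 x 2 array, in mm.

    ``centers`` is ordered row-major: row index runs along y from -pitch
    to +pitch, column index along x from -pitch/2 to +pitch/2, so index
    2 is the middle-row left electrode.
    """

    centers: tuple[tuple[float, float], ...]
    pitch_row_mm: float
    pitch_col_mm: float
    diameter_mm: float

    @property
    def centers_array(self) -> np.ndarray:
        return np.asarray(self.centers, dtype=float)

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


def _fmt(v: float) -> str:
    """Render 1.0 -> "1" and 3.5 -> "3.5" (the in-text label convention)."""
    return f"{v:g}"


def config_label(c: ElectrodeConfig) -> str:
    """Label a configuration as ``DxQy``, e.g. D3.5Q1."""
    return f"D{_fmt(c.diameter_mm)}Q{_fmt(c.spacing_mm)}"


_LABEL_RE = re.compile(r"^D(?P<d>\d+(?:\.\d+)?)Q(?P<q>\d+(?:\.\d+)?)$")


def parse_label(label: str) -> ElectrodeConfig:
    """Inverse of :func:`config_label`."""
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"not a DxQy configuration label: {label!r}")
    return ElectrodeConfig(float(m.group("d")), float(m.group("q")))


def enumerate_configs() -> list[ElectrodeConfig]:
    """All 36 candidates in deterministic order: D ascending, then Q ascending.

    This order is the tie-break order used everywhere downstream
    (training-sample layout, ranking ties), so it must never change.
    """
    return [ElectrodeConfig(d, q) for d in DIAMETERS_MM for q in SPACINGS_MM]


def bounding_area_cm2(c: ElectrodeConfig) -> float:
    """Coverage area of the array's bounding rectangle, in cm².

    Width (2-electrode axis) is 2D + Q and height (3-electrode axis) is
    3D + 2Q, so the area spans 0.315 cm² (D2Q0.5) to 2.34 cm² (D4.5Q3)
    over the candidate space.
    """
    d, q = c.diameter_mm, c.spacing_mm
    width_mm = 2.0 * d + q
    height_mm = 3.0 * d + 2.0 * q
    return width_mm * height_mm / 100.0


def electrode_centers(c: ElectrodeConfig) -> ArrayLayout:
    """Disc centres of the 3 x 2 array, centred at the origin."""
    p = c.pitch_mm
    xs = (-p / 2.0, p / 2.0)
    ys = (-p, 0.0, p)
    centers = tuple((x, y) for y in ys for x in xs)
    return ArrayLayout(
        centers=centers, pitch_row_mm=p, pitch_col_mm=p, diameter_mm=c.diameter_mm
    )


def configs_to_rows(configs: Iterable[ElectrodeConfig]) -> list[dict]:
    """Tabular view (label, D, Q, area) used by the CLI and file outputs."""
    return [
        {
            "label": cfg.label,
            "diameter_mm": cfg.diameter_mm,
            "spacing_mm": cfg.spacing_mm,
            "area_cm2": bounding_area_cm2(cfg),
        }
        for cfg in configs
    ]
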