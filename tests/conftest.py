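"""Shared test helpers: tiny synthetic inputs built at test time."""

from __future__ import annotations

import numpy as np

from urbanvar.types import Habitat, NestBox

M_PER_DEG_LAT = 111_194.9


def box_at(box_id: str, dx_m: float, dy_m: float, habitat=Habitat.FOREST,
           system_id: str = "S", lon0: float = 5.0, lat0: float = 48.0) -> NestBox:
    """A nest box offset (dx, dy) metres east/north of a reference point."""
    lat = lat0 + dy_m / M_PER_DEG_LAT
    lon = lon0 + dx_m / (M_PER_DEG_LAT * np.cos(np.radians(lat0)))
    return NestBox(box_id, system_id, lon, lat, habitat)
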