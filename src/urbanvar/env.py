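"""Continuous urbanisation covariates from raster grids.

Urbanisation is quantified as the proportion of impervious surface area (ISA)
within 100 m and 1000 m buffers of a cluster's centroid, and landscape
heterogeneity as the Shannon diversity of land-cover classes within the
1000 m buffer. Rasters are small in-memory grids (optionally round-tripped
through a plain-text format with a three-line header), standing in for
continent-scale imperviousness / land-cover products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .clustering import Cluster, local_xy_m
from .types import NestBox

__all__ = [
    "ToyRaster",
    "isa_proportion",
    "shannon_diversity",
    "attach_env",
]


@dataclass
class ToyRaster:
    """Rectangular grid anchored at a lon/lat origin (lower-left corner).

    ``values[i, j]`` is the cell in row i (south to north) and column j
    (west to east); cell centres sit at offsets ((j+0.5)*cell, (i+0.5)*cell)
    metres east/north of the origin. Values are ISA fractions in [0, 1] or
    integer land-cover class codes.
    """

    origin_lon: float
    origin_lat: float
    cell_size_m: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D grid")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be > 0")

    def cell_centres_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinates in metres east/north of the origin."""
        ny, nx = self.values.shape
        cx = (np.arange(nx) + 0.5) * self.cell_size_m
        cy = (np.arange(ny) + 0.5) * self.cell_size_m
        return np.meshgrid(cx, cy)

    def write_text(self, path: str | Path) -> None:
        header = f"origin_lon {self.origin_lon!r}\norigin_lat {self.origin_lat!r}\ncell_size_m {self.cell_size_m!r}\n"
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.8g")

    @classmethod
    def read_text(cls, path: str | Path) -> "ToyRaster":
        with open(path) as fh:
            hdr = {}
            for _ in range(3):
                key, val = fh.readline().split()
                hdr[key] = float(val)
            values = np.loadtxt(fh, ndmin=2)
        return cls(hdr["origin_lon"], hdr["origin_lat"], hdr["cell_size_m"], values)


def _cells_in_buffer(raster: ToyRaster, centre_lon: float, centre_lat: float, radius_m: float):
    """Boolean mask of cells whose centres fall within radius_m of the centre."""
    x0, y0 = local_xy_m(
        np.array([centre_lon]), np.array([centre_lat]), raster.origin_lon, raster.origin_lat
    )
    gx, gy = raster.cell_centres_xy()
    return (gx - x0[0]) ** 2 + (gy - y0[0]) ** 2 <= radius_m**2


def isa_proportion(
    raster: ToyRaster, centre_lon: float, centre_lat: float, radius_m: float
) -> float:
    """Mean ISA fraction of raster cells with centres inside the buffer."""
    mask = _cells_in_buffer(raster, centre_lon, centre_lat, radius_m)
    if not mask.any():
        raise ValueError(
            f"no raster cell centre within {radius_m} m of ({centre_lon}, {centre_lat}); "
            "use a larger radius or finer raster"
        )
    return float(np.mean(raster.values[mask]))


def shannon_diversity(class_counts: Mapping) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over land-cover classes."""
    counts = np.array([float(v) for v in class_counts.values()])
    if (counts < 0).any():
        raise ValueError("negative class count")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total class count must be > 0")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def landcover_shannon(
    raster: ToyRaster, centre_lon: float, centre_lat: float, radius_m: float = 1000.0
) -> float:
    """Shannon diversity of land-cover classes within the buffer."""
    mask = _cells_in_buffer(raster, centre_lon, centre_lat, radius_m)
    if not mask.any():
        raise ValueError("no land-cover cell centre inside buffer")
    classes, counts = np.unique(raster.values[mask].astype(int), return_counts=True)
    return shannon_diversity(dict(zip(classes.tolist(), counts.tolist())))


def cluster_centroid(cluster: Cluster, boxes_by_id: Mapping[str, NestBox]) -> tuple[float, float]:
    lons = [boxes_by_id[b].lon for b in cluster.member_boxes]
    lats = [boxes_by_id[b].lat for b in cluster.member_boxes]
    return float(np.mean(lons)), float(np.mean(lats))


def attach_env(
    clusters: list[Cluster],
    boxes: list[NestBox],
    isa_raster: ToyRaster,
    landcover_raster: ToyRaster,
) -> list[Cluster]:
    """Fill every cluster's EnvMetrics from the rasters (in place).

    Buffers are taken around the centroid of the member boxes: 100 m and
    1000 m for ISA, 1000 m for land-cover heterogeneity.
    """
    boxes_by_id = {b.box_id: b for b in boxes}
    for c in clusters:
        lon, lat = cluster_centroid(c, boxes_by_id)
        c.env.isa_100 = isa_proportion(isa_raster, lon, lat, 100.0)
        c.env.isa_1000 = isa_proportion(isa_raster, lon, lat, 1000.0)
        c.env.shannon_h = landcover_shannon(landcover_raster, lon, lat, 1000.0)
        if not math.isfinite(c.env.shannon_h):
            raise ValueError(f"non-finite shannon_h for cluster {c.cluster_id}")
    return clusters
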