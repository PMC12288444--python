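"""Grouping nest boxes into clusters (subpopulations).

A cluster is a connected component of the graph joining boxes at great-circle
distance <= 300 m (single linkage), kept only if it has at least 5 members.
This standardises the definition of a subpopulation across study systems
whose owner-defined plots differ wildly in shape and size. Cluster habitat is
the majority of the members' owner-assigned labels; geometry covariates
(area, mean latitude) come from the member coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import MultiPoint

from .types import Habitat, NestBox

logger = logging.getLogger("urbanvar")

__all__ = [
    "EnvMetrics",
    "Cluster",
    "haversine_m",
    "build_clusters",
    "assign_habitat",
    "cluster_geometry",
    "local_xy_m",
]

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius


@dataclass
class EnvMetrics:
    """Continuous urbanisation and heterogeneity covariates for one cluster."""

    isa_100: float = float("nan")
    isa_1000: float = float("nan")
    shannon_h: float = float("nan")


@dataclass
class Cluster:
    cluster_id: str
    system_id: str
    member_boxes: list[str]
    habitat: Habitat
    area_km2: float = float("nan")
    mean_lat: float = float("nan")
    years_studied: int = 0
    env: EnvMetrics = field(default_factory=EnvMetrics)
    mixed_fraction: float = 0.0

    @property
    def size(self) -> int:
        return len(self.member_boxes)


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres between points in degrees (vectorised)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def local_xy_m(lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float):
    """Project lon/lat to local metric x/y (equirectangular about lon0/lat0).

    Adequate for the few-km extents of nest-box clusters.
    """
    x = np.radians(np.asarray(lon) - lon0) * EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = np.radians(np.asarray(lat) - lat0) * EARTH_RADIUS_M
    return x, y


def assign_habitat(member_labels: list[Habitat], cluster_id: str = "?") -> tuple[Habitat, float]:
    """Majority habitat of a cluster's members.

    Returns (habitat, minority fraction). An exact tie raises: the habitat
    must then be assigned manually in configuration.
    """
    n_urban = sum(1 for h in member_labels if h is Habitat.URBAN)
    n_forest = len(member_labels) - n_urban
    if n_urban == n_forest:
        raise ValueError(
            f"cluster {cluster_id}: exact urban/forest tie ({n_urban}:{n_forest}); "
            "assign habitat manually in config"
        )
    habitat = Habitat.URBAN if n_urban > n_forest else Habitat.FOREST
    minority = min(n_urban, n_forest) / len(member_labels)
    if minority > 0:
        logger.warning(
            "cluster %s is habitat-mixed: %.0f%% minority labels", cluster_id, 100 * minority
        )
    return habitat, minority


def cluster_geometry(
    boxes: list[NestBox], buffer_m: float = 150.0
) -> tuple[float, float]:
    """Cluster area (km^2) and mean latitude from member coordinates.

    Area = convex hull of the member points buffered by ``buffer_m``, in a
    local metric projection. The buffer guarantees positive area even for
    coincident or collinear boxes.
    """
    lon = np.array([b.lon for b in boxes])
    lat = np.array([b.lat for b in boxes])
    lon0, lat0 = float(lon.mean()), float(lat.mean())
    x, y = local_xy_m(lon, lat, lon0, lat0)
    hull = MultiPoint(list(zip(x, y))).convex_hull
    area_km2 = hull.buffer(buffer_m, quad_segs=64).area / 1e6
    return float(area_km2), float(lat.mean())


def build_clusters(
    boxes: list[NestBox],
    max_link_m: float = 300.0,
    min_size: int = 5,
    buffer_m: float = 150.0,
) -> tuple[list[Cluster], list[NestBox]]:
    """Single-linkage clustering of one study system's nest boxes.

    Returns (clusters, unassigned boxes). Output is independent of the input
    ordering: members are sorted and cluster ids are derived from the
    smallest member box_id.
    """
    if not boxes:
        return [], []
    ids = [b.box_id for b in boxes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate box_id in input")
    systems = {b.system_id for b in boxes}
    if len(systems) != 1:
        raise ValueError(f"build_clusters expects one study system, got {sorted(systems)}")
    system_id = systems.pop()

    order = np.argsort(np.array(ids, dtype=object))
    boxes = [boxes[i] for i in order]
    n = len(boxes)
    lon = np.array([b.lon for b in boxes])
    lat = np.array([b.lat for b in boxes])
    d = haversine_m(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    adj = csr_matrix(d <= max_link_m)
    n_comp, labels = connected_components(adj, directed=False)

    clusters: list[Cluster] = []
    unassigned: list[NestBox] = []
    for comp in range(n_comp):
        members = [boxes[i] for i in np.flatnonzero(labels == comp)]
        if len(members) < min_size:
            unassigned.extend(members)
            continue
        cid = f"{system_id}:{members[0].box_id}"
        habitat, minority = assign_habitat([b.habitat_label for b in members], cid)
        area_km2, mean_lat = cluster_geometry(members, buffer_m=buffer_m)
        clusters.append(
            Cluster(
                cluster_id=cid,
                system_id=system_id,
                member_boxes=[b.box_id for b in members],
                habitat=habitat,
                area_km2=area_km2,
                mean_lat=mean_lat,
                mixed_fraction=minority,
            )
        )
    if not clusters:
        logger.warning("no cluster reached min_size=%d; all %d boxes unassigned", min_size, n)
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters, unassigned


def membership_map(clusters: list[Cluster]) -> dict[str, str]:
    """box_id -> cluster_id over a set of clusters."""
    out: dict[str, str] = {}
    for c in clusters:
        for b in c.member_boxes:
            if b in out:
                raise ValueError(f"box {b} assigned to two clusters")
            out[b] = c.cluster_id
    return out
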