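"""Model-ready design construction for the double-hierarchical model.

One species x trait dataset becomes a DHGLMData: a standardised response,
a mean-part design matrix X, a dispersion-part design matrix Z, and dense
grouping indices for year, study system and cluster, plus the cluster ->
habitat map used for habitat-specific among-cluster variances.

Trait-specific covariates (categorical urbanisation mode):

==============  =============================  ====================================
trait           mean part                      dispersion part
==============  =============================  ====================================
adult tarsus    habitat, latitude, sex         habitat, heterogeneity, latitude,
                                               area, years, sex
nestling tarsus habitat, latitude, chick age   habitat, heterogeneity, latitude,
                                               area, years
lay date        habitat, latitude              habitat, heterogeneity, latitude,
                                               area, years, female age
==============  =============================  ====================================

In the continuous (ISA) modes the categorical habitat column is replaced by
standardised impervious-surface proportions and a single among-cluster
variance is fitted in each part.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .clustering import Cluster, membership_map
from .preprocess import standardize
from .types import FemaleAge, Habitat, Sex, Trait, TraitObservation

logger = logging.getLogger("urbanvar")

__all__ = ["DHGLMData", "build_design"]


@dataclass
class DHGLMData:
    """Everything the sampler needs, in arrays."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    mean_names: list[str]
    disp_names: list[str]
    year_idx: np.ndarray
    sys_idx: np.ndarray
    clust_idx: np.ndarray
    cluster_habitat: np.ndarray  # (K_c,) 0=forest, 1=urban; all 0 when n_hab == 1
    n_hab: int
    year_levels: list = field(default_factory=list)
    sys_levels: list = field(default_factory=list)
    clust_levels: list = field(default_factory=list)
    y_mean: float = 0.0
    y_sd: float = 1.0
    habitat_term: str = "habitat_urban"

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_years(self) -> int:
        return len(self.year_levels)

    @property
    def n_systems(self) -> int:
        return len(self.sys_levels)

    @property
    def n_clusters(self) -> int:
        return len(self.clust_levels)

    def validate(self) -> None:
        n = self.n
        assert self.X.shape == (n, len(self.mean_names))
        assert self.Z.shape == (n, len(self.disp_names))
        for idx, k in (
            (self.year_idx, self.n_years),
            (self.sys_idx, self.n_systems),
            (self.clust_idx, self.n_clusters),
        ):
            assert idx.shape == (n,) and idx.min() >= 0 and idx.max() < k
        assert self.cluster_habitat.shape == (self.n_clusters,)
        assert self.n_hab in (1, 2)


def _dense_index(labels: list) -> tuple[np.ndarray, list]:
    levels = sorted(set(labels))
    lookup = {v: i for i, v in enumerate(levels)}
    return np.array([lookup[v] for v in labels], dtype=np.int64), levels


def build_design(
    obs: list[TraitObservation],
    clusters: list[Cluster],
    trait: Trait,
    urbanisation_mode: str = "categorical",
    standardise_response: bool = True,
) -> DHGLMData:
    """Assemble the DHGLM design for one species x trait dataset.

    Observations whose nest box is in no cluster, or which lack a covariate
    the trait's model requires (sex for adult tarsus, chick age for nestling
    tarsus, female age for lay date), are dropped with a logged count.
    """
    if urbanisation_mode not in ("categorical", "isa_100", "isa_1000", "isa_both"):
        raise ValueError(f"unknown urbanisation_mode {urbanisation_mode!r}")
    box_to_cluster = membership_map(clusters)
    by_id = {c.cluster_id: c for c in clusters}

    kept: list[TraitObservation] = []
    n_unclustered = 0
    n_missing_cov = 0
    for o in obs:
        if o.trait is not trait:
            raise ValueError(f"observation {o.individual_id} has trait {o.trait}, expected {trait}")
        cid = box_to_cluster.get(o.box_id)
        if cid is None:
            n_unclustered += 1
            continue
        if trait is Trait.ADULT_TARSUS and o.sex is Sex.UNKNOWN:
            n_missing_cov += 1
            continue
        if trait is Trait.NESTLING_TARSUS and not math.isfinite(o.chick_age):
            n_missing_cov += 1
            continue
        if trait is Trait.LAY_DATE and o.female_age is FemaleAge.UNKNOWN:
            n_missing_cov += 1
            continue
        kept.append(o)
    if n_unclustered or n_missing_cov:
        logger.info(
            "build_design dropped %d unclustered and %d covariate-missing rows",
            n_unclustered,
            n_missing_cov,
        )
    if not kept:
        raise ValueError("no observations left after design filtering")

    cluster_ids = [box_to_cluster[o.box_id] for o in kept]
    clust_idx, clust_levels = _dense_index(cluster_ids)
    year_idx, year_levels = _dense_index([o.year for o in kept])
    sys_idx, sys_levels = _dense_index([by_id[c].system_id for c in cluster_ids])

    # refresh years_studied on the clusters from the retained rows
    years_by_cluster: dict[str, set] = {c: set() for c in clust_levels}
    for o, cid in zip(kept, cluster_ids):
        years_by_cluster[cid].add(o.year)
    for cid, yrs in years_by_cluster.items():
        by_id[cid].years_studied = len(yrs)

    used = [by_id[c] for c in clust_levels]
    row_cluster = [by_id[c] for c in cluster_ids]

    n = len(kept)
    y_raw = np.array([o.value for o in kept], dtype=float)
    if standardise_response:
        y, y_mean, y_sd = standardize(y_raw, "response")
    else:
        y, y_mean, y_sd = y_raw, 0.0, 1.0

    def zcol(values, name):
        z, _, _ = standardize(values, name)
        return z

    lat = zcol([c.mean_lat for c in row_cluster], "latitude")
    shan = zcol([c.env.shannon_h for c in row_cluster], "heterogeneity")
    area = zcol([c.area_km2 for c in row_cluster], "cluster_area")
    years_n = zcol([c.years_studied for c in row_cluster], "cluster_years")

    if urbanisation_mode == "categorical":
        urb_cols = [("habitat_urban", np.array([1.0 if c.habitat is Habitat.URBAN else 0.0 for c in row_cluster]))]
        habitat_term = "habitat_urban"
        n_hab = 2
        cluster_habitat = np.array(
            [1 if by_id[c].habitat is Habitat.URBAN else 0 for c in clust_levels], dtype=np.int64
        )
    else:
        cols = []
        if urbanisation_mode in ("isa_100", "isa_both"):
            cols.append(("isa_100", zcol([c.env.isa_100 for c in row_cluster], "isa_100")))
        if urbanisation_mode in ("isa_1000", "isa_both"):
            cols.append(("isa_1000", zcol([c.env.isa_1000 for c in row_cluster], "isa_1000")))
        urb_cols = cols
        habitat_term = cols[0][0]
        n_hab = 1
        cluster_habitat = np.zeros(len(clust_levels), dtype=np.int64)

    mean_cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(n))]
    mean_cols += urb_cols
    mean_cols.append(("latitude", lat))
    if trait is Trait.ADULT_TARSUS:
        mean_cols.append(("sex_male", np.array([1.0 if o.sex is Sex.MALE else 0.0 for o in kept])))
    elif trait is Trait.NESTLING_TARSUS:
        mean_cols.append(("chick_age", zcol([o.chick_age for o in kept], "chick_age")))

    disp_cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(n))]
    disp_cols += urb_cols
    disp_cols.append(("heterogeneity", shan))
    disp_cols.append(("latitude", lat))
    disp_cols.append(("cluster_area", area))
    disp_cols.append(("cluster_years", years_n))
    if trait is Trait.ADULT_TARSUS:
        disp_cols.append(("sex_male", np.array([1.0 if o.sex is Sex.MALE else 0.0 for o in kept])))
    elif trait is Trait.LAY_DATE:
        disp_cols.append(
            ("female_age_yearling", np.array([1.0 if o.female_age is FemaleAge.YEARLING else 0.0 for o in kept]))
        )

    data = DHGLMData(
        y=y,
        X=np.column_stack([c for _, c in mean_cols]),
        Z=np.column_stack([c for _, c in disp_cols]),
        mean_names=[nm for nm, _ in mean_cols],
        disp_names=[nm for nm, _ in disp_cols],
        year_idx=year_idx,
        sys_idx=sys_idx,
        clust_idx=clust_idx,
        cluster_habitat=cluster_habitat,
        n_hab=n_hab,
        year_levels=year_levels,
        sys_levels=sys_levels,
        clust_levels=clust_levels,
        y_mean=y_mean,
        y_sd=y_sd,
        habitat_term=habitat_term,
    )
    data.validate()
    return data
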