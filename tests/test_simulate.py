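"""The synthetic-data generator: defaults, landscapes, forward simulation."""

from __future__ import annotations

import numpy as np
import pytest

from urbanvar.clustering import build_clusters
from urbanvar.dhglm import DHGLMParams
from urbanvar.simulate import (
    SimScenario,
    default_params,
    null_params,
    simulate_landscape,
    simulate_observations,
)
from urbanvar.types import Habitat, Species, Trait


class TestDefaultParams:
    def test_great_tit_lay_date_mean_habitat_effect(self):
        p = default_params(Species.GREAT_TIT, Trait.LAY_DATE)
        assert p.beta[1] == pytest.approx(-0.256)

    def test_blue_tit_nestling_dispersion_habitat_effect(self):
        p = default_params(Species.BLUE_TIT, Trait.NESTLING_TARSUS)
        assert p.gamma[1] == pytest.approx(0.223)

    def test_random_effect_sds_are_sqrt_of_printed_variances(self):
        p = default_params(Species.GREAT_TIT, Trait.ADULT_TARSUS)
        assert p.sd_clust[0] ** 2 == pytest.approx(0.056)
        assert p.sd_clust[1] ** 2 == pytest.approx(0.234)

    def test_unknown_combination_errors(self):
        with pytest.raises((KeyError, ValueError)):
            default_params("ostrich", Trait.LAY_DATE)

    def test_all_six_combinations_resolve(self):
        for sp in Species:
            for tr in Trait:
                p = default_params(sp, tr)
                assert isinstance(p, DHGLMParams)

    def test_null_params_remove_habitat_differences(self):
        p = null_params(Species.GREAT_TIT, Trait.ADULT_TARSUS)
        assert p.gamma[1] == 0.0
        assert p.sd_clust[0] == p.sd_clust[1]
        assert p.sdv_clust[0] == p.sdv_clust[1]

    def test_hypothesis_switches(self):
        h1 = null_params(Species.GREAT_TIT, Trait.ADULT_TARSUS, h1=True, h1_var_ratio=4.0)
        assert (h1.sd_clust[1] / h1.sd_clust[0]) ** 2 == pytest.approx(4.0)
        h2 = null_params(Species.GREAT_TIT, Trait.ADULT_TARSUS, h2=True, h2_gamma=0.2)
        assert h2.gamma[1] == 0.2
        h3 = null_params(Species.GREAT_TIT, Trait.ADULT_TARSUS, h3=True)
        assert (h3.sdv_clust[1] / h3.sdv_clust[0]) ** 2 == pytest.approx(4.0)


class TestLandscape:
    SC = SimScenario(n_systems=2, clusters_per_habitat=3, boxes_per_cluster=7, seed=5)

    def test_clustering_recovers_intended_memberships_exactly(self):
        land = simulate_landscape(self.SC)
        by_system: dict = {}
        for b in land.boxes:
            by_system.setdefault(b.system_id, []).append(b)
        got = set()
        for boxes in by_system.values():
            clusters, unassigned = build_clusters(boxes)
            assert unassigned == []
            got |= {frozenset(c.member_boxes) for c in clusters}
        intended = {frozenset(v) for v in land.intended_members.values()}
        assert got == intended

    def test_clusters_a_kilometre_apart_never_merge(self):
        land = simulate_landscape(self.SC)
        n_intended = len(land.intended_members)
        by_system: dict = {}
        for b in land.boxes:
            by_system.setdefault(b.system_id, []).append(b)
        n_got = sum(len(build_clusters(bs)[0]) for bs in by_system.values())
        assert n_got == n_intended

    def test_urban_boxes_sit_on_high_isa_cells(self):
        from urbanvar.env import isa_proportion

        land = simulate_landscape(self.SC)
        urb, forest = [], []
        for b in land.boxes:
            isa_r, _ = land.rasters[b.system_id]
            v = isa_proportion(isa_r, b.lon, b.lat, 120.0)
            (urb if b.habitat_label is Habitat.URBAN else forest).append(v)
        assert np.mean(urb) > 5 * max(np.mean(forest), 1e-6)

    def test_too_few_boxes_per_cluster_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            SimScenario(boxes_per_cluster=4)


class TestSimulateObservations:
    def test_requested_counts_are_honoured(self):
        sc = SimScenario(n_systems=2, clusters_per_habitat=2, boxes_per_cluster=5,
                         individuals_per_cluster_year=6, n_years=3, seed=1)
        sim = simulate_observations(sc)
        n_clusters = 2 * 2 * 2
        assert len(sim.clusters) == n_clusters
        # every cluster contributes individuals_per_cluster_year per active year
        from collections import Counter

        per = Counter()
        member_to_cluster = {b: c.cluster_id for c in sim.clusters for b in c.member_boxes}
        for o in sim.observations:
            per[(member_to_cluster[o.box_id], o.year)] += 1
        assert set(per.values()) == {6}

    def test_same_seed_is_reproducible(self):
        sc = SimScenario(n_systems=2, clusters_per_habitat=2, seed=9)
        a = simulate_observations(sc)
        b = simulate_observations(sc)
        assert [o.value for o in a.observations] == [o.value for o in b.observations]
        c = simulate_observations(sc, seed=10)
        assert [o.value for o in a.observations] != [o.value for o in c.observations]

    def test_degenerate_limit_collapses_to_the_fixed_effect_mean(self):
        # all variance components ~0 and a very negative dispersion intercept:
        # y equals its fixed-effect mean to numerical precision
        p = default_params(Species.GREAT_TIT, Trait.ADULT_TARSUS)
        import dataclasses

        degenerate = dataclasses.replace(
            p,
            gamma=np.concatenate([[-12.0], np.zeros(p.gamma.size - 1)]),
            sd_year=1e-12, sd_sys=1e-12, sd_clust=[1e-12, 1e-12],
            sdv_sys=1e-12, sdv_clust=[1e-12, 1e-12],
        )
        sc = SimScenario(n_systems=2, clusters_per_habitat=2, seed=3, params=degenerate)
        sim = simulate_observations(sc)
        mu = sim.design.X @ degenerate.beta
        np.testing.assert_allclose(sim.z_values, mu, atol=1e-4)

    def test_truth_record_carries_params_and_latents(self):
        sc = SimScenario(n_systems=2, clusters_per_habitat=2, seed=2)
        sim = simulate_observations(sc)
        assert sim.truth["params"] is sim.params
        assert sim.truth["effects"].a_clust.size == len(sim.clusters)
        assert sim.truth["n_obs"] == sim.design.n

    def test_values_written_in_original_units(self):
        sc = SimScenario(n_systems=2, clusters_per_habitat=2, seed=4)
        sim = simulate_observations(sc)
        vals = np.array([o.value for o in sim.observations])
        assert 14.0 < vals.mean() < 25.0  # adult tarsus in mm, not z-scores


class TestNullScenarioControl:
    def test_habitat_effects_rarely_flagged_without_a_generating_effect(self):
        """With all habitat differences switched off, the urban dispersion
        coefficient should not earn an 'evidence' label (false-positive
        control at small scale)."""
        from urbanvar.dhglm import sample_posterior
        from urbanvar.summaries import classify_evidence
        from urbanvar.types import MCMCSettings

        params = null_params(Species.GREAT_TIT, Trait.ADULT_TARSUS)
        flags = []
        for rep in range(3):
            sc = SimScenario(
                n_systems=2, clusters_per_habitat=3, boxes_per_cluster=6,
                individuals_per_cluster_year=10, n_years=4,
                seed=300 + rep, params=params,
            )
            sim = simulate_observations(sc)
            draws = sample_posterior(
                sim.design, MCMCSettings(chains=2, iterations=700, warmup=350),
                seed=400 + rep,
            )
            flags.append(classify_evidence(draws.get("b_disp[habitat_urban]"), "positive").value)
        assert sum(f != "evidence" for f in flags) >= 2, flags
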