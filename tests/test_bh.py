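"""Basin-hopping loop: moves, screening, acceptance statistics, uniqueness."""

import numpy as np
import pytest

from helpers import random_geometry
from pesmap.bh import (
    BHConfig,
    MinimaLibrary,
    MinimumRecord,
    StartupError,
    accept_step,
    perturb,
    register_unique,
    run_bh,
    screen,
)
from pesmap.fixtures import make_lj_cluster, make_torsion_chain
from pesmap.geom import Geometry, distance_matrix, dm_similarity
from pesmap.potentials import LennardJones, local_minimize

LJ_CFG = dict(min_interatomic=0.5, interaction_radius=6.0, energy_tol=1e-5,
              similarity_tol=5.0, mapping="element")


class TestPerturb:
    def test_null_move_with_zero_steps(self):
        g, model = make_torsion_chain(6, seed=0)
        cfg = BHConfig(dihedral_step=0.0, rigid_rot_step=0.0, translation_step=0.0)
        rng = np.random.default_rng(0)
        out = perturb(g, cfg, rng, model.topology(g))
        np.testing.assert_array_equal(out.coords, g.coords)

    @pytest.mark.parametrize("seed", range(3))
    def test_dihedral_moves_preserve_bonded_distances(self, seed):
        g, model = make_torsion_chain(8, seed=seed)
        cfg = BHConfig(dihedral_step=30.0, rigid_rot_step=0.0, translation_step=0.0)
        out = perturb(g, cfg, np.random.default_rng(seed), model.topology(g))
        for i in range(7):
            before = np.linalg.norm(g.coords[i + 1] - g.coords[i])
            after = np.linalg.norm(out.coords[i + 1] - out.coords[i])
            assert after == pytest.approx(before, abs=1e-9)

    def test_rigid_move_preserves_internal_distances(self):
        g = make_lj_cluster(5, seed=1)
        cfg = BHConfig(rigid_rot_step=30.0, translation_step=1.0)
        from pesmap.potentials import Topology

        topo = Topology(moieties=(tuple(range(5)),))
        out = perturb(g, cfg, np.random.default_rng(2), topo)
        np.testing.assert_allclose(
            distance_matrix(out).D, distance_matrix(g).D, atol=1e-9
        )

    def test_fixed_seed_reproduces_sequence(self):
        g = make_lj_cluster(6, seed=0)
        cfg = BHConfig(seed=7)
        seq1 = [perturb(g, cfg, np.random.default_rng(7)).coords for _ in range(1)]
        seq2 = [perturb(g, cfg, np.random.default_rng(7)).coords for _ in range(1)]
        np.testing.assert_array_equal(seq1[0], seq2[0])


class TestScreen:
    def test_clash_rejected_with_reason(self):
        g = Geometry(["X", "X"], [[0, 0, 0], [0.3, 0, 0]])
        res = screen(g, BHConfig(min_interatomic=0.8))
        assert not res and "clash" in res.reason and "0,1" in res.reason

    def test_dissociation_rejected_with_reason(self):
        g = Geometry(["X"] * 3, [[0, 0, 0], [1, 0, 0], [25.0, 0, 0]])
        res = screen(g, BHConfig(min_interatomic=0.8, interaction_radius=15.0))
        assert not res and "dissociation" in res.reason

    def test_compact_cluster_accepted(self):
        g, e, _ = local_minimize(LennardJones(), make_lj_cluster(6, seed=2))
        assert screen(g, BHConfig(min_interatomic=0.8, interaction_radius=15.0))

    def test_bonded_pairs_exempt_from_clash_rule(self):
        g, model = make_torsion_chain(5, seed=0)  # unit bonds < min_interatomic 1.1
        assert screen(g, BHConfig(min_interatomic=1.05, interaction_radius=50.0),
                      model.topology(g))


class TestAcceptStep:
    def test_new_global_minimum_always_replaces(self):
        cfg = BHConfig(thermal_energy=1e-9)
        rng = np.random.default_rng(0)
        assert accept_step(-10.0, -1.0, -9.0, cfg, rng) == "replace_gm"

    def test_equal_energy_always_accepted(self):
        cfg = BHConfig(thermal_energy=0.1)
        for s in range(10):
            assert accept_step(-1.0, -1.0, -5.0, cfg, np.random.default_rng(s)) == "accept"

    def test_metropolis_rate_at_one_thermal_energy(self):
        """Uphill by exactly kT accepts at frequency e^-1 over many draws."""
        cfg = BHConfig(thermal_energy=0.7)
        rng = np.random.default_rng(123)
        n = 100_000
        acc = sum(
            accept_step(-1.0 + 0.7, -1.0, -5.0, cfg, rng) == "accept" for _ in range(n)
        )
        assert acc / n == pytest.approx(np.exp(-1.0), abs=0.01)


class TestRegisterUnique:
    def _record(self, seed, energy):
        g, e, _ = local_minimize(LennardJones(), make_lj_cluster(6, seed=seed))
        return MinimumRecord(g.with_coords(g.coords, energy=energy), energy)

    def test_exact_duplicate_not_added(self):
        cfg = BHConfig(**LJ_CFG)
        lib = MinimaLibrary()
        rec = self._record(0, -12.0)
        assert register_unique(lib, rec, cfg)
        assert not register_unique(lib, rec, cfg)
        assert len(lib) == 1

    def test_energy_distinct_added(self):
        cfg = BHConfig(**LJ_CFG)
        lib = MinimaLibrary()
        rec = self._record(0, -12.0)
        register_unique(lib, rec, cfg)
        twin = MinimumRecord(rec.geometry, -12.0 + 2 * cfg.energy_tol)
        assert register_unique(lib, twin, cfg)

    def test_planted_near_duplicates_collapse(self):
        """10 records with 3 planted near-duplicates leave 7 unique minima."""
        cfg = BHConfig(**LJ_CFG)
        lib = MinimaLibrary()
        base = [self._record(s, -10.0 - s) for s in range(7)]
        dupes = []
        rng = np.random.default_rng(0)
        for rec in base[:3]:
            g = rec.geometry
            jitter = g.with_coords(g.coords + 1e-7 * rng.standard_normal(g.coords.shape))
            dupes.append(MinimumRecord(jitter, rec.energy + 1e-7))
        for rec in base + dupes:
            register_unique(lib, rec, cfg)
        assert len(lib) == 7


class TestRunBH:
    def test_zero_steps_library_is_minimised_start(self):
        model = LennardJones()
        start = make_lj_cluster(6, seed=0)
        cfg = BHConfig(n_steps=0, **LJ_CFG)
        lib, log = run_bh(model, start, cfg)
        assert len(lib) == 1 and len(log) == 0
        _, e, _ = local_minimize(model, start)
        assert lib.e_low == pytest.approx(e, abs=1e-10)

    def test_deterministic_under_seed(self):
        model = LennardJones()
        cfg = BHConfig(thermal_energy=0.5, n_steps=40, seed=3, **LJ_CFG)
        lib1, log1 = run_bh(model, make_lj_cluster(6, seed=3), cfg)
        lib2, log2 = run_bh(model, make_lj_cluster(6, seed=3), cfg)
        assert log1.equals(log2)
        assert len(lib1) == len(lib2)
        for r1, r2 in zip(lib1, lib2):
            np.testing.assert_array_equal(r1.geometry.coords, r2.geometry.coords)

    def test_e_low_monotone_and_records_idempotent(self):
        model = LennardJones()
        cfg = BHConfig(thermal_energy=0.5, n_steps=60, seed=5, **LJ_CFG)
        lib, log = run_bh(model, make_lj_cluster(7, seed=5), cfg)
        e_low = log.e_low.to_numpy()
        assert np.all(np.diff(e_low) <= 1e-12)
        for rec in lib:
            g2, e2, conv = local_minimize(model, rec.geometry)
            assert conv and e2 == pytest.approx(rec.energy, abs=1e-8)

    def test_startup_screening_enforced(self):
        model = LennardJones()
        # dimer forced apart beyond the interaction radius: minimisation
        # cannot pull it back inside, so the start must be refused
        start = Geometry(["X", "X"], [[0, 0, 0], [40.0, 0, 0]])
        cfg = BHConfig(n_steps=1, min_interatomic=0.5, interaction_radius=6.0)
        with pytest.raises(StartupError):
            run_bh(model, start, cfg)

    def test_thermal_energy_controls_uphill_tolerance(self):
        """Mean accepted uphill step grows with the acceptance window."""
        model = LennardJones()

        def mean_uphill(t):
            cfg = BHConfig(thermal_energy=t, n_steps=150, seed=11, **LJ_CFG)
            lib, log = run_bh(model, make_lj_cluster(7, seed=11), cfg)
            e = log[log.decision.isin(["accept", "replace_gm"])].energy.to_numpy()
            de = np.diff(e)
            up = de[de > 0]
            return up.mean() if up.size else 0.0

        assert mean_uphill(0.2) < mean_uphill(2.0)

    def test_lj7_runs_reach_global_minimum(self):
        """Seeded LJ7 searches find the pentagonal-bipyramid minimum."""
        model = LennardJones()
        oracle = min(
            local_minimize(model, make_lj_cluster(7, seed=900 + s))[1] for s in range(150)
        )
        hits = 0
        for seed in range(3):
            cfg = BHConfig(thermal_energy=0.5, n_steps=300, seed=seed, **LJ_CFG)
            lib, _ = run_bh(model, make_lj_cluster(7, seed=seed), cfg)
            hits += lib.e_low <= oracle + 1e-6
        assert hits == 3
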