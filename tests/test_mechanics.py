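"""Cell mechanics: contacts, forces, growth, division, removal."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import chisquare

import cryptsim.mechanics as mech_mod
from cryptsim import (
    CellPopulation,
    GrowthParams,
    MechanicsParams,
    V0_UM3,
    detect_contacts,
    divide_cell,
    make_ring_fixture,
    pairwise_force,
    migration_bias_force,
    step_positions,
)
from cryptsim.population import Cell, SC, EC_PROG, PC_TERM, EC_TERM
from conftest import random_surface_points


def cell_at(pos, state="SC", volume=V0_UM3, cid=0):
    return Cell(id=cid, position=np.asarray(pos, float), volume=volume,
                lineage_state=state)


def pop_from(positions, states=SC, volumes=V0_UM3):
    pop = CellPopulation()
    pop.add(np.asarray(positions, float), states=states, volumes=volumes)
    return pop


class TestContacts:
    def test_touching_pair_is_edge(self, surface):
        r = cell_at([4, 0, 5]).radius
        pop = pop_from([[4, 0, 5], [4, 0, 5 + 1.8 * r]])
        g = detect_contacts(pop, contact_factor=1.1)
        assert len(g.pairs) == 1

    def test_distant_pair_is_not_edge(self, surface):
        r = cell_at([4, 0, 5]).radius
        pop = pop_from([[4, 0, 5], [4, 0, 5 + 4 * r]])
        g = detect_contacts(pop, contact_factor=1.1)
        assert len(g.pairs) == 0

    def test_matches_all_pairs_brute_force(self, surface, rng):
        pts = random_surface_points(surface, rng, 20)
        pop = pop_from(pts, volumes=V0_UM3 * rng.uniform(1, 2, 20))
        factor = 1.25
        g = detect_contacts(pop, contact_factor=factor)
        r = pop.radius
        expected = set()
        for i in range(20):
            for j in range(i + 1, 20):
                if np.linalg.norm(pts[i] - pts[j]) < factor * (r[i] + r[j]):
                    expected.add((min(pop.id[i], pop.id[j]),
                                  max(pop.id[i], pop.id[j])))
        assert g.edges == expected

    def test_neighbour_lists_symmetric(self, surface, rng):
        pts = random_surface_points(surface, rng, 15)
        pop = pop_from(pts)
        g = detect_contacts(pop, contact_factor=1.3)
        for i in range(pop.n):
            for j in g.neighbours(i):
                assert i in g.neighbours(j)


class TestPairwiseForce:
    def test_zero_repulsion_full_adhesion_at_touching(self):
        p = MechanicsParams()
        a = cell_at([0, 0, 0], cid=0)
        b = cell_at([2 * a.radius, 0, 0], cid=1)  # d = r_i + r_j exactly
        f = pairwise_force(a, b, p)
        # attraction toward b (at +x) with full adhesion magnitude
        assert f[0] == pytest.approx(p.k_adh)

    def test_hertz_magnitude_closed_form(self):
        p = MechanicsParams(k_rep=1.0, k_adh=0.0)
        a = cell_at([0, 0, 0], cid=0)
        d = 2 * a.radius - 0.1  # overlap depth 0.1
        b = cell_at([d, 0, 0], cid=1)
        f = pairwise_force(a, b, p)
        assert np.linalg.norm(f) == pytest.approx(0.1**1.5, rel=1e-9)
        assert f[0] < 0  # pushes a away from b (b sits at +x)

    def test_newtons_third_law(self, rng):
        p = MechanicsParams()
        a = cell_at(rng.normal(size=3), cid=0)
        b = cell_at(a.position + rng.normal(scale=0.5, size=3), cid=1)
        assert np.allclose(pairwise_force(a, b, p), -pairwise_force(b, a, p))

    def test_coincident_centres_deterministic(self):
        p = MechanicsParams()
        a = cell_at([1, 1, 1], cid=3)
        b = cell_at([1, 1, 1], cid=7)
        f1 = pairwise_force(a, b, p)
        f2 = pairwise_force(a, b, p)
        assert np.allclose(f1, f2)
        assert np.linalg.norm(f1) > 0

    def test_total_internal_force_sums_to_zero(self, surface, rng):
        pts = random_surface_points(surface, rng, 30)
        pop = pop_from(pts, volumes=V0_UM3 * rng.uniform(1, 2, 30))
        p = MechanicsParams()
        g = detect_contacts(pop, p.contact_factor)
        F = mech_mod.pair_forces(pop, g.pairs, p)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-9)


class TestMigrationBias:
    def test_sc_has_no_bias(self, surface):
        f = migration_bias_force(cell_at([4, 0, 5], "SC"), surface)
        assert np.allclose(f, 0)

    def test_ec_moves_up_at_equator(self, surface):
        p = MechanicsParams()
        f = migration_bias_force(cell_at([4, 0, 0], "EC_progenitor"), surface, p)
        assert np.linalg.norm(f) == pytest.approx(p.bias_up)
        assert f[2] > 0  # up the axis

    def test_pc_moves_down_unless_bias_disabled(self, surface):
        p = MechanicsParams()
        pc = cell_at([4, 0, 5], "PC_terminal")
        f_on = migration_bias_force(pc, surface, p, pc_bias_on=True)
        assert f_on[2] == pytest.approx(-p.bias_down)
        f_off = migration_bias_force(pc, surface, p, pc_bias_on=False)
        assert np.allclose(f_off, 0)

    def test_pc_at_bottom_pole_has_zero_bias(self, surface):
        f = migration_bias_force(cell_at([0, 0, -4], "PC_terminal"), surface)
        assert np.allclose(f, 0)


class TestStepPositions:
    def test_isolated_cell_does_not_move(self, surface):
        pop = pop_from([[4, 0, 5]])
        p = MechanicsParams()
        g = detect_contacts(pop, p.contact_factor)
        before = pop.pos.copy()
        step_positions(pop, g, surface, p)
        assert np.allclose(pop.pos, before)

    def test_overlapping_pair_separates_monotonically(self, surface):
        p = MechanicsParams(k_adh=0.0)
        r = cell_at([0, 0, 0]).radius
        pop = pop_from([[4, 0, 5], [4, 0, 5 + r]])  # overlap depth r
        dist_prev = r
        for _ in range(80):
            g = detect_contacts(pop, p.contact_factor)
            step_positions(pop, g, surface, p)
            d = np.linalg.norm(pop.pos[0] - pop.pos[1])
            assert d >= dist_prev - 1e-12
            dist_prev = d
        # overlap decays as delta^{-1/2} growth: nearly resolved after 8 h
        assert dist_prev >= 2 * r - 0.01

    def test_two_body_matches_fine_timestep_oracle(self, surface):
        """Coarse integration within 1% of an independent ODE solution."""
        p = MechanicsParams(k_adh=0.0, k_rep=2.0)
        r = cell_at([0, 0, 0]).radius
        z0, gap0 = 5.0, 0.5 * r
        pop = pop_from([[4, 0, z0], [4, 0, z0 + 2 * r - gap0]])
        T = 1.0
        for _ in range(int(T / p.dt)):
            g = detect_contacts(pop, p.contact_factor)
            step_positions(pop, g, surface, p)
        d_sim = np.linalg.norm(pop.pos[0] - pop.pos[1])

        # independent oracle: d'(t) = 2 k (2r - d)^{3/2} / friction
        def rhs(t, d):
            delta = max(2 * r - d[0], 0.0)
            return [2 * p.k_rep * delta**1.5 / p.friction]

        sol = solve_ivp(rhs, (0, T), [2 * r - gap0], rtol=1e-10, atol=1e-12)
        assert d_sim == pytest.approx(sol.y[0, -1], rel=0.01)

    def test_lone_ec_climbs_at_bias_over_friction_rate(self, surface):
        p = MechanicsParams()
        pop = pop_from([[4, 0, 5]], states=EC_PROG)
        P0 = surface.axial_position(pop.pos)[0]
        hours = 2.0
        for _ in range(int(hours / p.dt)):
            g = detect_contacts(pop, p.contact_factor)
            step_positions(pop, g, surface, p)
        P1 = surface.axial_position(pop.pos)[0]
        assert P1 - P0 == pytest.approx(p.bias_up / p.friction * hours, rel=1e-6)

    def test_unstable_dt_rejected(self, surface):
        pop = pop_from([[4, 0, 5]])
        p = MechanicsParams()
        g = detect_contacts(pop, p.contact_factor)
        with pytest.raises(ValueError):
            step_positions(pop, g, surface, p, dt=1.0)


class TestCompression:
    def test_isolated_cell_keeps_own_volume(self, surface):
        pop = pop_from([[4, 0, 5]])
        g = detect_contacts(pop, 1.1)
        avail = mech_mod.available_volumes(pop, g)
        assert avail[0] == pytest.approx(pop.volume[0])

    def test_two_identical_spheres_at_distance_r(self):
        # analytic lens volume for R = r, d = r: V = 5/12 pi r^3
        r = 1.3
        v = mech_mod.sphere_overlap_volume(r, r, r)
        assert v == pytest.approx(5.0 / 12.0 * np.pi * r**3, rel=1e-12)

    def test_fully_engulfed_overlap_floors_at_zero(self, surface):
        # many coincident-ish neighbours push available volume to the floor
        pts = [[4, 0, 5]] + [[4, 0, 5 + 0.01 * k] for k in range(1, 7)]
        pop = pop_from(pts)
        g = detect_contacts(pop, 1.1)
        avail = mech_mod.available_volumes(pop, g)
        assert avail[0] == 0.0

    def test_local_compression_matches_vectorised(self, surface, rng):
        pts = random_surface_points(surface, rng, 12)
        pop = pop_from(pts, volumes=V0_UM3 * rng.uniform(1, 2, 12))
        g = detect_contacts(pop, 1.25)
        avail = mech_mod.available_volumes(pop, g)
        for i in (0, 5, 11):
            got = mech_mod.local_compression(pop.cell(i), g, pop)
            assert got == pytest.approx(avail[i], rel=1e-9)


class TestGrowth:
    def test_uncompressed_cell_doubles_in_one_cycle(self, surface):
        pop = pop_from([[4, 0, 5]])
        pop.growth_time[:] = 16.0
        growth = GrowthParams()
        g = detect_contacts(pop, 1.1)
        for _ in range(16):
            mech_mod.grow_cells(pop, g, 1.0, growth)
        assert pop.volume[0] == pytest.approx(2 * growth.v0, rel=1e-9)

    def test_compressed_cell_pauses(self, surface):
        pts = [[4, 0, 5]] + [[4, 0, 5 + 0.3 * k] for k in range(1, 5)]
        pop = pop_from(pts)
        growth = GrowthParams()
        g = detect_contacts(pop, 1.1)
        v_before = pop.volume[0]
        mech_mod.grow_cells(pop, g, 1.0, growth)
        assert pop.volume[0] == v_before
        assert pop.inhibited[0]

    def test_vp_rescaled_cell_keeps_growing(self, surface):
        """A cell below wild-type Vp but above 0.76 Vp grows only with the
        reduced contact-inhibition sensitivity."""
        from cryptsim.mutation import ProfileTable, mutant2_profile
        from cryptsim.params import FateParams

        growth = GrowthParams()
        table = ProfileTable(FateParams())
        table.add(mutant2_profile(4))

        def make(profile):
            pop = pop_from([[4, 0, 5], [4, 0, 6.0]])
            pop.profile[0] = profile
            return pop

        # tune geometry so available volume falls between 0.76 Vp and Vp
        for profile, should_grow in ((0, False), (1, True)):
            pop = make(profile)
            g = detect_contacts(pop, 1.1)
            avail = mech_mod.available_volumes(pop, g)
            assert 0.76 * growth.vp < avail[0] < growth.vp
            v0_before = pop.volume[0]
            mech_mod.grow_cells(pop, g, 1.0, growth, table)
            assert (pop.volume[0] > v0_before) == should_grow


class TestDivision:
    def test_volume_conserved(self, surface, rng):
        mother = cell_at([4, 0, 5], volume=2 * V0_UM3)
        d1, d2 = divide_cell(mother, rng, surface)
        assert d1.volume + d2.volume == pytest.approx(2 * V0_UM3)

    def test_daughters_inherit_profile_and_founder(self, surface, rng):
        mother = cell_at([4, 0, 5], volume=2 * V0_UM3)
        mother.profile = 3
        mother.founder_id = 42
        d1, d2 = divide_cell(mother, rng, surface)
        assert d1.profile == d2.profile == 3
        assert d1.founder_id == d2.founder_id == 42

    def test_terminal_cell_refuses(self, surface, rng):
        with pytest.raises(ValueError):
            divide_cell(cell_at([4, 0, 5], "EC_terminal"), rng, surface)

    def test_division_axis_uniform_on_tangent_circle(self, rng):
        """10^4 divisions: separation angles uniform (chi-square)."""
        mother = cell_at([0, 0, 10], volume=2 * V0_UM3)
        angles = []
        for _ in range(10_000):
            d1, d2 = divide_cell(mother, rng)
            v = d1.position - d2.position
            angles.append(np.arctan2(v[1], v[0]) % (2 * np.pi))
        counts, _ = np.histogram(angles, bins=12, range=(0, 2 * np.pi))
        assert chisquare(counts).pvalue > 1e-3


class TestRemoval:
    def _pop_at_P(self, surface, P_values, states=EC_TERM):
        pts = []
        for P in P_values:
            z = P - 4 * np.pi / 2
            pts.append([4.0, 0.0, z])
        return pop_from(pts, states=states)

    def test_exit_boundary_strict(self, surface):
        pop = self._pop_at_P(surface, [29.0, 30.0, 31.0])
        p = MechanicsParams()
        recs = mech_mod.apply_anoikis_and_exit(pop, surface, p, GrowthParams(), 0.0)
        assert [r.event for r in recs] == ["exit"]
        assert pop.n == 2  # P = 30 retained (strict inequality)

    def test_detached_cell_removed_as_anoikis(self, surface):
        pop = pop_from([[4, 0, 5]])
        pop.pos[0, 0] += 3.0  # push well off the surface
        p = MechanicsParams()
        recs = mech_mod.apply_anoikis_and_exit(pop, surface, p, GrowthParams(), 1.0)
        assert len(recs) == 1 and recs[0].event == "anoikis"
        assert pop.n == 0
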