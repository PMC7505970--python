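import numpy as np
import pytest

from exoevo import (Cell, DiffusionInstabilityError, LatticeState,
                    diffuse_doc, make_fixture,
                    micro_disturbance, place_newborn, simulate_lattice,
                    step_lattice)


def empty_lattice(params, L=None):
    return make_fixture("empty", params.with_(L=L or params.L), None)


class TestDiffusion:
    def test_uniform_field_unchanged(self, params):
        p = params.with_(L=5)
        lat = empty_lattice(p)
        for site in lat.sites():
            site.d = 3.7e-12
        diffuse_doc(lat, p.resolve_tau_diff(), p)
        assert all(site.d == pytest.approx(3.7e-12, rel=1e-14)
                   for site in lat.sites())

    def test_total_doc_conserved_on_random_lattices(self, params, rng):
        """Neumann boundaries make the update a pure redistribution."""
        p = params.with_(L=6)
        tau = p.resolve_tau_diff()
        for _ in range(1000):
            lat = empty_lattice(p)
            values = rng.uniform(0, 1e-11, size=(6, 6))
            for i in range(6):
                for j in range(6):
                    lat.grid[i][j].d = values[i, j]
            before = lat.total_doc
            diffuse_doc(lat, tau, p)
            assert lat.total_doc == pytest.approx(before, rel=1e-12)

    def test_interior_spike_follows_the_stencil(self, params):
        p = params.with_(L=5)
        lat = empty_lattice(p)
        d0 = 1e-10
        lat.grid[2][2].d = d0
        tau = p.resolve_tau_diff()
        f = p.sigma_diff * tau / p.site_length_sq
        diffuse_doc(lat, tau, p)
        assert lat.grid[2][2].d == pytest.approx((1 - 4 * f) * d0, rel=1e-12)
        for i, j in [(1, 2), (3, 2), (2, 1), (2, 3)]:
            assert lat.grid[i][j].d == pytest.approx(f * d0, rel=1e-12)
        assert lat.grid[0][0].d == 0.0

    def test_instability_guard(self, params):
        p = params.with_(sigma_diff=5e-5, L=4)
        lat = empty_lattice(p)
        with pytest.raises(DiffusionInstabilityError):
            diffuse_doc(lat, 1.0, p)   # 4f >> 1 at tau = 1 h


class TestPlacement:
    def _lattice_with_mother(self, params, occupied_neighbours):
        p = params.with_(L=3)
        lat = empty_lattice(p)
        lat.grid[1][1].cells.append(Cell(0.5))
        if occupied_neighbours:
            for i, j in [(0, 1), (2, 1), (1, 0), (1, 2)]:
                lat.grid[i][j].cells.append(Cell(0.5))
        return p, lat

    def test_no_dispersal_probability_means_always_stay(self, params, rng):
        p, lat = self._lattice_with_mother(params.with_(p_disp=0.0), False)
        for _ in range(1000):
            out = place_newborn(lat, (1, 1), Cell(0.5), rng, p)
            assert out == "stayed"
        assert lat.grid[1][1].M == 1001

    def test_all_neighbours_occupied_without_disturbance(self, params, rng):
        p, lat = self._lattice_with_mother(
            params.with_(p_open=0.0), True)
        outcomes = {place_newborn(lat, (1, 1), Cell(0.5), rng, p)
                    for _ in range(2000)}
        assert outcomes == {"stayed"}

    def test_dispersal_fraction_matches_p_disp(self, params):
        """With an empty neighbour always available, the fraction of
        newborns that leave the mother site estimates p_disp = 0.3."""
        rng = np.random.default_rng(42)
        n, moved = 10_000, 0
        for _ in range(n):
            p, lat = self._lattice_with_mother(params, False)
            if place_newborn(lat, (1, 1), Cell(0.5), rng, p) == "dispersed":
                moved += 1
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(moved / n - 0.3) < 4 * se

    def test_disturbance_opens_and_colonizes_a_neighbour(self, params):
        rng = np.random.default_rng(9)
        p, lat = self._lattice_with_mother(
            params.with_(p_disp=1.0, p_open=1.0), True)
        out = place_newborn(lat, (1, 1), Cell(0.5, strain_id=1), rng, p)
        assert out == "disturbance"
        # one neighbour now holds exactly the newborn
        hit = [lat.grid[i][j] for i, j in [(0, 1), (2, 1), (1, 0), (1, 2)]
               if lat.grid[i][j].M == 1
               and lat.grid[i][j].cells[0].strain_id == 1]
        assert len(hit) == 1
        assert hit[0].c > 0 and hit[0].d > 0   # recycled carbon


class TestDisturbance:
    def test_recycled_amounts(self, params):
        p = params.with_(L=3)
        lat = empty_lattice(p)
        lat.grid[0][0].cells.extend(Cell(0.5, 0.0) for _ in range(7))
        micro_disturbance(lat, (0, 0), p)
        assert lat.grid[0][0].M == 0
        assert lat.grid[0][0].c == pytest.approx(3.5e-9)
        assert lat.grid[0][0].d == pytest.approx(3.5e-9)

    def test_empty_target_is_noop(self, params):
        p = params.with_(L=3)
        lat = empty_lattice(p)
        micro_disturbance(lat, (1, 1), p)
        assert lat.grid[1][1].c == 0.0 and lat.grid[1][1].M == 0

    def test_full_leaching(self, params):
        p = params.with_(L=3, l=1.0)
        lat = empty_lattice(p)
        lat.grid[0][0].cells.append(Cell(0.5))
        micro_disturbance(lat, (0, 0), p)
        assert lat.grid[0][0].M == 0
        assert lat.grid[0][0].c == 0.0 and lat.grid[0][0].d == 0.0


class TestMasterLoop:
    def test_empty_lattice_clock_advances_by_tau_diff(self, params, rng):
        p = params.with_(L=3, tau_diff=0.1, sigma_diff=1e-7)
        lat = empty_lattice(p)
        step_lattice(lat, p, rng)
        assert lat.t == pytest.approx(0.1)
        assert lat.M_total == 0

    def test_fixed_seed_reproducibility(self, params):
        p = params.with_(L=4)
        init = LatticeState.monomorphic_steady(p, 0.5, seed=2)
        a = simulate_lattice(init.copy(), p, 2e3, seed=11)
        b = simulate_lattice(init.copy(), p, 2e3, seed=11)
        for key in a.trajectory:
            assert np.array_equal(a.trajectory[key], b.trajectory[key],
                                  equal_nan=True)
        assert a.counters == b.counters

    def test_carbon_closure_between_every_sample(self, params):
        p = params.with_(L=4)
        init = LatticeState.monomorphic_steady(p, 0.5, seed=2)
        run = simulate_lattice(init, p, 5e3, seed=3, rec_interval=250.0)
        tr = run.trajectory
        total = (tr["c"] + tr["d"] + tr["z"]
                 + tr["M"] * p.omega_M + tr["S_total"])
        budget = (tr["cum_inputs"] - tr["cum_leaching"]
                  - tr["cum_respiration"] - tr["cum_leached_recycling"]
                  + tr["clip_residual"])
        drift = np.diff(total) - np.diff(budget)
        assert np.abs(drift).max() < 1e-9 * tr["cum_inputs"][-1] + 1e-20

    def test_no_boundary_accumulation_of_doc(self, params):
        """Time-averaged corner DOC stays within sampling error of the
        centre in a neutral monomorphic run (reflecting boundaries)."""
        p = params.with_(L=5)
        init = LatticeState.monomorphic_steady(p, 0.5, seed=4)
        run = simulate_lattice(init, p, 8e4, seed=4, acc_start=2e4)
        d_avg = run.site_time_avg["d"].reshape(5, 5)
        corner = d_avg[0, 0]
        centre = d_avg[2, 2]
        assert corner == pytest.approx(centre, rel=0.5)
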