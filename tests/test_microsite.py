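import math

import numpy as np
import pytest

from exoevo import (Cell, FlowLedger, MicrositeState, apply_death,
                    apply_divisions, draw_death_time, integrate_flows,
                    simulate_single_site, steady_state)
from exoevo.lattice import LatticeState, step_lattice


def equilibrium_site(params, phi, n_cells=None):
    """Microsite at the deterministic equilibrium.  When ``n_cells`` is
    given, omega_M is left alone and the integer population approximates the
    equilibrium biomass; otherwise callers should pair the site with the
    matched-omega parameter trick used in the drift test."""
    ss = steady_state(params, phi)
    assert ss.viable
    if n_cells is None:
        n_cells = max(1, round(ss.state.m / params.omega_M))
    cells = [Cell(phi, 0.0) for _ in range(n_cells)]
    return MicrositeState(ss.state.c, ss.state.d, ss.state.z, cells), ss


class TestDeathClock:
    def test_no_cells_no_death(self, params, rng):
        assert draw_death_time(0, params, rng) == math.inf

    def test_exponential_mean(self, params, rng):
        draws = [draw_death_time(10, params, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(1 / (params.d_M * 10),
                                               rel=0.05)

    def test_seeded_reproducibility(self, params):
        a = draw_death_time(5, params, np.random.default_rng(7))
        b = draw_death_time(5, params, np.random.default_rng(7))
        assert a == b


class TestFlows:
    def test_empty_site_pools_follow_linear_flows(self, params):
        p = params.with_(I_D=1e-13)
        site = MicrositeState(c=0.0, d=0.0, z=0.0)
        dt = 10.0
        integrate_flows(site, dt, p)
        # exact solutions of the decoupled linear ODEs
        c_exact = p.I_C / p.l_C * (1 - math.exp(-p.l_C * dt))
        d_exact = p.I_D / p.l_D * (1 - math.exp(-p.l_D * dt))
        assert site.c == pytest.approx(c_exact, rel=1e-4)
        assert site.d == pytest.approx(d_exact, rel=1e-4)
        assert site.z == 0.0

    def test_equilibrium_site_does_not_drift(self, params):
        """With full leaching (l = 1) dead carbon is never recycled, so the
        continuous flows alone share their fixed point with the cdmz model;
        a site placed there must not drift."""
        p_full = params.with_(l=1.0)
        ss = steady_state(p_full, 0.5)
        n = 8
        p = p_full.with_(omega_M=ss.state.m / n)  # integer-cell equilibrium
        site = MicrositeState(ss.state.c, ss.state.d, ss.state.z,
                              [Cell(0.5, 0.0) for _ in range(n)])
        integrate_flows(site, 50.0, p)
        assert site.c == pytest.approx(ss.state.c, rel=1e-6)
        assert site.d == pytest.approx(ss.state.d, rel=1e-6)
        assert site.z == pytest.approx(ss.state.z, rel=1e-6)

    def test_recycling_pulses_explain_interdeath_drift(self, params):
        """With the default partial recycling, the slow SOC pool drains
        between death events at exactly the death-recycling flux the cdmz
        model credits continuously."""
        ss = steady_state(params, 0.5)
        n = 8
        p = params.with_(omega_M=ss.state.m / n)
        site = MicrositeState(ss.state.c, ss.state.d, ss.state.z,
                              [Cell(0.5, 0.0) for _ in range(n)])
        dt = 50.0
        integrate_flows(site, dt, p)
        missing = (1 - p.l) * p.p * p.d_M * ss.state.m * dt
        assert ss.state.c - site.c == pytest.approx(missing, rel=0.05)

    def test_full_allocation_stops_growth(self, params):
        site, _ = equilibrium_site(params, 0.5)
        for cell in site.cells:
            cell.phi = 1.0
        z0 = site.z
        deltas = integrate_flows(site, 5.0, params)
        assert deltas[1.0] == 0.0
        assert site.z > z0 * 0.99   # production balances deactivation

    def test_rejects_nonpositive_dt(self, params):
        with pytest.raises(ValueError):
            integrate_flows(MicrositeState(0, 0, 0), 0.0, params)


class TestDivisions:
    def test_excess_reserve_split_between_mother_and_daughter(self, params,
                                                              rng):
        w = params.omega_M
        site = MicrositeState(0, 0, 0, [Cell(0.4, 0.6 * w)])
        newborns = apply_divisions(site, 0.5 * w, rng, params)
        assert len(newborns) == 1
        assert site.cells[0].S == pytest.approx(0.05 * w)
        assert newborns[0].S == pytest.approx(0.05 * w)
        assert newborns[0].phi == 0.4   # p_mut = 0

    def test_below_threshold_just_accumulates(self, params, rng):
        w = params.omega_M
        site = MicrositeState(0, 0, 0, [Cell(0.5, 0.3 * w)])
        assert apply_divisions(site, 0.5 * w, rng, params) == []
        assert site.cells[0].S == pytest.approx(0.8 * w)

    def test_two_divisions_two_newborns(self, params, rng):
        w = params.omega_M
        site = MicrositeState(0, 0, 0, [Cell(0.5, 0.9 * w),
                                        Cell(0.5, 0.95 * w)])
        newborns = apply_divisions(site, 0.2 * w, rng, params)
        assert len(newborns) == 2


class TestDeath:
    def test_recycling_split(self, params, rng):
        site = MicrositeState(0, 0, 0, [Cell(0.5, 0.0)])
        apply_death(site, rng, params)
        assert site.M == 0
        assert site.c == pytest.approx(5e-10)
        assert site.d == pytest.approx(5e-10)

    def test_full_leaching_recycles_nothing(self, params, rng):
        p = params.with_(l=1.0)
        led = FlowLedger()
        site = MicrositeState(0, 0, 0, [Cell(0.5, 0.0)])
        apply_death(site, rng, p, led)
        assert site.c == 0.0 and site.d == 0.0
        assert led.leached_recycling == pytest.approx(p.omega_M)

    def test_empty_site_rejected(self, params, rng):
        with pytest.raises(ValueError):
            apply_death(MicrositeState(0, 0, 0), rng, params)


class TestSingleSite:
    def test_no_death_population_never_shrinks(self, params):
        site, _ = equilibrium_site(params, 0.5)
        run = simulate_single_site(params.with_(d_M=0.0), 0.5, T=2e4,
                                   seed=3, initial=site)
        M = run.trajectory["M"]
        assert (np.diff(M) >= 0).all()
        assert run.counters["deaths"] == 0

    def test_population_fluctuates_around_deterministic_equilibrium(
            self, params):
        ss = steady_state(params, 0.5)
        expected = ss.state.m / params.omega_M
        run = simulate_single_site(params, 0.5, T=3e5, seed=5)
        mean_M = run.trajectory["M"].mean()
        assert expected / 2 < mean_M < expected * 2

    def test_trait_distribution_frozen_without_mutation(self, params):
        run = simulate_single_site(params, 0.5, T=2e4, seed=3)
        alive = run.trajectory["M"] > 0
        assert np.all(run.trajectory["min_phi"][alive] == 0.5)
        assert np.all(run.trajectory["max_phi"][alive] == 0.5)

    def test_within_site_selection_favours_the_cheater_strain(self, params):
        """In a well-mixed site a strain that invests less in enzymes
        divides faster on the shared DOC pool, so it should fix far more
        often than the cooperator strain — the engine behind the erosion
        of enzyme allocation under mutation."""
        p = params.with_(tau_diff=1.0)
        site, _ = equilibrium_site(params, 0.5, n_cells=8)
        for idx, cell in enumerate(site.cells):
            cell.phi = 0.3 if idx % 2 == 0 else 0.7
            cell.strain_id = 0 if idx % 2 == 0 else 1
        cheat_wins = coop_wins = 0
        for seed in range(20):
            run = simulate_single_site(p, 0.5, T=2e5, seed=seed,
                                       initial=site.copy())
            tr = run.trajectory
            if tr["M"][-1] == 0:      # whole-population extinction: no winner
                continue
            if tr["M_resident"][-1] > 0 and tr["M_mutant"][-1] == 0:
                cheat_wins += 1
            elif tr["M_mutant"][-1] > 0 and tr["M_resident"][-1] == 0:
                coop_wins += 1
        assert cheat_wins >= 3
        assert cheat_wins > coop_wins

    def test_mutation_generates_trait_diversity(self, params):
        p = params.with_(p_mut=0.1, tau_diff=1.0)
        run = simulate_single_site(p, 0.5, T=2e6, with_mutation=True,
                                   seed=1)
        assert run.counters["mutations"] > 0
        tr = run.trajectory
        alive = tr["M"] > 0
        assert np.nanmin(tr["min_phi"][alive]) < 0.5

    def test_carbon_closure_of_hybrid_run(self, params):
        run = simulate_single_site(params, 0.5, T=5e4, seed=1)
        tr, led = run.trajectory, run.ledger
        def total(i):
            return (tr["c"][i] + tr["d"][i] + tr["z"][i]
                    + tr["M"][i] * params.omega_M + tr["S_total"][i])
        lhs = total(-1) - total(0)
        rhs = (led.inputs - led.leaching - led.respiration
               - led.leached_recycling + led.clip_residual)
        assert lhs == pytest.approx(rhs, abs=1e-9 * led.inputs)


class TestKernelMatchesReferenceLoop:
    def test_deterministic_limit_agrees(self, params):
        """With cell death switched off and no mutation the event loop is
        fully deterministic, so the compiled kernel and the plain-Python
        reference iteration must produce the same trajectory."""
        p = params.with_(d_M=0.0, L=1, tau_diff=1.0)
        site, ss = equilibrium_site(params, 0.5, n_cells=6)
        for cell in site.cells:        # spread reserves deterministically
            cell.S = 0.0
        ref = LatticeState([[site.copy()]])
        rng = np.random.default_rng(0)
        T = 3000.0
        while ref.t < T - 1e-9:
            step_lattice(ref, p, rng)
        run = simulate_single_site(p, 0.5, T, seed=0,
                                   initial=site.copy())
        fin = run.final.grid[0][0]
        refsite = ref.grid[0][0]
        assert fin.M == refsite.M
        assert fin.c == pytest.approx(refsite.c, rel=1e-9)
        assert fin.d == pytest.approx(refsite.d, rel=1e-9)
        assert fin.z == pytest.approx(refsite.z, rel=1e-9)
        assert sorted(c.S for c in fin.cells) == pytest.approx(
            sorted(c.S for c in refsite.cells), rel=1e-9)
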