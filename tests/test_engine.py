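"""The stochastic engine: per-molecule operations, the event-driven kernel,
the synchronous reference loop, and their equivalence."""

import math

import numpy as np
import pytest
from numba import njit
from scipy import stats

from fibrolat import (build_lattice, default_kinetics, initialize_tpa,
                      lysis_metrics, run_simulation)
from fibrolat import engine as eng
from fibrolat._kernel import _ff_1d, walk_eigensystem
from conftest import degenerate_kinetics, tiny_spec


class TestInitialization:
    def test_uniform_occupancy(self, rng):
        clot = build_lattice(nx=31, ny=31)
        mols = initialize_tpa(clot, 10_000, rng)
        counts = np.bincount([m.node for m in mols], minlength=clot.n_nodes)
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_reproducible_and_empty(self):
        clot = build_lattice(nx=5, ny=5)
        a = initialize_tpa(clot, 20, np.random.default_rng(1))
        b = initialize_tpa(clot, 20, np.random.default_rng(1))
        assert [m.node for m in a] == [m.node for m in b]
        assert initialize_tpa(clot, 0, np.random.default_rng(1)) == []
        with pytest.raises(ValueError):
            initialize_tpa(clot, -1, np.random.default_rng(1))


class TestStepOperations:
    def test_corner_moves(self, rng):
        clot = build_lattice(nx=4, ny=4)
        mol = eng.TpaMolecule(id=0, node=0)  # corner (0, 0)
        seen = set()
        for _ in range(200):
            mol.node = 0
            eng.step_unbound(mol, clot, rng)
            seen.add(mol.node)
        assert seen == {0, 1, 4}   # stay (wall) or the two interior moves

    def test_free_walk_msd(self, rng):
        # mean squared displacement ~ k steps on a wall-free region
        clot = build_lattice(nx=201, ny=201)
        k, n = 100, 300
        sq = []
        for _ in range(n):
            mol = eng.TpaMolecule(id=0, node=clot.node_id(100, 100))
            for _ in range(k):
                eng.step_unbound(mol, clot, rng)
            i, j = clot.node_ij(mol.node)
            sq.append((i - 100) ** 2 + (j - 100) ** 2)
        assert np.mean(sq) == pytest.approx(k, rel=0.15)

    def test_bind_unbind_degrade_sequence(self, rng):
        # degenerate kinetics (unbind 5 s, lysis 2 s, kinetic branch):
        # the fiber degrades at t+2 and the bound molecule rides a large FDP
        clot = build_lattice(nx=1, ny=1)
        kin = degenerate_kinetics(unbind=5.0, lysis=2.0)
        mol = eng.TpaMolecule(id=0, node=0)
        tdeg = np.full(clot.n_edges, math.inf)
        e = eng.attempt_bind(mol, clot, kin, rng, 0.0, tdeg)
        assert e == 0
        assert mol.state == eng.BOUND
        assert mol.scheduled_unbind_time == pytest.approx(5.0)
        assert tdeg[0] == pytest.approx(2.0)
        eng.degrade_fiber(clot, 0, 2.0, [mol])
        assert mol.state == eng.ON_LARGE_FDP
        assert mol.transit_start == pytest.approx(2.0)
        assert not clot.intact[0]
        with pytest.raises(RuntimeError):
            eng.degrade_fiber(clot, 0, 2.0, [mol])

    def test_bind_prob_zero_never_binds(self, rng):
        clot = build_lattice(nx=3, ny=3)
        kin = degenerate_kinetics()
        mol = eng.TpaMolecule(id=0, node=4)
        tdeg = np.full(clot.n_edges, math.inf)
        for _ in range(100):
            assert eng.attempt_bind(mol, clot, kin, rng, 0.0, tdeg,
                                    bind_prob=0.0) is None
        assert mol.state == eng.UNBOUND

    def test_large_fdp_mobility(self, rng):
        clot = build_lattice(nx=3, ny=1)
        # degrade the two x-edges; they share node 1, so they are adjacent
        clot.intact[0] = clot.intact[1] = False
        mol = eng.TpaMolecule(id=0, node=0, state=eng.ON_LARGE_FDP,
                              bound_edge=0)
        visits = {0: 0, 1: 0}
        for _ in range(400):
            eng.step_large_fdp(mol, clot, rng)
            visits[mol.bound_edge] += 1
        # exactly two adjacent openings: the rider alternates between them
        assert visits[0] > 0 and visits[1] > 0
        assert abs(visits[0] - visits[1]) <= 2

    def test_isolated_fdp_immobile(self, rng):
        clot = build_lattice(nx=3, ny=3)
        clot.intact[clot.n_x_edges + clot.n_y_edges + 4] = False  # z @ center
        mol = eng.TpaMolecule(id=0, node=4, state=eng.ON_LARGE_FDP,
                              bound_edge=clot.n_x_edges + clot.n_y_edges + 4)
        for _ in range(50):
            eng.step_large_fdp(mol, clot, rng)
            assert mol.bound_edge == clot.n_x_edges + clot.n_y_edges + 4


class TestDiffusionFastForward:
    def test_eigensystem_reconstructs_matrix_power(self):
        for L in (1, 2, 5, 9):
            Q, lam = walk_eigensystem(L)
            P = Q @ np.diag(lam) @ Q.T
            # rebuild the one-step matrix and compare the 7-step kernel
            P7 = np.linalg.matrix_power(P, 7)
            direct = Q @ np.diag(lam ** 7) @ Q.T
            np.testing.assert_allclose(P7, direct, atol=1e-12)
            np.testing.assert_allclose(P.sum(axis=1), 1.0)

    def test_ff_sampler_matches_chain_distribution(self):
        L, m, start, n = 5, 9, 2, 40_000
        Q, lam = walk_eigensystem(L)

        @njit
        def draw(n_draws, Q, lam):
            np.random.seed(99)
            out = np.empty(n_draws, np.int64)
            for i in range(n_draws):
                out[i] = _ff_1d(start, m, Q, lam)
            return out

        counts = np.bincount(draw(n, Q, lam), minlength=L)
        P = Q @ np.diag(lam) @ Q.T
        expected = np.linalg.matrix_power(P, m)[start] * n
        p = stats.chisquare(counts, expected).pvalue
        assert p > 0.001


def run_tiny(engine, seed, **kw):
    spec = tiny_spec(nx=1, ny=1, n_tpa=1, dt=1.0)
    kin = degenerate_kinetics(unbind=5.0, lysis=2.0)
    return run_simulation(spec, kin, rng_seed=seed, engine=engine,
                          max_time=50.0, **kw)


class TestEngineEquivalence:
    @pytest.mark.parametrize("engine", ["event", "stepwise"])
    def test_single_edge_hand_oracle(self, engine):
        # 1x1 lattice: the molecule binds the z-edge at the first step (t=1),
        # lysis is scheduled 2 s later, so the clot fully degrades at t=3.
        res = run_tiny(engine, seed=4)
        assert res.degrade_time_s[0] == pytest.approx(3.0)
        assert res.end_time_s == pytest.approx(3.0)
        assert not res.truncated
        assert res.n_binds == 1
        assert res.transit.duration_s.size == 0  # initial search is no transit

    def test_event_vs_stepwise_distributions(self):
        """The fast event-driven kernel and the plain synchronous loop are
        distributionally equivalent: full-lysis times over many seeds agree."""
        spec = tiny_spec(nx=2, ny=2, n_tpa=2, dt=0.5)
        kin = default_kinetics(72.7, mean_unbind_s=3.0, mean_lysis_s=5.0,
                               lysis_prob=0.8)
        ends = {}
        for engine in ("event", "stepwise"):
            ends[engine] = [
                run_simulation(spec, kin, rng_seed=s, engine=engine,
                               max_time=4000.0).end_time_s
                for s in range(90)]
            assert all(np.isfinite(ends[engine]))
        p = stats.ks_2samp(ends["event"], ends["stepwise"]).pvalue
        assert p > 0.005

    def test_transit_distribution_equivalence(self):
        spec = tiny_spec(nx=3, ny=3, n_tpa=3, dt=0.5)
        kin = default_kinetics(72.7, mean_unbind_s=2.0, mean_lysis_s=8.0,
                               lysis_prob=0.6)
        samples = {}
        for engine in ("event", "stepwise"):
            d = []
            for s in range(40):
                r = run_simulation(spec, kin, rng_seed=s, engine=engine,
                                   max_time=4000.0)
                d.extend(r.transit.duration_s)
            samples[engine] = d
        p = stats.ks_2samp(samples["event"], samples["stepwise"]).pvalue
        assert p > 0.005


class TestEngineInvariants:
    def test_determinism_and_seed_sensitivity(self):
        spec = tiny_spec(nx=6, ny=6, n_tpa=8, dt=0.5)
        kin = default_kinetics(72.7, mean_unbind_s=3.0, mean_lysis_s=6.0)
        a = run_simulation(spec, kin, rng_seed=11)
        b = run_simulation(spec, kin, rng_seed=11)
        c = run_simulation(spec, kin, rng_seed=12)
        np.testing.assert_array_equal(a.degrade_time_s, b.degrade_time_s)
        np.testing.assert_array_equal(a.transit.duration_s,
                                      b.transit.duration_s)
        assert not np.array_equal(a.degrade_time_s, c.degrade_time_s)

    def test_monotone_curve_and_completion(self):
        spec = tiny_spec(nx=10, ny=10, n_tpa=20, dt=0.5)
        kin = default_kinetics(72.7, mean_unbind_s=3.0, mean_lysis_s=6.0)
        res = run_simulation(spec, kin, rng_seed=5)
        curve = res.curve()
        assert np.all(np.diff(curve.fraction_degraded) >= 0)
        assert curve.fraction_degraded[-1] == 1.0
        assert not res.truncated
        assert np.all(res.transit.duration_s >= spec.time_step - 1e-12)
        assert np.all(res.transit.end_s <= res.end_time_s + 1e-9)

    def test_no_tpa_degrades_nothing(self):
        spec = tiny_spec(nx=4, ny=4, n_tpa=0)
        kin = default_kinetics(72.7)
        res = run_simulation(spec, kin, max_time=10.0)
        assert res.truncated
        assert np.all(np.isinf(res.degrade_time_s))

    def test_non_lytic_needs_max_time(self):
        spec = tiny_spec(nx=4, ny=4, n_tpa=4)
        kin = degenerate_kinetics(lysis_prob=0.0)
        with pytest.raises(ValueError, match="max_time"):
            run_simulation(spec, kin, max_time=None)
        res = run_simulation(spec, kin, max_time=20.0)
        assert res.truncated
        assert np.all(np.isinf(res.degrade_time_s))
        assert res.n_binds > 0

    def test_bind_prob_zero_whole_run(self):
        spec = tiny_spec(nx=4, ny=4, n_tpa=6)
        res = run_simulation(spec, default_kinetics(72.7), bind_prob=0.0,
                             max_time=20.0)
        assert res.n_binds == 0
        assert np.all(np.isinf(res.degrade_time_s))

    def test_diameter_mismatch_rejected(self):
        with pytest.raises(ValueError, match="diameter"):
            run_simulation(tiny_spec(), default_kinetics(145.4))

    def test_molecule_conservation_stepwise(self):
        spec = tiny_spec(nx=4, ny=4, n_tpa=7, dt=0.5)
        kin = default_kinetics(72.7, mean_unbind_s=2.0, mean_lysis_s=4.0)
        res = run_simulation(spec, kin, rng_seed=2, engine="stepwise",
                             max_time=3000.0)
        assert not res.truncated
        # episodes belong to existing molecules only
        assert res.transit.molecule.size == 0 or \
            res.transit.molecule.max() < spec.n_tpa

    def test_transit_on_intact_lattice_is_one_step(self):
        # with bind-on-contact, a kinetically released molecule on a fully
        # intact lattice always rebinds within one step
        spec = tiny_spec(nx=5, ny=5, n_tpa=5, dt=0.5)
        kin = degenerate_kinetics(unbind=2.0, lysis=1.0, lysis_prob=0.0,
                                  q=1e-12)
        res = run_simulation(spec, kin, max_time=60.0)
        assert res.transit.duration_s.size > 0
        np.testing.assert_allclose(res.transit.duration_s, spec.time_step)

    def test_more_tpa_is_never_slower(self):
        spec_lo = tiny_spec(nx=13, ny=13, n_tpa=15, dt=0.5)
        spec_hi = tiny_spec(nx=13, ny=13, n_tpa=150, dt=0.5)
        kin = default_kinetics(72.7, mean_unbind_s=5.0, mean_lysis_s=20.0)
        t50 = {}
        for name, spec in (("lo", spec_lo), ("hi", spec_hi)):
            vals = []
            for s in range(3):
                res = run_simulation(spec, kin, rng_seed=40 + s)
                vals.append(lysis_metrics(res.curve()).t50)
            t50[name] = np.mean(vals)
        assert t50["hi"] <= t50["lo"]
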