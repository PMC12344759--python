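"""Softcore potentials, lambda schedules, free-energy estimators, networks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deskmd.alchemy import (
    LambdaSchedule,
    TaggedSoftcoreHamiltonian,
    WorkRecord,
    bar_estimate,
    crooks_estimate,
    fep_estimate,
    free_energy_estimate,
    gauss_legendre_01,
    jarzynski_estimate,
    network_solve,
    schedule_eval,
    smoothstep_weight,
    softcore_pair_energy,
    ti_estimate,
)
from deskmd.model_core import pair_energy


class TestSmoothstep:
    @pytest.mark.parametrize("order", [1, 3, 5])
    def test_boundary_conditions(self, order):
        assert smoothstep_weight(0.0, order) == 0.0
        assert smoothstep_weight(1.0, order) == 1.0

    def test_midpoint_symmetry_order5(self):
        assert smoothstep_weight(0.5, 5) == pytest.approx(0.5)

    @pytest.mark.parametrize("order, tol", [(3, 1e-4), (5, 1e-8)])
    def test_vanishing_end_derivatives(self, order, tol):
        # one-sided finite difference; its truncation error scales with the
        # first non-vanishing derivative, hence the looser order-3 tolerance
        h = 1e-5
        d0 = (smoothstep_weight(h, order) - smoothstep_weight(0.0, order)) / h
        d1 = (smoothstep_weight(1.0, order) - smoothstep_weight(1.0 - h, order)) / h
        assert abs(d0) < tol
        assert abs(d1) < tol

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            smoothstep_weight(1.2, 3)


class TestSoftcore:
    def test_end_state_identity_lambda_one(self):
        for r in (0.8, 1.0, 1.7, 2.5):
            lj, coul, tot = softcore_pair_energy(r, 1.0, eps=1.0, sigma=1.0,
                                                 qq=0.6, alpha=0.5, beta_sc=1.0)
            ref = pair_energy(r, 4.0, 4.0, 0.0, 0.6)
            assert tot == pytest.approx(ref.total, rel=1e-12)

    def test_lambda_zero_fully_decoupled(self):
        assert softcore_pair_energy(0.0, 0.0, qq=3.0)[2] == 0.0
        assert softcore_pair_energy(1.3, 0.0, qq=3.0)[2] == 0.0

    def test_finite_at_contact_hand_value(self):
        lj, _, _ = softcore_pair_energy(0.0, 0.5, eps=1.0, sigma=1.0, alpha=0.5)
        assert lj == pytest.approx(24.0)  # 4*0.5*((0.25)^-2 - (0.25)^-1)

    @given(lam=st.floats(0.01, 0.99), r=st.floats(0.0, 3.0))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_finite_below_end_state(self, lam, r):
        lj, coul, tot = softcore_pair_energy(r, lam, qq=1.0, alpha=0.5, beta_sc=1.0)
        assert np.isfinite(tot)
        assert abs(lj) <= 4.0 / (0.5 * (1 - lam)) ** 2 / min(lam, 1.0) * 4 + 1e9

    def test_repulsive_branch_monotone_in_lambda(self):
        # inside the core (r << sigma) the energy grows with coupling
        vals = [softcore_pair_energy(0.3, lam, alpha=0.5)[0]
                for lam in np.linspace(0.1, 1.0, 10)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_negative_softcore_params_rejected(self):
        with pytest.raises(ValueError):
            softcore_pair_energy(1.0, 0.5, alpha=-0.1)


class TestSchedule:
    def _decharge_vdw_recharge(self, order=1):
        return LambdaSchedule(
            {"decharge": (0.0, 1 / 3), "vdw": (1 / 3, 2 / 3), "recharge": (2 / 3, 1.0)},
            mixing_order=order,
        )

    def test_staged_transformation_subinterval_arithmetic(self):
        sched = self._decharge_vdw_recharge()
        out = schedule_eval(sched, 0.5)
        assert out["decharge"][0] == pytest.approx(1.0)
        assert out["vdw"][0] == pytest.approx(0.5)
        assert out["recharge"][0] == pytest.approx(0.0)

    def test_end_states(self):
        sched = self._decharge_vdw_recharge(order=5)
        for name, (raw, w) in schedule_eval(sched, 0.0).items():
            assert raw == 0.0 and w == 0.0
        for name, (raw, w) in schedule_eval(sched, 1.0).items():
            assert raw == 1.0 and w == 1.0

    def test_single_term_linear_is_identity(self):
        sched = LambdaSchedule({"all": (0.0, 1.0)}, mixing_order=1)
        for lam in (0.0, 0.25, 0.7, 1.0):
            raw, w = schedule_eval(sched, lam)["all"]
            assert raw == pytest.approx(lam) and w == pytest.approx(lam)

    def test_invalid_subinterval_rejected(self):
        with pytest.raises(ValueError):
            LambdaSchedule({"bad": (0.5, 0.5)})


def harmonic_dg(k0=1.0, k1=4.0, kt=1.0):
    """Closed form for mutating a 1D harmonic spring k0 -> k1."""
    return 0.5 * kt * math.log(k1 / k0)


class TestEstimators:
    def test_fep_zero_du_gives_zero(self):
        assert fep_estimate(np.zeros(100)) == 0.0

    def test_ti_harmonic_mutation_analytic_integrand(self):
        # U(lam) = 0.5*k(lam)*x^2, k = (1-lam)*1 + lam*4
        # <dU/dlam> = 0.5*(k1-k0)*kT/k(lam); integral = 0.5*ln 4
        nodes, _ = gauss_legendre_01(12)
        means = 0.5 * 3.0 / ((1 - nodes) * 1.0 + nodes * 4.0)
        dg, unc = free_energy_estimate("TI", {"nodes": nodes, "dudl_means": means})
        assert dg == pytest.approx(harmonic_dg(), abs=1e-3)
        assert unc == 0.0

    def test_instantaneous_jarzynski_equals_fep(self):
        rng = np.random.default_rng(0)
        du = rng.normal(1.0, 0.5, 400)
        assert jarzynski_estimate(du) == pytest.approx(fep_estimate(du), abs=1e-14)

    def test_crooks_symmetric_distributions_give_zero(self):
        rng = np.random.default_rng(1)
        w = rng.normal(2.0, 1.0, 2000)
        fwd = WorkRecord("forward", w)
        rev = WorkRecord("reverse", -w + 4.0)  # mirror about dG = 2 then shift
        # mirror-symmetric about zero: dG = 0
        sym_f = WorkRecord("forward", rng.normal(1.0, 0.8, 3000))
        sym_r = WorkRecord("reverse", -sym_f.work + 2.0)
        dg0 = crooks_estimate(WorkRecord("forward", w), WorkRecord("reverse", w))
        assert dg0 == pytest.approx(0.0, abs=0.1)

    def test_bar_exact_on_gaussian_work(self):
        # Gaussian forward work N(mu, s): dG = mu - s^2/2 (beta = 1); reverse
        # work is then N(-mu + s^2, s) by Crooks
        mu, s, dg = 3.0, 1.0, 2.5
        rng = np.random.default_rng(2)
        wf = rng.normal(mu, s, 20_000)
        wr = rng.normal(-(mu - s * s), s, 20_000)
        assert bar_estimate(wf, wr) == pytest.approx(dg, abs=0.05)

    def test_estimator_concordance_harmonic_mutation(self):
        # sampled FEP / BAR / Jarzynski against the 0.5*ln 4 closed form
        k0, k1, kt = 1.0, 4.0, 1.0
        n_win, n_samp = 11, 800
        ks = np.linspace(k0, k1, n_win)
        rng = np.random.default_rng(3)
        dg_fep = dg_bar = 0.0
        fep_var = 0.0
        for a, b in zip(ks[:-1], ks[1:]):
            x = rng.normal(0.0, math.sqrt(kt / a), n_samp)
            du_f = 0.5 * (b - a) * x * x
            y = rng.normal(0.0, math.sqrt(kt / b), n_samp)
            du_r = 0.5 * (a - b) * y * y
            dg_fep += fep_estimate(du_f, 1 / kt)
            dg_bar += bar_estimate(du_f, du_r, 1 / kt)
        exact = harmonic_dg(k0, k1, kt)
        assert dg_fep == pytest.approx(exact, abs=0.03)
        assert dg_bar == pytest.approx(exact, abs=0.02)
        # instantaneous-switching Jarzynski over the same ladder = FEP
        assert abs(dg_bar - dg_fep) < 0.05

    def test_jensen_bound_jarzynski_below_mean_work(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            w = rng.normal(2.0, 1.2, 500)
            assert jarzynski_estimate(w) <= w.mean() + 1e-12

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            fep_estimate(np.array([]))
        with pytest.raises(ValueError):
            ti_estimate(np.array([0.5]), np.array([1.0]))
        with pytest.raises(ValueError):
            bar_estimate(np.array([]), np.array([1.0]))

    def test_bootstrap_uncertainty_positive_for_noisy_data(self):
        rng = np.random.default_rng(5)
        dg, unc = free_energy_estimate("FEP", {"du": rng.normal(1, 1, 500)})
        assert unc > 0.0


class TestTaggedSoftcore:
    def _fluid(self, n=32, seed=9):
        from deskmd import make_fixture

        return make_fixture("lj_fluid", {"n": n, "density": 0.3,
                                         "temperature": 1.2}, seed)

    def test_end_state_identity_against_full_system(self):
        from deskmd.model_core import total_energy_bruteforce

        sys_, st, _ = self._fluid()
        ham = TaggedSoftcoreHamiltonian(sys_, tagged=0)
        e_full = sum(total_energy_bruteforce(st, sys_).values())
        assert ham.energy(st.positions, st.box, 1.0) == pytest.approx(e_full, rel=1e-12)

    def test_decoupled_state_ignores_tagged_particle(self):
        sys_, st, _ = self._fluid()
        ham = TaggedSoftcoreHamiltonian(sys_, tagged=0)
        e0 = ham.energy(st.positions, st.box, 0.0)
        moved = st.positions.copy()
        moved[0] += 1.3  # move the ghost particle; nothing may change
        assert ham.energy(moved, st.box, 0.0) == pytest.approx(e0, rel=1e-12)

    @pytest.mark.parametrize("lam", [0.3, 0.8, 1.0])
    def test_forces_match_finite_differences(self, lam):
        sys_, st, _ = self._fluid(n=16)
        ham = TaggedSoftcoreHamiltonian(sys_, tagged=0)
        ff = ham.force_field(lam)
        _, f = ff(st.positions, st.box)
        h = 1e-6
        for p in (0, 3):
            for ax in range(3):
                pp, pm = st.positions.copy(), st.positions.copy()
                pp[p, ax] += h
                pm[p, ax] -= h
                fd = -(ham.energy(pp, st.box, lam) - ham.energy(pm, st.box, lam)) / (2 * h)
                assert f[p, ax] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_estimator_concordance_lj_decoupling_hremd(self):
        # decouple one LJ particle from a 32-particle fluid by H-REMD over a
        # lambda ladder; TI, summed FEP and summed BAR must agree within
        # their mutual statistical uncertainties
        from deskmd import stream
        from deskmd.integrators import Integrator, IntegratorConfig
        from deskmd.model_core import EnsembleParams
        from deskmd.remd import RemdProblem, ReplicaLayout, demux_trajectories, run_remd

        sys_, st0, _ = self._fluid()
        kt = 1.2
        ham = TaggedSoftcoreHamiltonian(sys_, tagged=0)
        lams = np.linspace(0.0, 1.0, 6)
        ffs = {float(l): ham.force_field(float(l)) for l in lams}

        def propagate(state, ens, rng, _w):
            cfg = IntegratorConfig(0.004, "langevin_middle", 1.0, kt)
            return Integrator(sys_, cfg, ffs[ens.lam[0]], rng).run(state, 25)

        def energy(state, ens):
            return ham.energy(state.positions, state.box, ens.lam[0])

        layout = ReplicaLayout.one_dimensional(
            "lambda", [EnsembleParams(beta=1.0 / kt, lam=(float(l),)) for l in lams])
        rng = stream(31, "aces")
        states = [st0.copy() for _ in lams]
        res = run_remd(layout, RemdProblem(propagate, energy), states, 220, rng)
        assert res.acceptance_rate > 0.1
        frames = demux_trajectories(res.walker_frames, res.labels_history)

        burn = 20
        dudl_means, dudl_se = [], []
        fep_sum = bar_sum = 0.0
        fep_var = 0.0
        per_ens = [np.array(frames[k][burn:]) for k in range(len(lams))]
        box = st0.box
        for k, lam in enumerate(lams):
            vals = np.array([ham.dudl(p, box, float(lam)) for p in per_ens[k]])
            dudl_means.append(vals.mean())
            dudl_se.append(vals.std() / math.sqrt(len(vals) / 10.0))  # corr. factor
        for k in range(len(lams) - 1):
            la, lb = float(lams[k]), float(lams[k + 1])
            du_f = np.array([ham.energy(p, box, lb) - ham.energy(p, box, la)
                             for p in per_ens[k]]) / kt
            du_r = np.array([ham.energy(p, box, la) - ham.energy(p, box, lb)
                             for p in per_ens[k + 1]]) / kt
            fep_sum += kt * fep_estimate(du_f)
            bar_sum += kt * bar_estimate(du_f, du_r)
            fep_var += (kt**2) * np.var(du_f) / (len(du_f) / 10.0)
        dg_ti = float(np.trapezoid(dudl_means, lams))
        se_ti = float(np.sqrt(np.trapezoid(np.square(dudl_se), lams)))
        tol = 3.0 * math.sqrt(se_ti**2 + fep_var) + 0.1
        assert abs(dg_ti - bar_sum) < tol
        assert abs(fep_sum - bar_sum) < tol


class TestNetwork:
    def test_single_edge(self):
        res = network_solve([("A", "B", 2.0, 1.0)])
        assert res.node_values["B"] - res.node_values["A"] == pytest.approx(2.0)
        assert res.edge_residuals[0][3] == pytest.approx(0.0)

    def test_consistent_triangle_zero_closure(self):
        edges = [("A", "B", 1.0, 1.0), ("B", "C", 2.0, 1.0), ("A", "C", 3.0, 1.0)]
        res = network_solve(edges)
        (cycle, closure), = res.cycle_residuals
        assert closure == pytest.approx(0.0, abs=1e-12)
        for *_ , resid in res.edge_residuals:
            assert resid == pytest.approx(0.0, abs=1e-12)

    def test_inconsistent_triangle_spreads_residual(self):
        edges = [("A", "B", 1.0, 1.0), ("B", "C", 2.0, 1.0), ("A", "C", 3.3, 1.0)]
        res = network_solve(edges)
        resids = sorted(abs(r) for *_, r in res.edge_residuals)
        assert np.allclose(resids, [0.1, 0.1, 0.1], atol=1e-10)
        (cycle, closure), = res.cycle_residuals
        assert abs(closure) == pytest.approx(0.3, abs=1e-12)

    def test_anchor_fixes_gauge(self):
        edges = [("A", "B", 2.0, 1.0)]
        res = network_solve(edges, anchors={"A": 10.0})
        assert res.node_values["A"] == pytest.approx(10.0, abs=1e-6)
        assert res.node_values["B"] == pytest.approx(12.0, abs=1e-6)
        assert not res.gauge_warnings

    def test_disconnected_components_warned_and_zero_meaned(self):
        edges = [("A", "B", 2.0, 1.0), ("C", "D", 1.0, 1.0)]
        res = network_solve(edges)
        assert len(res.gauge_warnings) == 2
        assert res.node_values["A"] + res.node_values["B"] == pytest.approx(0.0)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            network_solve([("A", "B", 1.0, 0.0)])
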