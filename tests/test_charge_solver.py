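"""Newton solver: residuals, Jacobian, convergence and oracle equivalence."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from pcp import (Atom, ElectronDistribution, ElementParams, Molecule,
                 NonConvergenceError, ParameterSet, distance_matrix,
                 make_toy_system, molecular_energy, pcpp_all, solve_charges)
from pcp.charge_solver import jacobian, residuals

EA = ElementParams.from_IA("Xa", I=10.0, A=2.0, N0=3)
EB = ElementParams.from_IA("Xb", I=14.0, A=1.0, N0=5)


def transfer_energy(ts, deltas):
    """Oracle energy as a function of electron transfer off neutrality.

    deltas has n-1 entries; the last atom balances the books.
    """
    mol, params = ts.molecule, ts.params
    N0, _, _ = params.element_arrays(mol)
    d = np.append(deltas, -np.sum(deltas))
    N = N0 + d
    if np.any(N <= 0):
        return np.inf
    return molecular_energy(mol, ElectronDistribution.from_N(N, N0),
                            ts.R, params)


class TestResiduals:
    def test_isolated_neutral_atom_zero(self):
        mol = Molecule([Atom("Xa", 0, 0, 0)])
        params = ParameterSet(elements={"Xa": EA})
        x = np.array([0.0, EA.mu0])
        np.testing.assert_allclose(
            residuals(x, mol, distance_matrix(mol), params), 0.0, atol=1e-14)

    def test_neutral_homonuclear_zero(self):
        mol = Molecule([Atom("Xa", 0, 0, 0), Atom("Xa", 2, 0, 0)])
        params = ParameterSet(elements={"Xa": EA}, pairs={("Xa", "Xa"): 6.0})
        x = np.array([0.0, 0.0, EA.mu0])
        np.testing.assert_allclose(
            residuals(x, mol, distance_matrix(mol), params), 0.0, atol=1e-14)

    def test_matches_energy_model_pcpp(self):
        """Cross-module oracle: residual_i == pcpp_i - mu_M, and the last
        entry is the conservation defect."""
        ts = make_toy_system(4, seed=3)
        mol, params = ts.molecule, ts.params
        N0, _, _ = params.element_arrays(mol)
        rng = np.random.default_rng(5)
        Na = rng.uniform(-0.05, 0.05, 4)
        muM = -9.0
        x = np.append(Na, muM)
        r = residuals(x, mol, ts.R, params)
        dist = ElectronDistribution.from_Na(Na, N0)
        mus = pcpp_all(mol, dist, ts.R, params)
        np.testing.assert_allclose(r[:-1], mus - muM, rtol=1e-12)
        assert r[-1] == pytest.approx(dist.q.sum(), abs=1e-12)


class TestJacobian:
    def test_zero_k_gives_diagonal_gamma_block(self):
        mol = Molecule([Atom("Xa", 0, 0, 0), Atom("Xb", 2, 0, 0)])
        params = ParameterSet(elements={"Xa": EA, "Xb": EB},
                              pairs={("Xa", "Xb"): 0.0})
        J = jacobian(np.zeros(3), mol, distance_matrix(mol), params)
        np.testing.assert_allclose(J[:2, :2],
                                   np.diag([EA.gamma, EB.gamma]), atol=1e-14)

    def test_single_atom_closed_form(self):
        mol = Molecule([Atom("Xa", 0, 0, 0)])
        params = ParameterSet(elements={"Xa": EA})
        J = jacobian(np.array([0.0, EA.mu0]), mol, distance_matrix(mol),
                     params)
        np.testing.assert_allclose(
            J, [[EA.gamma, -1.0], [-EA.N0, 0.0]], atol=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, seed):
        ts = make_toy_system(4, seed=seed)
        mol, params = ts.molecule, ts.params
        rng = np.random.default_rng(seed)
        x = np.append(rng.uniform(-0.1, 0.1, 4), -10.0)
        J = jacobian(x, mol, ts.R, params)
        h = 1e-7
        for j in range(5):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fd = (residuals(xp, mol, ts.R, params)
                  - residuals(xm, mol, ts.R, params)) / (2 * h)
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-5, atol=1e-6)


class TestSolveCharges:
    def test_isolated_atom(self):
        mol = Molecule([Atom("Xa", 0, 0, 0)])
        sol = solve_charges(mol, ParameterSet(elements={"Xa": EA}))
        assert sol.q[0] == pytest.approx(0.0, abs=1e-12)
        assert sol.N[0] == pytest.approx(EA.N0, abs=1e-12)
        assert sol.muM == pytest.approx(EA.mu0, abs=1e-10)

    def test_homonuclear_symmetry(self):
        ts = make_toy_system(2, seed=7, homonuclear=True)
        sol = solve_charges(ts.molecule, ts.params)
        np.testing.assert_allclose(sol.q, 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_two_atom_matches_grid_oracle(self, seed):
        """Constrained 1-D minimization oracle: dense grid over the charge
        transfer followed by bounded scalar refinement."""
        ts = make_toy_system(2, seed=seed)
        sol = solve_charges(ts.molecule, ts.params)
        grid = np.linspace(-1.5, 1.5, 3001)
        E = [transfer_energy(ts, [d]) for d in grid]
        i = int(np.argmin(E))
        res = minimize_scalar(lambda d: transfer_energy(ts, [d]),
                              bounds=(grid[max(i - 1, 0)],
                                      grid[min(i + 1, len(grid) - 1)]),
                              method="bounded", options={"xatol": 1e-10})
        assert sol.q[0] == pytest.approx(-res.x, abs=1e-4)

    @pytest.mark.parametrize("seed", range(3))
    def test_three_atom_matches_grid_oracle(self, seed):
        ts = make_toy_system(3, seed=seed)
        sol = solve_charges(ts.molecule, ts.params)
        g = np.linspace(-1.2, 1.2, 49)
        best, bd = np.inf, None
        for a in g:
            for b in g:
                e = transfer_energy(ts, [a, b])
                if e < best:
                    best, bd = e, (a, b)
        res = minimize(lambda d: transfer_energy(ts, d), bd,
                       method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-12})
        d = np.append(res.x, -np.sum(res.x))
        np.testing.assert_allclose(sol.q, -d, atol=1e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_equalization(self, seed):
        ts = make_toy_system(2 + seed % 5, seed=100 + seed)
        sol = solve_charges(ts.molecule, ts.params)
        assert abs(sol.q.sum()) <= 1e-8
        mus = pcpp_all(ts.molecule, sol.distribution, ts.R, ts.params)
        assert np.abs(mus - sol.muM).max() <= 1e-9

    def test_nonzero_net_charge_conserved(self):
        ts = make_toy_system(3, seed=5, net_charge=1)
        sol = solve_charges(ts.molecule, ts.params)
        assert sol.q.sum() == pytest.approx(1.0, abs=1e-8)

    def test_solution_beats_random_feasible_perturbations(self):
        ts = make_toy_system(4, seed=11)
        sol = solve_charges(ts.molecule, ts.params)
        N0, _, _ = ts.params.element_arrays(ts.molecule)
        rng = np.random.default_rng(0)
        for _ in range(100):
            d = rng.uniform(-0.2, 0.2, 3)
            N = sol.N + np.append(d, -d.sum())
            if np.any(N <= 0):
                continue
            E = molecular_energy(ts.molecule,
                                 ElectronDistribution.from_N(N, N0),
                                 ts.R, ts.params)
            assert sol.EM <= E + 1e-12

    def test_geometry_independent_when_k_zero(self):
        ts = make_toy_system(3, seed=13)
        params = ts.params.with_pairs({p: 0.0 for p in ts.params.pairs})
        sol1 = solve_charges(ts.molecule, params)
        stretched = Molecule([Atom(a.element, 3 * a.x, 3 * a.y, 3 * a.z)
                              for a in ts.molecule.atoms])
        sol2 = solve_charges(stretched, params)
        np.testing.assert_allclose(sol1.q, sol2.q, atol=1e-12)

    def test_deterministic_bitwise(self):
        ts = make_toy_system(4, seed=21)
        a = solve_charges(ts.molecule, ts.params)
        b = solve_charges(ts.molecule, ts.params)
        assert np.array_equal(a.q, b.q) and a.EM == b.EM
        assert a.iterations == b.iterations

    def test_em_matches_energy_model(self):
        ts = make_toy_system(3, seed=17)
        sol = solve_charges(ts.molecule, ts.params)
        assert sol.EM == pytest.approx(
            molecular_energy(ts.molecule, sol.distribution, ts.R, ts.params),
            rel=1e-14)

    def test_nonfinite_parameters_rejected(self):
        mol = Molecule([Atom("Xa", 0, 0, 0), Atom("Xb", 2, 0, 0)])
        bad = ElementParams("Xb", 5, 14.0, 1.0, float("nan"), -12.0)
        params = ParameterSet(elements={"Xa": EA, "Xb": bad},
                              pairs={("Xa", "Xb"): 5.0})
        with pytest.raises(ValueError, match="non-finite"):
            solve_charges(mol, params)

    def test_runaway_system_raises_with_history(self):
        # enormous site-potential mismatch with strong coupling: the energy
        # has no interior minimum and the iteration must fail loudly
        e1 = ElementParams("Xa", 1, 0.0, 0.0, 5.09, -10.14)
        e2 = ElementParams("Xb", 7, 0.0, 0.0, 93.65, -100.38)
        e3 = ElementParams("Xc", 5, 0.0, 0.0, 58.73, -67.08)
        mol = Molecule([Atom("Xa", 0, 0, 0), Atom("Xb", 3.64, 0, 0),
                        Atom("Xc", 1.2046, 1.1421, 0)])
        params = ParameterSet(
            elements={"Xa": e1, "Xb": e2, "Xc": e3},
            pairs={("Xa", "Xb"): 21.55, ("Xa", "Xc"): 17.63,
                   ("Xb", "Xc"): 12.09})
        with pytest.raises(NonConvergenceError) as exc:
            solve_charges(mol, params, max_iter=50)
        assert len(exc.value.history) > 0
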