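"""Ground-state charge distribution by damped Newton-Raphson.

The ground state of the molecular energy model under fixed total electron
count is characterized by chemical-potential equalization: every atom's
in-molecule chemical potential equals a single molecular value mu_M, and
the charges sum to the net molecular charge.  The unknowns are solved in
the log variables Na_i = ln(N_i/N0_i), so every iterate automatically
keeps N_i > 0 (iterating in N itself can step negative and then the
logarithm is undefined).  The unknown vector is x = (Na_1..Na_n, mu_M)
and the n+1 residuals are

    r_i     = -mu_M + mu0_i + gamma_i Na_i
              - s * sum_{j != i} k_ij N0_j (1 - exp(Na_j)) / R_ij
    r_{n+1} = sum_i N0_i (1 - exp(Na_i)) - net_charge,

with analytic Jacobian.  A plain Newton step can overshoot for large k or
small R, so each step is halved (up to 30 times) until the residual
infinity-norm decreases.  Initialization: Na = 0, mu_M = mean(mu0).
The solve is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy_model import ElectronDistribution, ParameterSet, molecular_energy
from .errors import NonConvergenceError, SingularJacobianError
from .molecule_io import Molecule, distance_matrix

__all__ = ["ChargeSolution", "residuals", "jacobian", "solve_charges"]

DEFAULT_TOL = 1e-10  # eV, residual infinity-norm
DEFAULT_MAX_ITER = 100
_MAX_HALVINGS = 30
_MAX_LOG_STEP = 20.0  # max |delta Na| per iteration before damping


@dataclass
class ChargeSolution:
    """Converged electron distribution of one molecule.

    Attributes
    ----------
    Na, N, q : arrays in atom order (dimensionless, e, e)
    muM : equalized molecular chemical potential (eV)
    EM : molecular energy at the solution (eV)
    iterations : Newton iterations taken
    residual_inf_norm : final residual infinity-norm (eV)
    converged : whether the tolerance was met
    residual_history : per-iteration residual norms (diagnostic)
    """

    Na: np.ndarray
    N: np.ndarray
    q: np.ndarray
    muM: float
    EM: float
    iterations: int
    residual_inf_norm: float
    converged: bool
    residual_history: list[float]

    @property
    def distribution(self) -> ElectronDistribution:
        return ElectronDistribution(N=self.N, q=self.q, Na=self.Na)


def _system_arrays(mol: Molecule, R: np.ndarray, params: ParameterSet):
    N0, gamma, mu0 = params.element_arrays(mol)
    K = params.k_matrix(mol)
    n = len(mol)
    KoverR = np.zeros((n, n))
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        KoverR[off] = K[off] / R[off]
    return N0, gamma, mu0, KoverR


def residuals(x: np.ndarray, mol: Molecule, R: np.ndarray,
              params: ParameterSet, net_charge: float = 0.0) -> np.ndarray:
    """The n+1 residuals at unknown vector x = (Na_1..Na_n, mu_M).

    First n entries are mu_i^M - mu_M (eV); the last is the conservation
    defect sum(q) - net_charge (e).
    """
    N0, gamma, mu0, KoverR = _system_arrays(mol, R, params)
    Na, muM = x[:-1], x[-1]
    with np.errstate(over="ignore", invalid="ignore"):
        q = N0 * (1.0 - np.exp(Na))
        r = np.empty(len(Na) + 1)
        r[:-1] = -muM + mu0 + gamma * Na - params.interaction_sign * (KoverR @ q)
        r[-1] = q.sum() - net_charge
    return r


def jacobian(x: np.ndarray, mol: Molecule, R: np.ndarray,
             params: ParameterSet) -> np.ndarray:
    """Analytic (n+1) x (n+1) Jacobian of :func:`residuals` at x."""
    N0, gamma, mu0, KoverR = _system_arrays(mol, R, params)
    Na = x[:-1]
    n = len(Na)
    expNa = np.exp(Na)
    J = np.zeros((n + 1, n + 1))
    # d r_i / d Na_j = s * k_ij N0_j exp(Na_j) / R_ij for j != i
    J[:n, :n] = params.interaction_sign * KoverR * (N0 * expNa)[None, :]
    J[np.arange(n), np.arange(n)] = gamma
    J[:n, n] = -1.0
    J[n, :n] = -N0 * expNa
    return J


def solve_charges(mol: Molecule, params: ParameterSet, *,
                  R: np.ndarray | None = None,
                  tol: float = DEFAULT_TOL,
                  max_iter: int = DEFAULT_MAX_ITER) -> ChargeSolution:
    """Solve the equalization + conservation system for one molecule.

    Raises
    ------
    NonConvergenceError
        If the residual norm has not met ``tol`` after ``max_iter``
        damped-Newton iterations (the error carries the residual history).
    SingularJacobianError
        If the Newton linear system is singular.
    """
    N0, gamma, mu0 = params.element_arrays(mol)
    if not (np.all(np.isfinite(gamma)) and np.all(np.isfinite(mu0))):
        raise ValueError("non-finite element parameters")
    if R is None:
        R = distance_matrix(mol)
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("non-finite distance matrix")
    net = float(mol.net_charge)
    n = len(mol)

    x = np.zeros(n + 1)
    x[-1] = mu0.mean()
    r = residuals(x, mol, R, params, net)
    norm = float(np.abs(r).max())
    history = [norm]

    it = 0
    while norm > tol and it < max_iter:
        J = jacobian(x, mol, R, params)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise SingularJacobianError(
                f"singular Newton system at iteration {it}: {exc}; "
                "check the geometry and pair parameters"
            ) from exc
        # cap the log-variable step so exp() cannot overflow on wild iterates
        step_inf = float(np.abs(step[:-1]).max()) if n else 0.0
        t = min(1.0, _MAX_LOG_STEP / step_inf) if step_inf > _MAX_LOG_STEP \
            else 1.0
        for _ in range(_MAX_HALVINGS + 1):
            r_new = residuals(x + t * step, mol, R, params, net)
            norm_new = float(np.abs(r_new).max())
            if norm_new < norm:
                break
            t *= 0.5
        else:
            raise NonConvergenceError(
                f"damped Newton stagnated at iteration {it} "
                f"(residual inf-norm {norm:.3e})", history
            )
        x = x + t * step
        r, norm = r_new, norm_new
        history.append(norm)
        it += 1

    if norm > tol:
        raise NonConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(residual inf-norm {norm:.3e})", history
        )

    Na, muM = x[:-1], float(x[-1])
    dist = ElectronDistribution.from_Na(Na, N0)
    EM = molecular_energy(mol, dist, R, params)
    return ChargeSolution(
        Na=Na, N=dist.N, q=dist.q, muM=muM, EM=EM, iterations=it,
        residual_inf_norm=norm, converged=True, residual_history=history,
    )
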