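"""Least-squares estimation of pairwise interaction parameters.

The k values of the energy model are fitted so that the solved charges
(and optionally energies) of a training set of molecules reproduce
reference values — in the original application, ab initio HF/STO-3G
Mulliken charges and total energies.  The objective is

    sum_molecules [ w_q * sum_atoms (q_calc - q_ref)^2
                    + w_E * (E_calc - E_ref)^2 ]

where q_calc and E_calc come from the charge solver at the candidate k.
The optimization is a finite-difference trust-region least squares over
the free k vector: the inner solve is not guaranteed differentiable at
penalized points (a candidate k for which some training molecule fails to
converge contributes a large finite residual instead of aborting the fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .charge_solver import solve_charges
from .energy_model import COULOMB_EV_ANGSTROM, ParameterSet, pair_key
from .errors import PCPError
from .molecule_io import Molecule

__all__ = ["TrainingMolecule", "FitProblem", "FitResult",
           "fit_pair_parameters", "read_reference_charges",
           "read_reference_energies"]

_PENALTY = 1.0e3  # residual assigned per entry when the inner solve fails
DEFAULT_ENERGY_WEIGHT_SCALE = 1.0e-2  # w_E = scale / n_atoms per molecule


@dataclass
class TrainingMolecule:
    molecule: Molecule
    q_ref: np.ndarray                 # per-atom reference charges (e)
    E_ref: float | None = None        # optional reference energy (eV)

    def __post_init__(self):
        self.q_ref = np.asarray(self.q_ref, dtype=float)
        if len(self.q_ref) != len(self.molecule):
            raise ValueError(
                f"{self.molecule.name!r}: {len(self.q_ref)} reference charges "
                f"for {len(self.molecule)} atoms"
            )


@dataclass
class FitProblem:
    """Training set, free parameters and weighting of one fit.

    ``w_E = None`` selects the default per-molecule energy weight
    1e-2 / n_atoms (charges dominate, energies regularize); set 0 to fit
    charges only.  Bounds are per-pair (lo, hi) in eV*Angstrom.
    """

    training: list[TrainingMolecule]
    free_pairs: list[tuple[str, str]]
    w_q: float = 1.0
    w_E: float | None = None
    bounds: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict)

    def __post_init__(self):
        self.free_pairs = [pair_key(*p) for p in self.free_pairs]
        if not self.free_pairs:
            raise ValueError("empty free-parameter set")
        if self.w_q < 0 or (self.w_E is not None and self.w_E < 0):
            raise ValueError("weights must be non-negative")
        if self.w_q == 0 and self.w_E == 0:
            raise ValueError("at least one weight must be positive")

    def energy_weight(self, tm: TrainingMolecule) -> float:
        if self.w_E is not None:
            return self.w_E
        return DEFAULT_ENERGY_WEIGHT_SCALE / len(tm.molecule)


@dataclass
class FitResult:
    params: ParameterSet
    objective: float
    start_objective: float
    per_molecule: pd.DataFrame  # name, charge_rms_e, energy_residual_eV
    n_evaluations: int
    success: bool
    message: str

    @property
    def fitted_k(self) -> dict[tuple[str, str], float]:
        return dict(self.params.pairs)


def _molecule_residuals(tm: TrainingMolecule, problem: FitProblem,
                        params: ParameterSet) -> np.ndarray:
    n_entries = len(tm.molecule) + (1 if tm.E_ref is not None else 0)
    try:
        sol = solve_charges(tm.molecule, params)
    except (PCPError, np.linalg.LinAlgError):
        return np.full(n_entries, _PENALTY)
    res = list(np.sqrt(problem.w_q) * (sol.q - tm.q_ref))
    if tm.E_ref is not None:
        res.append(np.sqrt(problem.energy_weight(tm)) * (sol.EM - tm.E_ref))
    return np.asarray(res)


def fit_pair_parameters(problem: FitProblem, start: ParameterSet, *,
                        xtol: float = 1e-12, ftol: float = 1e-14,
                        gtol: float = 1e-12, max_nfev: int | None = None,
                        diff_step: float = 1e-6) -> FitResult:
    """Fit the free k values of ``start`` against the training references.

    Every objective evaluation solves all training molecules at the
    candidate k; a non-convergent candidate is penalized, not fatal.
    Pairs occurring in the training set but not free must already be in
    ``start``; free pairs missing there start at the bare Coulomb
    constant (14.3996 eV*Angstrom).
    """
    free = problem.free_pairs
    x0 = np.array([start.pairs.get(p, COULOMB_EV_ANGSTROM) for p in free])
    lo = np.array([problem.bounds.get(p, (-np.inf, np.inf))[0] for p in free])
    hi = np.array([problem.bounds.get(p, (-np.inf, np.inf))[1] for p in free])

    def residual_vector(x: np.ndarray) -> np.ndarray:
        params = start.with_pairs(dict(zip(free, x)))
        return np.concatenate([
            _molecule_residuals(tm, problem, params) for tm in problem.training
        ])

    r0 = residual_vector(x0)
    opt = least_squares(residual_vector, x0, bounds=(lo, hi), method="trf",
                        diff_step=diff_step, xtol=xtol, ftol=ftol, gtol=gtol,
                        max_nfev=max_nfev)
    # least_squares never returns a worse point than x0, so the
    # objective-non-increase invariant holds by construction
    fitted = start.with_pairs(dict(zip(free, opt.x)))
    fitted.metadata["fit"] = (
        f"least squares over {len(free)} pair parameter(s), "
        f"{len(problem.training)} training molecule(s)"
    )

    rows = []
    for tm in problem.training:
        try:
            sol = solve_charges(tm.molecule, fitted)
            rows.append({
                "molecule": tm.molecule.name,
                "charge_rms_e": float(np.sqrt(np.mean((sol.q - tm.q_ref) ** 2))),
                "energy_residual_eV": (float(sol.EM - tm.E_ref)
                                       if tm.E_ref is not None else np.nan),
            })
        except PCPError:
            rows.append({"molecule": tm.molecule.name,
                         "charge_rms_e": np.nan, "energy_residual_eV": np.nan})

    return FitResult(
        params=fitted,
        objective=float(np.sum(opt.fun**2)),
        start_objective=float(np.sum(r0**2)),
        per_molecule=pd.DataFrame(rows),
        n_evaluations=int(opt.nfev),
        success=bool(opt.success),
        message=str(opt.message),
    )


def read_reference_charges(path: str | Path) -> dict[str, np.ndarray]:
    """CSV ``molecule,atom_index,element,q_ref`` -> per-molecule charge arrays.

    Atom indices are 1-based in the file and must be contiguous per molecule.
    """
    df = pd.read_csv(path)
    out = {}
    for mol, g in df.groupby("molecule", sort=False):
        g = g.sort_values("atom_index")
        if list(g["atom_index"]) != list(range(1, len(g) + 1)):
            raise ValueError(f"{mol}: atom_index must be 1..n without gaps")
        out[mol] = g["q_ref"].to_numpy(dtype=float)
    return out


def read_reference_energies(path: str | Path) -> dict[str, float]:
    """CSV ``molecule,E_ref`` -> reference total energies (eV)."""
    df = pd.read_csv(path)
    return {row["molecule"]: float(row["E_ref"]) for _, row in df.iterrows()}
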