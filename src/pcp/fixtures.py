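"""Packaged validation tables and synthetic toy systems.

The validation tables transcribe the published comparison of PCP-model
total energies (Tables 2-3: organic and inorganic molecules vs ab initio
HF/STO-3G) and per-atom charges (Tables 4-5: vs STO-3G Mulliken and PM3).
They are data, not computation: the published per-molecule values cannot
be recomputed here because the fitted k database and the geometries
behind them were never published.  Toy systems, by contrast, are fully
specified fictitious molecules used to exercise the solver against
independent oracles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .element_params import ElementParams
from .energy_model import ParameterSet, pair_key
from .molecule_io import Atom, Molecule

__all__ = ["TableFixture", "load_table", "ToySystem", "make_toy_system",
           "make_recovery_problem", "TABLE5_PRINTED_R2"]

#: Printed trailing R^2 pair of the inorganic charge table (PCP, PM3).
#: Its scope is ambiguous in the source (last molecule vs whole table):
#: recomputation matches neither reading at 3 decimals, so it is stored
#: for reference only and excluded from validation.
TABLE5_PRINTED_R2 = (0.964, 0.846)

_EXPECTED_ROWS = {2: 15, 3: 24}


def _read_packaged_csv(name: str) -> pd.DataFrame:
    text = resources.files("pcp.data.tables").joinpath(name).read_text("utf-8")
    body = "".join(l for l in text.splitlines(keepends=True)
                   if not l.startswith("#"))
    return pd.read_csv(io.StringIO(body))


@dataclass
class TableFixture:
    """One transcribed validation table.

    ``energies`` (tables 2/3): molecule, E_pcp_eV, E_abinitio_eV,
    abs_error_eV, rel_error.  ``charges`` (tables 4/5): molecule,
    atom_index, atom_label, q_abinitio, q_pcp, q_pm3 (NaN where the
    source prints a dash).  ``printed_r2`` (table 4 only): per-molecule
    printed R^2 of each method column against ab initio.
    """

    table_id: int
    energies: pd.DataFrame | None = None
    charges: pd.DataFrame | None = None
    printed_r2: pd.DataFrame | None = None

    @property
    def molecules(self) -> list[str]:
        df = self.energies if self.energies is not None else self.charges
        return list(dict.fromkeys(df["molecule"]))


def load_table(table_id: int) -> TableFixture:
    """Load one of the packaged validation tables (id in {2, 3, 4, 5})."""
    if table_id in (2, 3):
        df = _read_packaged_csv(f"table{table_id}_energies.csv")
        if len(df) != _EXPECTED_ROWS[table_id]:
            raise AssertionError(
                f"table {table_id}: expected {_EXPECTED_ROWS[table_id]} rows, "
                f"got {len(df)} (corrupted fixture)"
            )
        return TableFixture(table_id, energies=df)
    if table_id == 4:
        return TableFixture(4, charges=_read_packaged_csv("table4_charges.csv"),
                            printed_r2=_read_packaged_csv("table4_r2.csv"))
    if table_id == 5:
        return TableFixture(5, charges=_read_packaged_csv("table5_charges.csv"))
    raise ValueError(f"no packaged table with id {table_id!r}")


@dataclass
class ToySystem:
    """A fully specified fictitious molecule for oracle tests."""

    molecule: Molecule
    params: ParameterSet
    seed: int

    @property
    def R(self) -> np.ndarray:
        from .molecule_io import distance_matrix

        return distance_matrix(self.molecule)


def _toy_element(symbol: str, rng, hardness_range, mu0_range) -> ElementParams:
    """Draw one fictitious element from hardness and site potential.

    Drawing gamma/N0 (the site hardness, eV/e^2) and mu0 directly keeps
    the molecular energy locally convex around neutrality for reasonable
    k/R; the corresponding (I, A) are back-computed so the record is
    self-consistent with the parameter-derivation formulas (I may come
    out unphysical for a fictitious element; only gamma > 0 matters).
    """
    import math

    N0 = int(rng.integers(2, 9))
    gamma = float(rng.uniform(*hardness_range)) * N0
    mu0 = float(rng.uniform(*mu0_range))
    L1 = (N0 - 1) * math.log((N0 - 1) / N0)
    L2 = (N0 + 1) * math.log((N0 + 1) / N0)
    I = gamma * L1 - mu0
    A = I - gamma * (L1 + L2)
    return ElementParams(symbol=symbol, N0=N0, I=I, A=A, gamma=gamma, mu0=mu0)


def _projected_hessian_ok(system: "ToySystem", q_solution, N_solution,
                          margin: float = 0.5) -> bool:
    """True when the solved point is a proper constrained local minimum.

    The energy in charge space has Hessian diag(gamma_i/N_i) + s*k_ij/R_ij
    (zero diagonal on the pair part); the pair part is indefinite, so a
    draw can place the stationary point on a saddle — such systems are
    rejected, since only interior minima are meaningful test subjects.
    """
    params, mol = system.params, system.molecule
    n = len(mol)
    _, gamma, _ = params.element_arrays(mol)
    R = system.R
    K = params.k_matrix(mol)
    H = np.zeros((n, n))
    off = ~np.eye(n, dtype=bool)
    H[off] = params.interaction_sign * K[off] / R[off]
    H[np.diag_indices(n)] = gamma / N_solution
    # orthonormal basis of the conservation hyperplane sum(dq) = 0
    basis = np.linalg.svd(np.ones((1, n)))[2][1:].T
    eig = np.linalg.eigvalsh(basis.T @ H @ basis)
    return bool(eig.min() > margin)


def make_toy_system(n_atoms: int = 3, seed: int = 0, *,
                    homonuclear: bool = False,
                    hardness_range: tuple[float, float] = (8.0, 15.0),
                    mu0_range: tuple[float, float] = (-15.0, -5.0),
                    k_range: tuple[float, float] = (3.0, 12.0),
                    min_separation: float = 1.5,
                    net_charge: int = 0,
                    max_redraws: int = 200) -> ToySystem:
    """Generate a random small molecule with known, solvable parameters.

    Element draws mimic the scales real main-group atoms occupy: site
    hardness gamma/N0 of 8-15 eV/e^2, neutral-atom chemical potentials of
    -15 to -5 eV, pair strengths of 3-12 eV*Angstrom around/below the bare
    Coulomb constant, and internuclear separations of at least 1.5 A in a
    box of ~2.5 A per atom.  Each candidate is solved and kept only if it
    converges to an interior constrained minimum with moderate charges
    (|q| <= 1.2 e); infeasible draws are redrawn deterministically, so the
    result is reproducible for a given seed.
    """
    if not 2 <= n_atoms <= 6:
        raise ValueError("toy systems are 2-6 atoms")
    from .charge_solver import solve_charges
    from .errors import PCPError

    ss = np.random.SeedSequence([seed, n_atoms, int(homonuclear), net_charge])
    for child in ss.spawn(max_redraws):
        rng = np.random.default_rng(child)
        n_species = 1 if homonuclear else n_atoms
        species = [_toy_element(f"X{i + 1}", rng, hardness_range, mu0_range)
                   for i in range(n_species)]
        symbols = ([species[0].symbol] * n_atoms if homonuclear
                   else [p.symbol for p in species])

        box = 2.5 * n_atoms ** (1 / 3) + 1.0
        positions: list[np.ndarray] = []
        tries = 0
        while len(positions) < n_atoms and tries < 1000:
            cand = rng.uniform(0.0, box, size=3)
            tries += 1
            if all(np.linalg.norm(cand - p) >= min_separation
                   for p in positions):
                positions.append(cand)
        if len(positions) < n_atoms:
            continue
        atoms = [Atom(s, *map(float, p)) for s, p in zip(symbols, positions)]

        uniq = sorted(set(symbols))
        pairs = {pair_key(a, b): float(rng.uniform(*k_range))
                 for i, a in enumerate(uniq) for b in uniq[i:]}
        params = ParameterSet(
            elements={p.symbol: p for p in species}, pairs=pairs,
            metadata={"origin": f"make_toy_system(seed={seed})"},
        )
        mol = Molecule(atoms, net_charge=net_charge, name=f"toy-{seed}")
        system = ToySystem(molecule=mol, params=params, seed=seed)
        try:
            sol = solve_charges(mol, params)
        except PCPError:
            continue
        if np.abs(sol.q).max() > 1.2:
            continue
        if not _projected_hessian_ok(system, sol.q, sol.N):
            continue
        return system
    raise RuntimeError(
        f"no feasible toy system within {max_redraws} redraws (seed {seed})"
    )


def make_recovery_problem(seed: int = 0, *, n_molecules: int = 5,
                          noise_sigma_q: float = 0.0,
                          noise_seed: int | None = None):
    """Self-generated parameter-recovery experiment for the fitter.

    Builds two fictitious species (three unordered element pairs), draws
    hidden true pair strengths k*, generates ``n_molecules`` mixed-
    composition 3-4 atom molecules, and produces training references by
    solving each molecule at k*.  Optional zero-mean Gaussian noise of
    width ``noise_sigma_q`` (e) is added to the reference charges, drawn
    from ``noise_seed`` (defaults to ``seed``) so one problem can be
    repeated under different noise realizations.

    Returns ``(training, params_true, start)`` where ``start`` carries the
    same elements but all free pairs at 0 (always solvable: zero coupling
    decouples the atoms).
    """
    from .charge_solver import solve_charges
    from .errors import PCPError
    from .param_fit import TrainingMolecule

    compositions = [("X1", "X1", "X2"), ("X1", "X2", "X2"),
                    ("X1", "X1", "X2", "X2"), ("X1", "X2", "X2", "X2"),
                    ("X2", "X1", "X1", "X1")]
    ss = np.random.SeedSequence([seed, 0x5EED])
    for child in ss.spawn(100):
        rng = np.random.default_rng(child)
        species = {s: _toy_element(s, rng, (8.0, 15.0), (-15.0, -5.0))
                   for s in ("X1", "X2")}
        k_true = {p: float(rng.uniform(3.0, 12.0))
                  for p in (("X1", "X1"), ("X1", "X2"), ("X2", "X2"))}
        params_true = ParameterSet(elements=species, pairs=k_true,
                                   metadata={"origin": "recovery k*"})
        training, ok = [], True
        for m_idx in range(n_molecules):
            symbols = compositions[m_idx % len(compositions)]
            mol = None
            for _ in range(50):
                pts: list[np.ndarray] = []
                box = 2.5 * len(symbols) ** (1 / 3) + 1.0
                while len(pts) < len(symbols):
                    cand = rng.uniform(0.0, box, size=3)
                    if all(np.linalg.norm(cand - p) >= 1.5 for p in pts):
                        pts.append(cand)
                cand_mol = Molecule(
                    [Atom(s, *map(float, p)) for s, p in zip(symbols, pts)],
                    name=f"train-{m_idx}")
                try:
                    sol = solve_charges(cand_mol, params_true)
                except PCPError:
                    continue
                sys_ = ToySystem(cand_mol, params_true, seed)
                if (np.abs(sol.q).max() <= 1.2
                        and _projected_hessian_ok(sys_, sol.q, sol.N)):
                    mol = cand_mol
                    break
            if mol is None:
                ok = False
                break
            training.append(TrainingMolecule(mol, sol.q.copy(), sol.EM))
        if not ok:
            continue
        if noise_sigma_q:
            noise_rng = np.random.default_rng(
                np.random.SeedSequence([seed if noise_seed is None
                                        else noise_seed, 0xA015E]))
            for tm in training:
                tm.q_ref = tm.q_ref + noise_sigma_q * noise_rng.standard_normal(
                    len(tm.molecule))
        start = ParameterSet(elements=species,
                             pairs={p: 0.0 for p in k_true})
        return training, params_true, start
    raise RuntimeError(f"no feasible recovery problem for seed {seed}")
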