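"""Molecular energy model and per-atom chemical potentials.

The molecular energy is a sum of isolated-atom PCP energies plus a
screened Coulomb-like pair interaction with fitted strengths k_ab
(eV*Angstrom, one value per unordered element pair):

    E_M = sum_a N_a (mu0_a + gamma_a ln(N_a/N0_a) - gamma_a)
        + s * (1/2) sum_a sum_{b != a} k_ab q_a q_b / R_ab

under the default ``half_pair_sum`` convention with sign s = +1.  With
that convention the per-atom chemical potential inside the molecule,

    mu_a^M = mu0_a + gamma_a ln(N_a/N0_a) - s * sum_{b != a} k_ab q_b / R_ab,

is exactly the partial derivative dE_M/dN_a — the variational structure
the charge solver relies on.  ``double_pair_sum`` (no 1/2, i.e. each pair
counted twice) and the sign toggle are exposed for sensitivity checks;
gradient consistency holds only under ``half_pair_sum``.

Fitted k values are convention-bound: a parameter file always records the
convention it was fitted under.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict

from .element_params import ElementParams
from .errors import MissingParameterError
from .molecule_io import Molecule

__all__ = [
    "ParameterSet",
    "ElectronDistribution",
    "molecular_energy",
    "pcpp",
    "pcpp_all",
    "COULOMB_EV_ANGSTROM",
]

# e^2 / (4 pi eps0) in eV*Angstrom: the bare Coulomb pair constant, the
# physically-motivated default starting value for k when fitting.
COULOMB_EV_ANGSTROM = 14.3996


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered element-pair key."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ParameterSet:
    """Element parameters plus symmetric pairwise interaction strengths.

    ``pairs`` maps an unordered element pair to k (eV*Angstrom); one k per
    element pair is shared across a molecule and across molecules, which is
    what lets a fitted parameter database generalize.  ``atom_pair_overrides``
    optionally pins k for specific atom-index pairs of a molecule.
    """

    elements: dict[str, ElementParams]
    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    convention: Literal["half_pair_sum", "double_pair_sum"] = "half_pair_sum"
    interaction_sign: float = 1.0
    atom_pair_overrides: dict[tuple[int, int], float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pairs = {pair_key(*k): float(v) for k, v in self.pairs.items()}
        if self.interaction_sign not in (1.0, -1.0):
            raise ValueError("interaction_sign must be +1 or -1")
        for k, v in self.pairs.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite k for pair {k}")

    def element(self, symbol: str) -> ElementParams:
        try:
            return self.elements[symbol]
        except KeyError:
            raise MissingParameterError(
                f"no element parameters for {symbol!r}"
            ) from None

    def k(self, a: str, b: str) -> float:
        try:
            return self.pairs[pair_key(a, b)]
        except KeyError:
            raise MissingParameterError(
                f"no interaction parameter k for element pair {pair_key(a, b)}"
            ) from None

    def with_pairs(self, updates: dict[tuple[str, str], float]) -> "ParameterSet":
        """Copy with some pair parameters replaced (used by the fitter)."""
        new = dict(self.pairs)
        new.update({pair_key(*k): v for k, v in updates.items()})
        return ParameterSet(
            elements=self.elements, pairs=new, convention=self.convention,
            interaction_sign=self.interaction_sign,
            atom_pair_overrides=dict(self.atom_pair_overrides),
            metadata=dict(self.metadata),
        )

    # -- per-molecule vector/matrix views used by the solver -----------------

    def element_arrays(self, mol: Molecule):
        """(N0, gamma, mu0) vectors in atom order."""
        ps = [self.element(e) for e in mol.elements]
        return (np.array([p.N0 for p in ps], dtype=float),
                np.array([p.gamma for p in ps]),
                np.array([p.mu0 for p in ps]))

    def k_matrix(self, mol: Molecule) -> np.ndarray:
        """Symmetric n x n matrix of k values (zero diagonal)."""
        els = mol.elements
        n = len(els)
        K = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                K[i, j] = K[j, i] = self.k(els[i], els[j])
        for (i, j), v in self.atom_pair_overrides.items():
            K[i, j] = K[j, i] = v
        return K

    # -- JSON round trip -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = _ParameterFile(
            convention=self.convention,
            interaction_sign=self.interaction_sign,
            metadata={k: str(v) for k, v in self.metadata.items()},
            elements={
                s: _ElementRecord(Z=p.N0, I_eV=p.I, A_eV=p.A)
                for s, p in self.elements.items()
            },
            pairs={f"{a}-{b}": v for (a, b), v in self.pairs.items()},
        )
        Path(path).write_text(doc.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        doc = _ParameterFile.model_validate_json(Path(path).read_text())
        elements = {
            s: ElementParams.from_IA(s, I=r.I_eV, A=r.A_eV, N0=r.Z)
            for s, r in doc.elements.items()
        }
        pairs = {}
        for key, v in doc.pairs.items():
            a, _, b = key.partition("-")
            if not b:
                raise ValueError(f"pair key {key!r} is not of the form 'A-B'")
            pairs[pair_key(a, b)] = v
        return cls(elements=elements, pairs=pairs, convention=doc.convention,
                   interaction_sign=doc.interaction_sign, metadata=doc.metadata)


class _ElementRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")
    Z: int
    I_eV: float
    A_eV: float


class _ParameterFile(BaseModel):
    """Strict schema of the on-disk parameter JSON."""

    model_config = ConfigDict(extra="forbid")
    convention: Literal["half_pair_sum", "double_pair_sum"] = "half_pair_sum"
    interaction_sign: float = 1.0
    metadata: dict[str, str] = {}
    elements: dict[str, _ElementRecord]
    pairs: dict[str, float] = {}


@dataclass(frozen=True)
class ElectronDistribution:
    """Per-atom electron populations and the equivalent charge/log views.

    N_a > 0; q_a = N0_a - N_a (charge in e, nuclear charge Z = N0 for the
    neutral species); Na_a = ln(N_a / N0_a), the solver's working variable.
    """

    N: np.ndarray
    q: np.ndarray
    Na: np.ndarray

    def __post_init__(self):
        if np.any(self.N <= 0):
            raise ValueError("electron populations must be positive")
        N0 = self.N + self.q
        if not (np.allclose(self.q, N0 - self.N, atol=1e-12)
                and np.allclose(self.Na, np.log(self.N / N0), atol=1e-12)):
            raise ValueError("inconsistent (N, q, Na) triple")

    @classmethod
    def from_N(cls, N, N0) -> "ElectronDistribution":
        N = np.asarray(N, dtype=float)
        N0 = np.asarray(N0, dtype=float)
        if np.any(N <= 0):
            raise ValueError("electron populations must be positive")
        return cls(N=N, q=N0 - N, Na=np.log(N / N0))

    @classmethod
    def from_Na(cls, Na, N0) -> "ElectronDistribution":
        Na = np.asarray(Na, dtype=float)
        N0 = np.asarray(N0, dtype=float)
        N = N0 * np.exp(Na)
        return cls(N=N, q=N0 * (1.0 - np.exp(Na)), Na=Na)


def _interaction_prefactor(params: ParameterSet) -> float:
    half = 0.5 if params.convention == "half_pair_sum" else 1.0
    return params.interaction_sign * half


def molecular_energy(mol: Molecule, dist: ElectronDistribution,
                     R: np.ndarray, params: ParameterSet) -> float:
    """Total molecular energy E_M (eV) at the given electron distribution."""
    N0, gamma, mu0 = params.element_arrays(mol)
    atom_terms = dist.N * (mu0 + gamma * dist.Na - gamma)
    K = params.k_matrix(mol)
    n = len(mol)
    if n > 1:
        iu = np.triu_indices(n, k=1)
        pair_sum = np.sum(K[iu] * dist.q[iu[0]] * dist.q[iu[1]] / R[iu])
    else:
        pair_sum = 0.0
    # half_pair_sum: s * (1/2) * double sum == s * sum over unordered pairs
    return float(atom_terms.sum()
                 + 2.0 * _interaction_prefactor(params) * pair_sum)


def pcpp_all(mol: Molecule, dist: ElectronDistribution,
             R: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Chemical potential of every atom in the molecule (eV), vectorized.

    mu_a^M = mu0_a + gamma_a Na_a - s * sum_{b != a} k_ab q_b / R_ab.
    The b-sum excludes b = a (the self term would divide by R_aa = 0).
    """
    N0, gamma, mu0 = params.element_arrays(mol)
    K = params.k_matrix(mol)
    n = len(mol)
    if n > 1:
        Rsafe = R + np.eye(n)  # diagonal of K is zero, so the value is moot
        coul = (K * dist.q[None, :] / Rsafe).sum(axis=1)
    else:
        coul = np.zeros(1)
    return mu0 + gamma * dist.Na - params.interaction_sign * coul


def pcpp(mol: Molecule, dist: ElectronDistribution, R: np.ndarray,
         params: ParameterSet, alpha: int) -> float:
    """Chemical potential of atom ``alpha`` inside the molecule (eV).

    Under the default half_pair_sum convention this equals dE_M/dN_alpha.
    """
    return float(pcpp_all(mol, dist, R, params)[alpha])
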