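"""Per-element parameters of the pseudo-chemical-potential (PCP) model.

The PCP model assigns each atomic site a chemical potential that varies
logarithmically with its electron population N,

    mu(N) = mu0 + gamma * ln(N / N0),

where N0 is the electron count of the neutral atom, mu0 the chemical
potential at neutrality, and gamma a softness-like slope parameter (eV).
Integrating mu over N (with the integration constant set to zero, since
only energy differences matter) gives the isolated-atom energy curve

    E(N) = N * (mu(N) - gamma).

Both parameters are fixed by two experimental observables of the isolated
atom, the first ionization energy I and the electron affinity A:

    gamma = (I - A) / [ (N0-1) ln((N0-1)/N0) + (N0+1) ln((N0+1)/N0) ],
    mu0   = -I + gamma * (N0-1) ln((N0-1)/N0),

with the 0*ln(0) := 0 convention so hydrogen (N0 = 1) is well defined:
there gamma = (I - A)/(2 ln 2) and mu0 = -I exactly.

A subtlety worth knowing: these defining formulas correspond to ionization
and affinity differences of the curve F(N) = N * mu(N), not of E(N) above.
The two curves differ by the linear term -gamma*N, which shifts I and A
each by +gamma and cancels in I - A — so gamma is the same either way,
but E(N0-1) - E(N0) evaluates to I + gamma, not I.  :func:`recover_IA`
inverts the parameter derivation exactly (differences of F) and is the
module's round-trip self-check.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import DomainError, InvalidElementError

__all__ = [
    "ElementParams",
    "gamma_from_IA",
    "mu0_from_IA",
    "pcp",
    "atomic_energy",
    "load_element_table",
]


def _nlog(n: float) -> float:
    """n * ln(n) with the 0*ln(0) := 0 convention."""
    return 0.0 if n == 0 else n * math.log(n)


def _check_N0(N0: int) -> int:
    if not float(N0).is_integer() or N0 < 1:
        raise InvalidElementError(
            f"neutral electron count must be a positive integer, got {N0!r}"
        )
    return int(N0)


def gamma_from_IA(I: float, A: float, N0: int) -> float:
    """Slope parameter gamma (eV) from ionization energy and electron affinity.

    gamma = (I - A) / [(N0-1) ln((N0-1)/N0) + (N0+1) ln((N0+1)/N0)],
    evaluated with 0*ln(0) := 0 so that N0 = 1 gives (I - A)/(2 ln 2).

    A warning is emitted when I < A (gamma < 0 is permitted but anomalous;
    it arises only from unphysical or heavily extrapolated inputs).
    """
    N0 = _check_N0(N0)
    lnN0 = math.log(N0)
    # (N0-1)ln((N0-1)/N0) + (N0+1)ln((N0+1)/N0), grouped to use the 0 ln 0 rule
    denom = (_nlog(N0 - 1) - (N0 - 1) * lnN0) + (_nlog(N0 + 1) - (N0 + 1) * lnN0)
    if I < A:
        warnings.warn(
            f"I ({I}) < A ({A}): derived gamma is negative; "
            "the chemical potential will decrease with electron count",
            stacklevel=2,
        )
    return (I - A) / denom


def mu0_from_IA(I: float, gamma: float, N0: int) -> float:
    """Chemical potential at neutrality, mu0 = -I + gamma*(N0-1)ln((N0-1)/N0).

    For N0 = 1 the correction term vanishes and mu0 = -I exactly.
    """
    N0 = _check_N0(N0)
    if N0 == 1:
        return -I
    return -I + gamma * (N0 - 1) * math.log((N0 - 1) / N0)


@dataclass(frozen=True)
class ElementParams:
    """PCP parameters of one element.

    Attributes
    ----------
    symbol : str
        IUPAC element symbol (or a fictitious label for toy systems).
    N0 : int
        Electron count of the neutral atom (= atomic number Z).
    I, A : float
        First ionization energy and electron affinity (eV).
    gamma, mu0 : float
        Derived PCP slope and neutral-atom chemical potential (eV).
    """

    symbol: str
    N0: int
    I: float
    A: float
    gamma: float
    mu0: float

    @classmethod
    def from_IA(cls, symbol: str, I: float, A: float, N0: int) -> "ElementParams":
        """Derive (gamma, mu0) from (I, A, N0) and build the record."""
        g = gamma_from_IA(I, A, N0)
        return cls(symbol=symbol, N0=_check_N0(N0), I=I, A=A,
                   gamma=g, mu0=mu0_from_IA(I, g, N0))

    def pcp(self, N: float) -> float:
        """Chemical potential mu(N) = mu0 + gamma ln(N/N0); requires N > 0."""
        return pcp(self, N)

    def energy(self, N: float) -> float:
        """Isolated-atom energy E(N) = N (mu(N) - gamma); requires N > 0."""
        return atomic_energy(self, N)


def pcp(params: ElementParams, N: float) -> float:
    """Evaluate the pseudo chemical potential of an isolated atom at N electrons."""
    if N <= 0:
        raise DomainError(f"electron count must be positive, got {N}")
    return params.mu0 + params.gamma * math.log(N / params.N0)


def atomic_energy(params: ElementParams, N: float) -> float:
    """Isolated-atom energy E(N) = N (mu(N) - gamma), integration constant zero.

    This is the energy curve embedded in the molecular model; dE/dN = mu(N).
    Note E(N0-1) - E(N0) = I + gamma under this curve (see the module
    docstring); use :func:`recover_IA` for the exact (I, A) round trip.
    E(0) = 0 by the analytic limit N ln N -> 0; N < 0 is a domain error.
    """
    if N == 0:
        return 0.0
    if N < 0:
        raise DomainError(f"electron count must be non-negative, got {N}")
    return N * (pcp(params, N) - params.gamma)


def recover_IA(params: ElementParams) -> tuple[float, float]:
    """Invert the parameter derivation: (gamma, mu0, N0) -> (I, A).

    Computed as differences of the derivation's energy curve
    F(N) = N * mu(N) (with F(0) = 0):

        I = F(N0-1) - F(N0),   A = F(N0) - F(N0+1).

    Exact inverse of (:func:`gamma_from_IA`, :func:`mu0_from_IA`); for any
    inputs with I > A the round trip closes to floating-point precision.
    """

    def F(N: float) -> float:
        return 0.0 if N == 0 else N * pcp(params, N)

    N0 = params.N0
    return F(N0 - 1) - F(N0), F(N0) - F(N0 + 1)


def load_element_table(path: str | Path | None = None,
                       overrides: dict | None = None) -> dict[str, ElementParams]:
    """Load the packaged element I/A table and derive PCP parameters.

    Parameters
    ----------
    path : optional
        JSON file mapping symbol -> {"Z": int, "I_eV": float, "A_eV": float};
        defaults to the packaged reference compilation.
    overrides : optional
        Per-symbol overrides merged on top of the file, same record layout
        (partial records allowed, e.g. ``{"O": {"A_eV": 1.46}}``).
    """
    if path is None:
        raw = json.loads(
            resources.files("pcp.data").joinpath("elements.json").read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    raw.pop("_metadata", None)
    for sym, rec in (overrides or {}).items():
        raw[sym] = {**raw.get(sym, {}), **rec}
    table = {}
    for sym, rec in raw.items():
        table[sym] = ElementParams.from_IA(
            sym, I=rec["I_eV"], A=rec["A_eV"], N0=rec["Z"]
        )
    return table
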