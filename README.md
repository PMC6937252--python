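# pcp — partial atomic charges by logarithmic chemical-potential equalization

`pcp` computes partial atomic charges and a semi-empirical total energy for
a molecular geometry by chemical-potential (electronegativity)
equalization, in the QEq/EEM family but with a logarithmic site potential.
It is aimed at people who need fast, geometry-aware charge assignment —
force-field preparation, screening, method studies — and at anyone who
wants a transparent, fully tested reference implementation of this model
family.

## The model

Each atomic site α carries a pseudo chemical potential that grows with the
logarithm of its electron population N_α:

    μ_α(N_α) = μ⁰_α + γ_α ln(N_α / N⁰_α)

where N⁰_α is the neutral atom's electron count, and (γ_α, μ⁰_α) are fixed
by the element's first ionization energy I and electron affinity A:

    γ  = (I − A) / [(N⁰−1) ln((N⁰−1)/N⁰) + (N⁰+1) ln((N⁰+1)/N⁰)]
    μ⁰ = −I + γ (N⁰−1) ln((N⁰−1)/N⁰)        (0·ln 0 := 0, so μ⁰_H = −I)

The molecular energy adds a screened Coulomb-like pair interaction with
fitted strengths k_αβ (eV·Å, one per element pair):

    E^M = Σ_α N_α(μ⁰_α + γ_α ln(N_α/N⁰_α) − γ_α)
        + ½ Σ_α Σ_{β≠α} k_αβ q_α q_β / R_αβ,     q_α = Z_α − N_α

The ground state equalizes every site's in-molecule potential
μ^M_α = ∂E^M/∂N_α under charge conservation Σ q_α = net charge; the
package solves that nonlinear system by damped Newton–Raphson in the log
variables ln(N_α/N⁰_α), which keeps every iterate's populations positive.
Pair parameters can be fitted by least squares against reference charges
and energies (`pcp.fit_pair_parameters`).  See `docs/methods.md` for the
conventions, numerical choices, and known inconsistencies in the source
formulation.

## Worked example

The published parameter database is not available (see below), so the
example uses a fully specified synthetic three-atom system from the
package's own generator:

```python
from pcp import make_toy_system
from pcp.molecule_io import write_xyz

ts = make_toy_system(3, seed=42)        # molecule + parameters, reproducible
ts.params.to_json("toy_params.json")
write_xyz(ts.molecule, "toy.xyz")
```

```
$ pcp charges toy.xyz --params toy_params.json
index,element,q,N,mu
1,X1,-0.163974,6.163974,-10.077492
2,X2,-0.041693,2.041693,-10.077492
3,X3,0.205666,1.794334,-10.077492
# mu_M = -10.077492 eV, E_M = -724.523695 eV, iterations = 4
```

Reading the output: atom 3 has donated 0.206 electrons (charge +0.206 e)
and atoms 1–2 have absorbed them; the charges sum to zero (neutral
molecule), and all three sites sit at the same equalized chemical
potential μ^M = −10.077 eV — the equalization condition that defines the
ground state.  E_M is the model's total energy at that distribution.
Deriving element parameters from measured data works the same way for
real elements:

```
$ pcp derive-element --symbol O --ionization 13.618 --affinity 1.461
{
  "symbol": "O",
  "N0": 8,
  ...
  "gamma_eV": 97.00179899780338,
  "mu0_eV": -104.28749715082496
}
```

Other commands: `pcp energy` (E_M only), `pcp fit` (least-squares fitting
of k_αβ against reference-charge CSVs), `pcp validate-tables` (recompute
the packaged validation statistics, see next section).

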