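# Methods

## The model

`pcp` assigns partial atomic charges and a semi-empirical total energy to a
molecule by chemical-potential equalization, in the same family as QEq and
EEM, but with a *logarithmic* site potential.  Each atomic site α carries a
pseudo chemical potential

    μ_α(N_α) = μ⁰_α + γ_α ln(N_α / N⁰_α)

where N_α is the site's electron population, N⁰_α the neutral-atom electron
count (= atomic number Z_α), μ⁰_α the chemical potential at neutrality, and
γ_α a softness-like slope (all energies in eV).  Integrating μ over N with
the integration constant set to zero gives the isolated-site energy curve
E_α(N) = N(μ_α(N) − γ_α).  The molecular energy adds a screened
Coulomb-like pair term with fitted strengths k_αβ (eV·Å), one value per
unordered element pair:

    E^M = Σ_α N_α (μ⁰_α + γ_α ln(N_α/N⁰_α) − γ_α)
        + s · (1/2) Σ_α Σ_{β≠α} k_αβ q_α q_β / R_αβ

with q_α = Z_α − N_α the partial charge (e) and R_αβ the internuclear
distance (Å, standard XYZ convention).  Under the default
`half_pair_sum` convention with sign s = +1 the per-atom chemical potential
inside the molecule,

    μ^M_α = μ⁰_α + γ_α ln(N_α/N⁰_α) − s Σ_{β≠α} k_αβ q_β / R_αβ,

is exactly ∂E^M/∂N_α, which is what makes the equalization conditions the
stationarity conditions of constrained energy minimization.  The source
formulation is ambiguous on both the 1/2 factor and the sign of the pair
term (different equations carry different versions); `half_pair_sum`/+1 is
the default because it is the only combination with this exact variational
structure, and the alternatives are exposed in `ParameterSet`
(`convention`, `interaction_sign`) for sensitivity checks.  Fitted k values
are convention-bound; parameter files record the convention.

## Element parameters

(γ, μ⁰) are fixed by the neutral atom's first ionization energy I and
electron affinity A:

    γ  = (I − A) / [(N⁰−1) ln((N⁰−1)/N⁰) + (N⁰+1) ln((N⁰+1)/N⁰)]
    μ⁰ = −I + γ (N⁰−1) ln((N⁰−1)/N⁰)

with the 0·ln 0 := 0 convention, so hydrogen gives γ_H = (I−A)/(2 ln 2) and
μ⁰_H = −I exactly.  A consistency point the user should know: these
defining formulas correspond to I/A differences of the curve N·μ(N), not of
E(N) = N(μ−γ).  The two curves differ by the linear term −γN, which shifts
I and A each by +γ and cancels in I−A; consequently γ is curve-independent,
but evaluating E(N⁰−1) − E(N⁰) on the model's energy curve yields I + γ.
`recover_IA` inverts the derivation exactly and is the round-trip
self-check used in the tests.

The packaged `elements.json` ships CRC/NIST reference I/A values (eV) for
24 main-group and transition elements; the original work does not print the
compilation it used, so exact numeric agreement with the authors' γ, μ⁰ is
not claimable.  Elements whose anion is unbound (N, Mg, Mn, Zn, Be) carry
the conventional negative estimate, flagged in the file; γ stays positive
as long as I > A.  All values are overridable per run.

Caution: with these literal parameters, chemically bonded element pairs
have μ⁰ gaps of tens of eV (e.g. H at −13.6 eV vs O at about −104 eV), and
plain equalization then predicts charge transfer far beyond published
magnitudes unless the k database compensates.  Since the authors' fitted k
database is unpublished, this package makes no claim about per-molecule
charges of real molecules with bare starting parameters; see "What is and
is not reproduced" below.

## Solving for the ground-state charges

The ground state solves μ^M_1 = … = μ^M_n = μ^M subject to Σ q_α =
net_charge.  The unknowns are the log populations Na_α = ln(N_α/N⁰_α) plus
μ^M, so every iterate keeps N_α > 0 by construction (iterating in N itself
can step negative, where the logarithm is undefined).  The n+1 residuals
(equalization rows in eV, conservation row in e) are solved by
damped Newton–Raphson with the analytic Jacobian:

* initialization Na = 0, μ^M = mean(μ⁰) — the neutral promolecule;
* dense LU solve of each Newton system (systems are small);
* step-halving line search (up to 30 halvings) accepting a decrease of the
  residual ∞-norm, with the log-variable step first capped at 20 to keep
  the exponentials finite on wild iterates;
* defaults tol = 1e-10 eV on the residual ∞-norm, max_iter = 100 (the
  source states no tolerances; typical feasible systems converge in 2–6
  iterations);
* deterministic: identical inputs give bit-identical outputs.

Failure modes are explicit: a singular Newton system raises
`SingularJacobianError`, and stagnation or iteration exhaustion raises
`NonConvergenceError` carrying the residual-norm history.  Non-convergence
is a real property of the model, not only a numerical artifact: the pair
term is an indefinite quadratic form in q, so for strong coupling
(k/R large against the site hardnesses γ_α/N_α) the energy has no interior
minimum and charge transfer runs away.  The solver fails loudly in that
regime rather than returning a saddle.

## Parameter fitting

`fit_pair_parameters` estimates the free k values by least squares against
reference charges (and optionally energies) for a training set, the same
scheme used to build the original parameter database from HF/STO-3G
references.  The objective per molecule is w_q Σ_atoms (q_calc − q_ref)² +
w_E (E_calc − E_ref)², with defaults w_q = 1 and w_E = 10⁻²/n_atoms —
charges dominate, energies regularize; both configurable.  The outer
optimizer is SciPy's trust-region-reflective least squares with
finite-difference derivatives, because the inner solve is not guaranteed
differentiable at penalized points: a candidate k for which some training
molecule fails to converge contributes a large finite residual (10³ per
entry) instead of aborting.  Free pairs missing from the starting set
start at the bare Coulomb pair constant 14.3996 eV·Å, the physically
motivated scale of the interaction.  One k per unordered element pair is
the fitting unit (shared across molecules); per-atom-pair overrides exist
for sensitivity work but are never fitted.

## Synthetic toy systems

The published tables cannot be recomputed (below), so solver correctness
rests on fully specified fictitious systems from `make_toy_system`:

* site hardness γ/N⁰ drawn uniformly from 8–15 eV/e², the range real
  main-group atoms occupy (e.g. H ≈ 9.3, C ≈ 10.0, O ≈ 12.1 eV/e² from the
  packaged table);
* μ⁰ from −15 to −5 eV — deliberately narrower than the literal real-atom
  range, so that equalization produces partial charges of ordinary
  magnitude rather than runaway transfer;
* k from 3–12 eV·Å (at and below the bare Coulomb constant, i.e. screened),
  internuclear separations ≥ 1.5 Å in a box of ~2.5 Å per atom;
* (I, A) back-computed from (γ, μ⁰) so each fictitious record is
  self-consistent with the derivation formulas.

Each draw is solved and accepted only if it converges to an interior
constrained minimum: |q| ≤ 1.2 e and the projected Hessian
diag(γ_α/N_α) + s·k_αβ/R_αβ restricted to Σ dq = 0 positive definite
(margin 0.5 eV/e²).  Infeasible draws are redrawn deterministically from a
spawned seed sequence, so a given seed always yields the same system.
The feasibility filter is part of the generator's contract — only systems
with a proper minimum are meaningful subjects for the minimization oracle —
and its rejection behavior is itself what the non-convergence test
exercises in reverse.

What the toys do not emulate: real bond-length geometries, the wide μ⁰
spreads of real element pairs, conformational correlation between charges
and geometry, and any quantum-mechanical reference behavior.  Passing the
toy-based tests therefore demonstrates that the solver solves the stated
equations correctly, not that the model reproduces ab initio charges for
real molecules.

## Validation against the published tables

The packaged CSVs transcribe the published comparison tables (total
energies of 15 organic and 24 inorganic molecules vs HF/STO-3G; per-atom
charges of 16 molecules vs STO-3G Mulliken and PM3), and
`table_validation` recomputes the printed summary statistics:

* OLS regression of ab initio on model energies, computed on energy
  magnitudes — all energies are negative and the published correlation
  plot uses positive values; only that reading reproduces the printed
  intercepts.  The inorganic table reproduces slope and intercept to the
  printed precision (0.9909, −38.809).
* Charge R² as the squared Pearson correlation between a method's per-atom
  charges and the ab initio column; all twelve printed values reproduce to
  ≤ 5·10⁻⁵ (the ethane column is exactly collinear, hence exactly 1).
* Relative energy error as (E_model − E_ab)/E_ab, the convention that
  reproduces every row of the inorganic table.

Three printed values are inconsistent with the printed data they
summarize, and the corresponding acceptance checks are deliberately left
failing rather than reinterpreted: the organic table's regression
intercept (−45.322 printed; −50.03 from its own 15 rows under every
orientation/sign choice, with the slope matching to four decimals), the
CF4 relative error (printed under the model-energy denominator while the
rest of the tables use the ab initio denominator), and the claim that all
relative errors lie below 0.0176 (the water row itself prints 0.0191).

## What is and is not reproduced

Reproduced from scratch: every summary statistic above; all solver
properties (conservation ≤ 1e-8 e, equalization spread ≤ 1e-10 eV on 200
toys; agreement with an independent grid+refinement constrained minimizer
to 1e-4 e on two-atom and 1e-3 e on three-atom systems; chemical potential
vs finite-difference energy gradient to relative 1e-6); the element
round trip to 1e-9 eV; exact recovery of hidden pair parameters from
noiseless self-generated references (and recovery within a band calibrated
over 20 noise realizations at σ_q = 0.01 e — observed worst case 0.39
relative, asserted at 0.8).

Not reproduced, by necessity: the per-molecule energies and charges of the
published tables.  They require the authors' fitted k database and the
molecular-dynamics geometries, neither of which was published.  The tables
are shipped as reference data and validation surface only.

## Problem sizes and tolerances used in the checks

Property checks use 200 toy systems of 2–6 atoms; oracle comparisons 50
two-atom and 20 three-atom systems (3001-point line grid, 49×49 plane
grid, then local refinement); gradient checks 100 systems at step 1e-5;
the recovery experiment 5 molecules of 3–4 atoms with 3 free pairs.  The
full test suite runs in well under a minute on one CPU.
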