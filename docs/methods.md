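# Methods

## Model and assumptions

The population is a discrete-time Markov chain over four states — healthy
(1), mentally ill (2), other-cause death (3), suicide (4) — advanced in
one-year steps. The six free parameters are the annual exit probabilities
from the two living states (`p21, p31, p41` from healthy; `p12, p32, p42`
from mentally ill); the stay probabilities are the row complements. The
model is homogeneous: no age, sex or duration structure, identical risks
within a compartment, and time-constant parameters.

Two variants share the same living-state flows:

- **No replacement** (closed system): deaths accumulate as absorbing
  stocks. The living population contracts by factor matrix whose spectral
  radius is strictly below 1 whenever any death probability is positive,
  so w + x → 0 geometrically. Mainly of diagnostic interest.
- **With replacement**: every death in year n re-enters the healthy
  compartment in year n+1 as a newborn. Under this bookkeeping y and z
  are *annual flows*, not cumulative stocks, and w + x + y + z = Q₀
  exactly — this is the only reading under which the closed-form
  stationary state below holds. Replacement is a mathematical device that
  makes a non-trivial equilibrium exist; it is not a demographic claim.

The replacement map has the unique fixed point (up to the scale Q₀)

    (w, x, y, z) ∝ (S, p21, p31·S + p32·p21, p41·S + p42·p21),
    S = p12 + p32 + p42,
    R = (1 + p31 + p41)·S + p21·(1 + p32 + p42),

where R is exactly the sum of the four unnormalized components, so the
stationary fractions are the components over R. The fixed point is
verified in the test suite three independent ways: direct substitution
into the step map, power iteration from arbitrary starts, and the leading
eigenvector of the 4×4 update matrix computed by `numpy.linalg.eig`.

## Parameters, units, defaults

All six parameters are probabilities per year. The default scenario is
the Hong Kong 2012 setting (hospital-authority psychiatric-service
counts and Coroner-court suicide ascertainment): `p21 = 0.00286`,
`p12 = 0.0667`, `p31 = 0.006`, `p32 = 0.012`, `p41 = 0.0000834`
(8.34/100,000), `p42 = 0.0025` (250/100,000 — a 30-fold risk
differential), with Q₀ = 7,000,000 and 150,000 initially mentally ill
(2.14% starting prevalence). When Q₀ is changed without specifying an
initial ill stock, the 150,000 is rescaled proportionally.

## Sensitivity analysis

The equilibrium suicide count is z = Q₀·N/R with N = p41·S + p42·p21.
`dz_dparam` differentiates this rational function analytically through
*every* appearance of the parameter in N, S and R; a central finite
difference (default step h = 1e-8) is provided as an independent check.
The first-order intervention projection is Δz = Δp·∂z/∂p; the reference
intervention is Δp41 = 1e-5 (1 per 100,000).

Two derivative conventions exist in informal use. The shortcut
Δz ≈ Δp41·w (the risk change applied to the equilibrium healthy stock,
`project_delta_z_prevalence_approx`) agrees with the full derivative to
one decimal at the default parameters, but only the full derivative
reproduces the equivalent-perturbation column of the scenario table
(e.g. 29, not 28, at reference), so the full derivative is canonical
throughout.

The **equivalent perturbation** of p42 — how far the high-risk
parameter must move to match the reference population-wide Δz — is
computed two ways: linearized (Δz divided by ∂z/∂p42) and exact (Brent
root-finding of the re-solved equilibrium over the remaining headroom
[0, 1 − p12 − p32 − p42], |Δp| tolerance 1e-12). The exact search is run
on the *increase* side of p42: for scenarios with small p42 even setting
it to zero cannot remove 67 suicides, so the magnitude-matched upward
perturbation is the quantity that is always defined. The two modes agree
within 0.5×10⁻⁵ on every scenario row; which one produced any particular
published table is immaterial at printed precision.

The scenario table sweeps 11 (p41, p42) pairs in four blocks (the base
pair; p42 held while p41 sweeps 1e-5…5e-4; p41 held while p42 sweeps
1e-4…1e-2; the ratio held at 30). Δz is nearly invariant (≈67) across
rows because it is dominated by the healthy share, which never leaves
0.95–0.97. Printed rounding is z and Δz to integers, Δz/z to 0.1
percentage point, the equivalent Δp42 to an integer in 1e-5 units, all
half away from zero.

Derivatives with respect to p21, p12, p31 and p32 are computed by the
same differentiation and exposed in the sensitivity report; they extend
the tabulated p41/p42 analysis to the full parameter vector.

## Stochastic cohort simulation

The deterministic map is the expectation of per-individual independent
categorical draws, realized efficiently as one four-outcome multinomial
draw per compartment-year. Deaths in year n re-enter as healthy in year
n+1, mirroring the deterministic bookkeeping, so living + current-year
deaths = Q₀ each year. One integer seed controls a run; per-year
generators are spawned from a `numpy` `SeedSequence`, so tallies are
bit-reproducible given (seed, Q₀, years, initial state).

The simulator emulates annual *transition tallies* of a homogeneous
closed population. It deliberately omits features of real registries —
age/cohort structure, secular trends in rates, diagnostic misclassification,
under-ascertainment of suicide, migration, and any contagion or
overdispersion. Passing recovery tests therefore demonstrate internal
statistical consistency of the estimator with the model's own sampling
scheme, not robustness to those real-data complications.

Parameter recovery pools events over years: p̂ = (total events of the
flow) / (total start-of-year count of the source compartment), with
binomial standard error √(p̂(1−p̂)/exposure). Zero exposure raises rather
than returning 0, since the probability is then undefined. Long-run
share summaries discard a configurable burn-in (default 50 years) to
drop the transient from the out-of-equilibrium start.

## Numerical choices

- All deterministic computation in double precision; compartments are
  real numbers, not integers, in the deterministic model.
- Power iteration stops when the largest absolute per-compartment change
  in one step is below tol·Q₀, with tol = 1e-10 and a 100,000-year cap
  (the chain itself defines no stopping rule; at the default parameters
  convergence takes ≈250 years).
- S = 0 (no exit from the ill state) raises `DegenerateChainError`: the
  living population funnels irreversibly into the ill state and the
  closed form does not determine the equilibrium, so no limit value is
  invented.
- Finite-difference derivative checks use central differences on the
  unvalidated rational form (probes may step a hair outside [0,1]); the
  difference quotient carries a roundoff floor of order eps·z/h, which
  the property tests account for where a derivative passes near zero.
- Rounding for display follows the conventions above (half away from
  zero, implemented via `decimal`), with rates at one decimal per
  100,000, two decimals per 1,000, one decimal for percents.
- Report bundles are byte-stable for a fixed config apart from the log's
  timestamp line; the log records a SHA-256 config digest, library
  versions, convergence diagnostics and the rounding rules.

## Problem sizes in the test suite

Property tests run the closed-form/power-iteration comparison on 1,000
random valid parameter sets (rows drawn as scaled simplex points with
row sums in [0.1, 1) so mixing is fast), derivative checks on 200 sets ×
6 parameters, and stochastic recovery at Q₀ = 10⁶ for 500 years plus a
20-seed coverage check at Q₀ = 2×10⁵ — sizes at which binomial standard
errors are small enough to make 4-SE recovery a sharp test while the
whole suite runs in seconds.

## Limitations

- Replacement into the healthy state only; no births into the ill state,
  no migration, no demographic change. Q₀ is exactly conserved.
- One-year resolution: multiple transitions within a year (fall ill and
  die) are not representable; the estimates absorb them into the annual
  probabilities.
- Homogeneous compartments — the "mentally ill" state aggregates all
  psychiatric-service users regardless of diagnosis or severity.
- The equilibrium comparison of strategies ignores intervention cost;
  equal unit cost of risk reduction in the two groups is an assumption
  the equivalent-perturbation column makes explicit rather than resolves.
- First-order Δz projections are linearizations; they are accurate to
  printed precision for |Δp| ≲ 1e-4 here, and the exact re-solve is
  available where that is in doubt.
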