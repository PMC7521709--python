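# Methods

## Model and assumptions

The organism is reduced to `c` scalar endogenous features, each understood
as the time average of some measurable quantity over a characteristic
period (24 h for humans).  Homeostasis is modelled as first-order
relaxation of each feature toward a target that depends linearly on the
departures of all other features from their own equilibria (couplings
`ε_{i,j}`, unit diagonal by convention), on chemical doses (potencies
`ν_{i,k}`) and on disease intensities (virulences `δ_{i,l}`).  Everything
is a small-perturbation linearization around the healthy equilibrium:
nonlinear response terms, alternative out-of-homeostasis equilibria and
immune/psychosomatic feedback from endogenous features onto exposure or
disease features are all outside the model's scope by construction.  The
linear regime is a reasonable approximation of single-site binding up to
ligand concentrations of about 1.5·Kd (≈60% occupancy), which
`binding_fraction` makes checkable.

Chemical and disease features are *imposed* on the organism (no feedback
from E-type onto N/D-type), and disease-causing biological agents are
summarized by G-type growth-capacity features that obey the same linear
algebra rather than by explicit population dynamics.

## Compounding: one pass vs self-consistent

Substituting each feature's direct chemical response into its neighbours'
coupling terms once gives the compounded coefficients `ν̃ = ε·ν`,
`δ̃ = ε·δ`.  This single-substitution form is the package default because
it is the definition the rest of the calculus (activities, scaling laws)
is built on.  The fully self-consistent linear response
`ν̃ = (I − ε_off)⁻¹ ν` is available via `mode="self_consistent"`; the two
differ at second order in the off-diagonal couplings, which the test suite
verifies by the 100× gap contraction between coupling scales 1e-2 and
1e-3.

## Relaxation dynamics and stability

The coupled linear dynamics relax the deviation `x = E − E*` from the
steady state as `dx/dt = −K(I − ε_off)x`, `K = diag(k)`.  The trajectory
is propagated with the matrix exponential on the requested time grid —
exact for a linear system, no integration tolerance to tune — anchored at
the algebraic steady state of the supplied compounded system, so the
terminal state matches `steady_state` for either compounding mode.  (The
raw coupled ODE's own fixed point is the self-consistent steady state;
anchoring at the compounded steady state keeps the dynamics consistent
with whichever compounding convention the caller chose, and is exact in
the one-pass case to the same first order as the compounding itself.)
Stability is checked before propagation: all eigenvalues of `K(I − ε_off)`
must have positive real part (for the uniform-rate case this is exactly
"spectral radius of the off-diagonal coupling below 1"); otherwise a
`StabilityError` reports the spectral abscissa.  The model itself never
states a stability condition; this is the natural one for the linearized
dynamics.

## Regimen design

`design_regimen` minimizes a weighted least-squares objective over doses:
symptom/host-neutrality rows `‖ν̃N − δ̃D‖²` and growth rows
`‖ν̃^G N ± h^G‖²`, solved with bounded least squares (`scipy.optimize.
lsq_linear`) under the default nonnegativity constraint (doses are
physical amounts), or unconstrained for rank-style existence arguments.
Infeasibility is not an error: per-row residuals are always reported so
"≈0" claims are auditable.  Two sign conventions for growth suppression
are exposed because the therapeutic condition can be read either as
driving the capacity to zero (`ν̃^G N = −h^G`, the default, consistent
with `G = h^G + ν̃^G N` and suppression at `G ≤ 0`) or literally as
`ν̃^G N = +h^G`; the default is the reading that actually suppresses.

Default weights are 1 for all rows; the solver tolerance is 1e-10
relative, and agreement targets in the tests use 1e-8 absolute — standard
double-precision practice.

## Monte-Carlo scaling studies

Only means and variances of the random quantities are prescribed by the
theory, so distribution families were fixed once: potencies are centered
normals, off-diagonal couplings unit-variance normals (this is what makes
the compounded-potency magnitude grow exactly as `√c`), and dose shares
Gamma with mean 1 and standard deviation `σ_ε` (positivity guaranteed; the
spread must simply be finite).  All families satisfy the CLT conditions
the theory assumes; heavy-tailed alternatives are a non-goal.

The normalized activity uses the row-RMS convention `Ã_i =
Σ_k ν̃_{i,k}N_k / (Q·rms_k(ν̃_{i,k}))`.  A consequence worth being explicit
about: with that normalization `Σ_k u_k² = n_N` identically, so the
variance of `Ã` *across dose draws at fixed composition* equals
`σ_ε²/n_N` exactly.  The `rms` statistic of `rms_activity_scaling`
measures precisely that dose-fluctuation component (activity minus its
dose-share expectation); the full ensemble spread carries an additional
composition term with the same `1/√n_N` exponent but a larger prefactor
`√(1+σ_ε²)`.  The mean-absolute and RMS statistics are both reported —
for a centered normal they differ by `√(2/π) ≈ 0.798`, and conflating
them changes prefactors but no exponent.

For the robustness comparison, two copies of the system are perturbed
multiplicatively by `∓ϵ₁` (potencies) and `∓ϵ₂` (dose shares) and each
activity renormalized by its own perturbed row RMS.  The mean absolute
difference falls as `1/√n_N`, which is the assertion under test; the
measured prefactor is recorded next to the printed product form
`σ_ε·σ_ϵ1·σ_ϵ2`, which a direct expansion does not reproduce (the two
perturbations enter in quadrature and survive at `σ_ε = 0`), so no test
asserts it.

Problem sizes: the diversity scans use `n_N ∈ {10, 100, 1000}` with 2000
repetitions (slope standard errors ≈0.01, comfortably inside the ±0.03
band the exponent checks use); the complexity scan uses
`c ∈ {16, 64, 256, 1024}` with 32 organisms per cell, pooling all `c`
features per organism.  These sizes put every Monte-Carlo acceptance check
well under a minute on one core while leaving ≥5× margin between the
Monte-Carlo error and the asserted tolerance.  Exponents are fitted by
weighted least squares on log₁₀–log₁₀ means with Monte-Carlo standard
errors propagated to a 95% half-width.  The synergy exponent needs no
Monte-Carlo tolerance at all: activity is exactly linear in `Q/s`, so a
shared substream across `s` values recovers −1 to machine precision.

Seeding: one root seed spawns one `numpy` `SeedSequence` substream per
grid cell, so results are bit-for-bit reproducible and cells are
independent.

## Tail calculus

All tail arithmetic runs in log space through `scipy.special.log_ndtr`;
naive density ratios underflow near `X ≈ 8.5` in double precision while
the log route is accurate far beyond `X = 10`.  The threshold solves
`c·P[Z > X] = ω` by Brent's method on the log-tail over a [−40, 50]
bracket to 1e-12 in `X`.  The suppression ratio uses the closed form
`W = P[Z > √γ·X_ω] / P[Z > X_ω]` (substitute `u = √γX` in the mixed
regimen's tail integral), with `X_ω` defined from the unmixed (γ=1) tail
and held fixed — each individual regimen alone defines what "strong"
means — and is verified against direct adaptive quadrature of both tail
integrals to 1e-10 relative.

The exponential approximation `W ≈ exp(−(γ−1)X_ω²/2)` matches the exact
asymptotic `ln W = −(γ−1)X²/2 − ln γ/2 + o(1)`; its log-error band
(≤15% relative + 0.2 absolute over `X_ω ∈ [3,8]`, `γ ∈ [1.05,1.3]`) is
dominated by the `ln γ/2` prefactor the approximation drops.  The
closed-form threshold approximations for ω ∈ {1, 10} are implemented as
reconstructions (`2√(log₁₀c)` and `(log₁₀c)^{2/3}`) because their source
presentation is typographically ambiguous; they are exposed for
comparison, documented as such, and no test asserts their accuracy.

The worked-example complexities — `3×10⁴` ("low", `X_ω ≈ 3.4`) and
`10¹²` ("high", `X_ω ≈ 6.7`) for ω = 10, γ = 1.2 — are configuration
defaults chosen to represent a simple organism vs a complex host; with
them the expected strong-effect counts come out ≈2.9 and ≈0.10.

## Mixtures

The realized diversity factor of a mix is defined as the number of
distinct compounds in the union divided by the mean number per edible — a
count-based definition (abundances don't weight it), which is 1 for
identical edibles, `r` for disjoint equal-sized ones, and 1.2 for two
10-compound edibles sharing 8.  Intra-edible compositions are normalized
to mass fractions.  Bimolecular dilution factors take the concentration
of an edible-unique compound as the per-edible dose `Q/r` over the
edible's compound count; rates against a fixed organism partner scale
linearly in that concentration and rates between compounds unique to two
different edibles scale as the mean pairwise product — the square of the
linear factor exactly when edible sizes are equal.

## Synthetic fixtures

`generate_fixture` builds random organisms from a seed.  Two constrained
modes exist because the interesting identities are *not* generic:
`perfect-regimen-consistent` projects the reference-requirement vector out
of the potency row space so the healthy regimen is exactly neutral (a
constraint on admissible organisms, satisfied by construction, never by
accident), and `therapy-solvable` plants the disease's compounded
virulence load inside the compounded potency column space through a
positive dose vector (and, when growth features are requested, orients the
growth potencies so the same dose exactly suppresses the agent with
positive basal capacities).  Default construction scales: coupling spread
0.1 (safely inside the stability region for the default sizes), potency
spread 1, rates in [0.5, 2], baselines in [1, 10].

## What the synthetic ensembles do and do not show

The generators emulate the *statistical* structure the theory assumes —
independent centered potencies, CLT-friendly couplings, positive mean-1
dose shares — not any real organism's biology.  Passing tests therefore
show that the scaling laws and tail formulas follow from those
assumptions, not that real potency matrices are independent or centered,
that real coupling networks are dense Gaussian, or that real activities
are Gaussian deep in their tails.  Correlated potencies, sparse or
modular coupling topologies and heavy-tailed effects are exactly the
regimes where the printed exponents could fail, and none of them are
exercised here.

## Known limitations

Strictly linear response (no saturation, no toxic thresholds); no
feedback from the organism onto exposure or disease; G-type features
summarize pathogen fitness without population dynamics; the diversity
factor ignores abundances; the one-pass compounding convention is an
approximation whose error grows with coupling strength.
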