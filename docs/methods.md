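# Methods

## Models

All four architectures describe a single gene copy in a well-mixed volume
with discrete molecule counts and mass-action kinetics. mRNA decays at rate
β per molecule; β = 1 defines the unit of time, and the transcription rate
α (default 50) is the burst scale: a fully active promoter supports a
Poisson(α/β) mRNA distribution.

**Cooperative binding.** The promoter carries three repressor sites,
tracked as eight explicit microstates E_000…E_111. A repressor binds any
free site with association rate k_on per molecule; the dissociation rate
from a state with k occupied sites is k_on·c^(k−1)·K_r per bound site, so
the sequential dissociation constants are K_r, cK_r, c²K_r. With c = 1 the
sites are independent and the generator is invariant under site
permutations (asserted in the tests); c < 1 is cooperativity. Transcription
proceeds from every state except E_111. Free repressor is an explicit
species; since one gene depletes at most three molecules, the equilibrium
activity is computed with free R ≈ R_T:

    a(x) = (1 + 3x + 3x²/c) / (1 + 3x + 3x²/c + x³/c³),   x = R_T/K_r.

**Sequestration family.** Species are the promoter (E_F free, E_A
activator-bound and transcribing, E_R activator+repressor-bound and
silenced), free activator A, free repressor R, the inert complex R_A, and
mRNA. Reversible reactions (dissociation constant in parentheses):
A+E_F⇌E_A (K_a), A+R⇌R_A (K_s), blocking R+E_A⇌E_R (K_b), displacement
E_R⇌E_F+R_A (K_d). Totals A_T = A+R_A+E_A+E_R and R_T = R+R_A+E_R are
conserved exactly (checked exhaustively and along simulations).

**Kinetic splitting.** The equilibrium constants fix only k_off/k_on.
Every reaction shares one association rate constant k_on (default 1 per
molecule per unit time) with k_off = k_on·K. Activity is independent of
k_on except through the displacement cycle (below); the noise statistics
are not. The default puts promoter dwell times on the scale of the mRNA
lifetime, the regime in which noise-induced switch transitions are visible:
with much faster binding (k_on ≫ β) the promoter averages out, mRNA
distributions become unimodal and near-Poissonian, and the architectural
noise differences largely disappear. k_on is a first-class configuration
knob for exploring that crossover.

**Thermodynamic consistency of displacement.** The promoter cycle
E_F→E_A→E_R→E_F satisfies detailed balance iff K_a·K_b = K_s·K_d
(`thermo_cycle_gap` returns (K_a·K_b)/(K_s·K_d)). The shipped displacement
parameters give a driven cycle (gap 4×10⁻⁴), so the stationary state
depends on the kinetic splitting; it is computed with the shared-k_on
splitting throughout, in both the mean-field chain and the CME.

## Parameter calibration

These switch designs are characterised in the literature by their
qualitative regimes (strong vs weak activator, tight sequestration) and by
the resulting effective Hill coefficients (≈1.3 and ≈3 for the cooperative
switch without/with cooperativity; ≈50 for sequestration and
sequestration+blocking; ≈2 for a weak activator; ≈200 for the triple
switch) rather than by a canonical table of constants. The shipped
defaults (`src/switchnoise/configs/defaults.toml`) were therefore
calibrated once against those reported sensitivities using the mean-field
titration geometry — EC90 ≈ 1 − 9·K̃_a and EC10 ≈ 1 + 9·K̃_s/K̃_a for the
sequestration switch — and then frozen before any noise comparison was
examined:

- strong activator: K̃_a = 5×10⁻³, K̃_s = 2.5×10⁻⁵ → n_eff ≈ 45;
- weak activator: K̃_a = 0.1 (same K̃_s) → n_eff ≈ 1.8;
- blocking: K̃_b = 10⁻² on the strong-activator base → n_eff ≈ 42;
- triple switch: K̃_a = 10⁻³, K̃_s = 2.5×10⁻⁶, K̃_b = 10⁻³, K̃_d = 10 →
  n_eff ≈ 185 (displacement both rescues the activation phase and drives
  the promoter into E_R past the threshold, sharpening both edges).

K̃ denotes a constant divided by A_T (default A_T = 100 molecules). The
cooperative switch uses K_r = 2000 and c = 0.01, placing its transition at
integer-resolvable repressor counts.

## Activity and sensitivity

For the sequestration family the default backend treats titration
deterministically: given promoter occupancies, the free levels solve the
quadratic titration equilibrium A·R = K_s·R_A under conservation (with the
single promoter's content included), and the 2- or 3-state promoter chain
is solved at those levels; the two steps iterate with damping 0.5 to a
fixed point with residual < 10⁻¹⁰. The exact CME promoter marginal is
available as `backend="cme"` and agrees with the mean-field activity to
well under 2% for A_T ≥ 100 (tested on a 3×3 grid of constants); the
mean-field backend is used for curves and EC extraction because it is
continuous in the load (no integer rounding of R_T).

EC90/EC10 are bracketed on the activity grid (400 points; linear on [0, 2]
for the sequestration family, logarithmic for cooperative binding, with
automatic extension when a target is not bracketed) and refined by
bisection on the continuous model to |activity − target| < 10⁻⁶. The
effective Hill coefficient is log 81 / log(EC10/EC90); for an exact Hill-n
curve this recovers n to floating-point accuracy (property-tested).

## Chemical master equation engine

The reachable state space under per-species caps is enumerated by
breadth-first search (vectorised over the frontier). The mRNA count is
truncated at M_max (default: mean + 10 SD of the constitutive Poisson
bound); truncation is reflecting (transitions leaving the box are
dropped), the standard choice for stationary solves. The sparse generator
has column sums zero to 10⁻¹²; the stationary vector is obtained by sparse
LU with one row replaced by the normalisation constraint, with a
uniformised power iteration as fallback. A solution is accepted only if
‖Qp‖∞ < 10⁻¹⁰ and the probability on every truncation boundary is below
10⁻⁸; caps are doubled automatically until the tail criterion passes.
Doubling M_max changes mean and Fano by < 10⁻⁶ at the tested operating
points.

**Moment path.** mRNA is a linear birth-death process driven by the
promoter indicator ξ (transcription α·ξ, decay β·m) with no feedback, so
its stationary moments follow from the promoter/complex chain alone:

    E[m] = (α/β)·E[ξ],
    Var(m) = E[m] + (α²/β)·ξᵀ(βI − Q)⁻¹(ξ∘π − E[ξ]π),

where Q and π are the generator and stationary distribution of the chain
with the mRNA dimension collapsed, and the resolvent term integrates the
exponentially filtered autocovariance of ξ. This reproduces the full
truncated-joint solution to solver precision (asserted for all four
architectures) at 10²–10³× lower cost, and is what `fano_curve`, the scans
and the turnover comparisons use. The full joint solve is retained for
distribution shape (modality).

Modality of the mRNA marginal counts local maxima after merging
equal-valued plateaus, ignoring peaks carrying less than 10⁻⁴ probability
(configurable) so that far-tail ripples never register as modes.

Closed-form oracles: the constitutive gene gives exactly Poisson(α/β), and
the two-state telegraph promoter gives mean (α/β)·k_on/(k_on+k_off) and
Fano 1 + α·k_off/((k_on+k_off)(k_on+k_off+β)); both are reproduced to
10⁻⁸.

## Stochastic simulation

The Gillespie direct method over the same reaction tables (numba-compiled
with a pure-Python fallback). `simulate` records the full event log
(times + reaction indices; states reconstructed on demand) for timeseries
and promoter dwell-time analysis; `stationary_moments` streams
time-weighted first and second mRNA moments into ≥ 20 batch windows after
a 10% burn-in, with batch-means standard errors and a delta-method error
for the Fano factor. The two estimators follow identical sample paths for
the same seed and agree to 10⁻⁹. SSA stationary estimates agree with the
exact solution within three standard errors at EC90 and EC10 of every
architecture (the cross-validation asserted in the acceptance suite, run
lengths 2–4×10⁴ time units per point).

## Analysis layer

**Phase windows and noise AUC.** TAP is [0, EC90] and TRP [EC10, 2] on the
molar-ratio axis (the integration bounds are a package choice, exposed as
arguments); the Fano curve is integrated by the trapezoidal rule with
interpolated window edges.

**Scans** evaluate n_eff (mean-field) and the two AUCs (moment path, 21
loads) per grid point at A_T = 30, α = 20 — copy numbers chosen so a 4×4×2
scan completes in seconds while preserving the normalized-constant
geometry. Failures (e.g. activity never reaching 0.9) are flagged per row,
never fatal, and row order is deterministic.

**Matched sensitivity.** K_b of the blocking and triple switches is
calibrated by scalar least squares over log K_b so their mean-mRNA curves
match the sequestration-only reference (coarse log-grid profile, warning if
non-unimodal, then bounded refinement); matched mean curves agree to < 2%
maximum relative difference. Noise (variance, Fano, CV) is then compared
at loads spanning the transition. Under turnover the mean curves are
matched in the turnover scenario itself: first against the quasi-static
Poisson-mixture means, then refined against the exact stationary means at
the evaluation loads, because finite turnover shifts each architecture
away from the quasi-static limit by a different amount.

**Repressor turnover.** Production ∅→R at r_prod with degradation at
r_deg per molecule, r_prod = r_deg·R_T so the stationary mean matches the
fixed-count model. Degradation acts on complexed repressor too (releasing
the activator), making the total repressor count an exact Poisson(R_T)
birth-death; degrading free repressor only is available as a switch but,
under deep sequestration, lets the complexed pool grow until the activator
is titrated at every load — a qualitatively different model. The default
r_deg = 0.01·β (a stable protein, lifetime 100 mRNA lifetimes) keeps the
pool in the slowly fluctuating regime; at r_deg ≈ β the degradation-driven
activator release out-competes the K_s-limited release channel and the
switch chemistry itself changes. Consequences, all asserted at defaults:
sensitivity drops for every architecture (the activity becomes a Poisson
mixture over R_T, computed quasi-statically), and the stationary mRNA
variance rises at both operating points. The Fano factor is *not* uniformly
ordered — smearing R_T flattens the noise peak at the threshold while
raising the mean — so the turnover claims are asserted on variance. The
fast-turnover limit recovers the fixed-count statistics for the
cooperative switch (plain birth-death of free R); for the sequestration
family that limit is a different model, not the fixed-count one, and is
not asserted.

**Deterministic ODE.** Mass-action ODEs on the conservation-reduced
variables (promoter occupancy fractions and the complex level), all steady
states found by multi-start root solving on a deterministic grid,
classified by the eigenvalues of a finite-difference Jacobian. At the
shipped parameters the sequestration switch is monostable at every load
even where the stochastic mRNA marginal is bimodal — the bimodality is
noise-induced, not deterministic bistability. The ODE mean agrees with the
CME mean to a few percent at a few hundred molecules.

## Problem sizes in the shipped tests

Structural/exhaustive checks run at A_T = R_T ≤ 10; noise orderings and
modality at A_T = 50–100; turnover comparisons at A_T = 25–50 via the
moment path; SSA/CME cross-validation at the full A_T = 100 defaults.
These sizes are package choices balancing resolution of the sharp
transition (R_T granularity 1/A_T) against state-space growth; all
qualitative conclusions were spot-checked to be stable under doubling.

## What the defaults do and do not show

The synthetic parameter sets emulate the published operating regimes
(deep titration, strong vs weak activator, driven displacement). Passing
tests therefore demonstrate the mechanistic claims within this model
family: single gene copy, no translation/protein reporter layer, no
feedback, fixed cell volume, one shared association rate constant, and
calibrated rather than measured constants. They do not establish the
behaviour of any specific biological switch, multi-copy genes, or regimes
where the binding timescale approaches the mRNA lifetime from above.
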