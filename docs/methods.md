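# Methods

## Kinetic model

Folding is modeled as a continuous-time first-order network of
conformational states.  For the reference system (horse apomyoglobin, pH
6.0, 8 °C) the network is the sequential chain U ⇌ I ⇌ M ⇌ N' ⇌ N.  Every
directed transition carries the log-linear denaturant dependence

    ln k_ij(urea) = ln k⁰_ij + m‡_ij [urea] / RT

with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T = 281.15 K by default (both
configurable through `Constants`).  The generator matrix uses the
column-convention (columns = source species, columns sum to zero), so mass
conservation holds by construction.  Populations follow from the
eigendecomposition p(t) = V e^{Λt} V⁻¹ p(0); the stationary mode (|λ| <
10⁻⁹ × max|λ|) gives the equilibrium distribution, and the magnitudes of
the remaining eigenvalues are the apparent rate constants.  Near-degenerate
nonzero eigenvalues are handled by a deterministic 1-part-in-10⁹
perturbation of the off-diagonal rates with a warning; a matrix that stays
defective raises an error.  This is a measure-zero situation that never
arises for the fitted parameter sets.

The observable is tryptophan fluorescence, modeled per species as a linear
function of urea (intercept at 0 M plus slope), on a relative scale where
the acid-unfolded protein at pH 2.0 is 1.  A predicted trace is the
population-weighted sum of species signals.  Phase amplitudes come from the
eigenvector projection of the initial condition onto the fluorescence
functional; a phase is booked as a burst (unobservable) when its amplitude
attenuated through the dead time, |F_i|·e^{−λ_i·t_dead}, falls below an
amplitude floor (default 0.01 relative fluorescence) or when its relaxation
time is shorter than one fifth of the dead time.  The floor reproduces the
usual burst-phase bookkeeping without hand labeling; the reference study
does not state the threshold it used, so the default is a package choice.

Free-energy diagrams place states and barriers on the α-value coordinate
(cumulative kinetic m-value from N, normalized to 1 at U) with barrier
heights ΔG‡ = −RT ln(k⁰/A₀) − m‡[urea]; the pre-exponential factor
defaults to A₀ = 10⁶ s⁻¹ and only shifts barriers rigidly.

## Reference parameter set

The per-species fluorescence intercepts (U 1.25, I 0.80, M 1.90, N' 1.58,
N 1.32) and shared urea slopes (0.060 M⁻¹ for U and I, 0.045 M⁻¹ for M,
N' and N) are transcribed values.  The elementary rate constants and
kinetic m-values are *reconstructed*: the study's table of elementary
constants lives in supplementary material that is not distributed with the
package, so `reference_parameters()` builds a set that satisfies the
printed constraints simultaneously:

* aggregate stabilities and m-values at 0 M urea, with the kinetic species
  grouped into the equilibrium-resolved ones (N_eq = {N, N'}, M_eq = {M},
  U_eq = {I, U}): ΔG⁰ = 0.9 and 2.2 kcal/mol (sum 3.1), m = 1.4 and 1.4
  (sum 2.8), midpoints Cm = ΔG⁰/m ≈ 0.6, 1.6, 1.1 M;
* an N-to-M single-state gap of ~1.0 kcal/mol.  Note these first two
  constraints cannot both hold exactly: a Boltzmann aggregate {N, N'} is
  strictly more stable than N alone, so the aggregate gap always exceeds
  the single-state gap.  The reconstruction uses G(M) = 0.92 kcal/mol
  (aggregate 0.95), keeping both within ±0.1 kcal/mol;
* apparent-rate anchors: slow phase ≈ 2 s⁻¹ and fast refolding phase
  ≈ 10⁴ s⁻¹ at 0 M urea, fast unfolding phase ≈ 4×10³ s⁻¹ at 3.5 M;
* chevron shape: the fast refolding limb flattens at low urea (the
  rollover caused by the U ⇌ I pre-equilibrium, with [I]/[U] ≈ 4 at 0 M
  and unity near 1.1 M) and the slow unfolding limb rolls over near 3.5 M
  (where N and N' are equally stable);
* U ⇌ I equilibration within the CF dead time: the exchange rate is fixed
  at ten times the dead-rate (6.7×10⁴ s⁻¹ at 0 M), so only the ratio of
  the two rate constants is meaningful — mirroring its identifiability in
  the data;
* reverse rates follow from detailed balance against the state free
  energies, so the scheme reproduces its thermodynamics exactly.

One further trade-off is intentional and documented: with the aggregate
M ⇌ U_eq stability pinned at 2.2 kcal/mol and the total m between M and U
at 1.4 kcal mol⁻¹ M⁻¹, the *population* crossing of M against {U, I}
cannot sit at 1.6 M while the burst-phase pool favors I at low urea and
the fast-phase rollover is visible.  The reconstruction keeps the kinetic
evidence for I (the study's central observation) and the exact ΔG⁰/m
arithmetic; its population crossing lies near 2.25 M.  Midpoints reported
by `derived_thermo` are defined as Cm = ΔG⁰/m, which is also how the
printed midpoints were computed.  α-values come out ordered
N (0) < N' (0.16) < M (0.50) < I (0.75) < U (1).

## Synthetic data

`ExperimentDesign` encodes the two instruments: continuous flow (dead time
150 µs, the middle of the calibrated 102–175 µs range; traces to 10 ms;
default noise σ = 0.02) and stopped flow (dead time 5.3 ms; traces to
10 s; σ = 0.01).  Time grids are log-spaced from the dead time (no data
before the dead time are synthesized; the burst phase enters only through
back-extrapolated amplitudes).  Initial conditions: refolding from pH 2.0
starts as 100% U (a residual I fraction is configurable and off by
default), refolding from 0.8 M urea and unfolding start from the scheme's
equilibrium distribution at 0.8 and 0 M.  Default urea grids span 0–4 M
(CF) and 0–7.6 M (SF) for kinetics and 0–8 M in 0.25 M steps for
equilibrium curves.  Noise is additive i.i.d. Gaussian on the relative
fluorescence, seeded; the generator is bitwise reproducible given its
seed.

Equilibrium curves are generated for a default set of eight channels —
seven fluorescence wavelengths with intercept patterns emulating a
tryptophan emission series (some channels rise then fall across the two
transitions, long-wavelength channels are monotone) plus one far-UV CD
channel in mean-residue-ellipticity units.  What the generator does *not*
emulate: correlated (1/f or drift) noise, mixing artifacts,
photobleaching, wavelength-resolved kinetics, proline isomerization or
aggregation side reactions, and pH-jump transients (the pH jump is treated
as instantaneous re-equilibration of rate constants).  Passing tests
therefore demonstrate correctness of the analysis under ideal additive
noise, not robustness to instrument systematics.

## Trace fitting and curation

Traces are fitted to F_eq + Σ F_i e^{−λ_i t} by variable projection: for
fixed rates the amplitudes are exact linear least squares, and the
nonlinear search runs over log rates only, from a deterministic
decade-spaced multistart (10⁰–10⁵ s⁻¹).  The phase count (1 or 2) is
chosen by an F-test on the residual sum of squares at α = 0.01.  Phases
whose dead-time-attenuated amplitude falls below the artifact floor are
excluded from labeling and cumulative-amplitude bookkeeping (a fitted
component faster than the dead time back-extrapolates to arbitrary
values).  Labels follow condition, amplitude sign and rate order: 1 = fast
refolding rise, 2 = slow refolding decrease / slow unfolding, 2' = sole
phase of refolding from 0.8 M, 3 = fast unfolding.

`build_observations` curates an assembled chevron into fit-ready records,
reflecting what each instrument can determine: rows whose relaxation time
exceeds half the trace window are dropped (CF cannot measure the ~2 s⁻¹
phase), rows whose attenuated amplitude is below the floor or below three
times the trace's own residual noise are dropped, F_eq is blanked when the
slowest phase was unresolved, and the deepest cumulative amplitude is
blanked for traces that never saw their fast phase.  This mirrors how CF
and SF datasets are combined in practice.

## Equilibrium global fit

The three-state LEM fit shares (m₁, Cm₁, m₂, Cm₂) across channels and
profiles the per-channel baselines out exactly (they are linear given the
thermodynamics), so the nonlinear search is four-dimensional, run from ≥ 8
seeded starts with tolerances of 10⁻¹² on the objective.  Channels are
weighted by their noise — supplied, read from a `sigma` column, or
estimated in a second pass from the per-channel residual spread with a
degrees-of-freedom correction — which is essential when fluorescence and
ellipticity channels share one objective.  The CD channel's intermediate
baseline slope is weakly identifiable and is pinned to zero by default
(an option frees it).  Standard errors come from the Gauss–Newton
curvature at the optimum.  A seeded replicate study at the package's
default conditions (30 urea points, 8 channels, 1% relative noise) shows
these errors are accurate for the first midpoint but modestly
anticonservative for the second (the empirical spread of Cm₂ is about
twice the curvature value, and 2σ intervals cover the truth ~88% of the
time rather than 95%): the likelihood surface around Cm₂ is wider than
its local quadratic.  Treat midpoint uncertainties as lower bounds.

The parameterization is (Cm, m) with ΔG⁰ = m·Cm derived, and the fraction
algebra uses the folding direction N → M → U as transitions 1 and 2.
Helix content from ellipticity at 222 nm uses the linear two-reference
convention with configurable coil (−2340) and helix (−32640 deg cm²
dmol⁻¹) limits.

## Scheme optimization

The objective confronts a candidate scheme with three observation blocks:
log apparent rates (chevron records, matched by phase label), linear
cumulative amplitudes plus F_eq, and optionally an equilibrium signal
curve.  Blocks are weighted to contribute equally per degree of freedom
(the study fitted by manual exploration and states no weighting; this is
the package's choice).  An observed record with no predicted counterpart
incurs a large finite penalty (10 in log-rate units) so the objective
stays finite and deterministic.

Fitting is seeded multistart bounded least squares over {ln k⁰, m‡,
fluorescence intercepts} with bounds ln k⁰ ∈ [ln 10⁻³, ln 10⁸] and |m‡| ≤
5 kcal mol⁻¹ M⁻¹; the U and N intercepts are held at their baseline
values, as in the source analysis, and the per-species slopes stay fixed
(they are set by the measured baselines; freeing them adds nothing
identifiable, a deliberate narrowing of the nominal parameter list).
Sub-dead-time exchange steps are parameterized as (equilibrium ratio, step
m-value) with the total exchange pinned at ten times the dead-rate.
Multistart alternates local perturbations with broad draws of the ratio
and intercept parameters, whose trade-off is bimodal.  `heuristic_init`
builds a data-driven starting point by reading the chevron the way a
practitioner would (slow-limb slopes and intercepts, fast-phase plateau,
cumulative amplitudes); it centers the multistart and is the CLI default.
Per-parameter standard errors from the Jacobian curvature expose
unidentifiable directions; parameters ending on bounds are flagged.

Identifiability caveat: the N ⇌ N' elementary constants at 0 M urea are
long extrapolations from data confined to 3–4 M (the fast unfolding phase)
and are determined only as rates *within* that range; recovery tests
therefore compare those two laws at 3.9 M rather than at 0 M.  Likewise
only the U ⇌ I ratio, never the individual exchange rates, is compared.

`derived_thermo` converts a chain's rate laws into stepwise and aggregate
ΔG⁰, m and Cm (Cm = ΔG⁰/m, flagged undefined when m = 0), with aggregate
free energies by Boltzmann summation; it agrees with the eigen-solution
population free energies to 10⁻⁶ kcal/mol.  `compare_schemes` optimizes
each candidate — the five-state chain, the three four-state chains lacking
I, M or N', and the two off-pathway permutations — and reports residuals,
parameter counts and an AIC convenience value; no significance threshold
is asserted because the source comparison was visual.  On noise-free
synthetic observations the five-state fit beats every four-state variant
by orders of magnitude; with realistic noise the off-pathway permutation
of I is indistinguishable from the on-pathway chain (both at the noise
floor), exactly as expected when the U/I/M pre-equilibrium is much faster
than the rate-limiting step.

## Burst-phase intensity recovery

The back-extrapolated F0R1 of a refolding trace equals the t = 0 value of
the observable (non-burst) eigenmodes — a known linear functional of the
per-species fluorescence.  Because a residual U fraction is always present
in the U/I pre-equilibrium (~20% at 0 M urea), F0R1 is not itself the I
intercept; `recover_burst_intensity` inverts the linear relation at each
fitted trace using the scheme's rates and the other species' intensities,
then averages.  This mirrors how the burst intermediate's fluorescence was
determined in the source analysis (F0R1 was used to fix it within the
model) and recovers 0.80 to better than 1% from noise-free traces.

## Problem sizes and determinism

All randomness is seeded (generators, multistarts, replicate studies); the
test suite and the acceptance script are deterministic.  The canonical
synthetic study uses ~30 traces (CF refolding 0–3 M, CF unfolding
3.7–4.1 M, SF refolding 0.1–1.7 M, SF unfolding 2.3–5.3 M, SF refolding
from 0.8 M urea) at 40 points per decade; replicate studies use 100
seeded repeats for the equilibrium fit and 3 for the scheme fit, with
multistart counts of 1–4 in tests against a library default of 8.  These
sizes were chosen so the full analysis remains a desk-scale computation
while every identifiable parameter stays well constrained.

## Known limitations

* The reconstructed reference set matches every printed constraint within
  its tolerance but is not unique; quantities the study did not pin down
  (e.g. the I/U gap at 0 M, the m-value split within the U–M segment) are
  package choices recorded in the provenance notes.
* Curvature-based uncertainties (equilibrium midpoints, scheme
  parameters) are anticonservative where the objective is strongly
  nonlinear; see the equilibrium section.
* Trace fitting is limited to two exponential phases, as in the source
  analysis; in narrow urea windows where three relaxations have comparable
  amplitudes within one instrument's window (e.g. unfolding near 2.5–3 M
  in CF), the two-phase description smears them, and the curation rules
  exclude such records rather than model them.
* No direct refinement against raw traces (the fit targets derived rates
  and amplitudes, as the source analysis did), no parallel-pathway
  topologies, no pH-dependence, and no stochastic single-molecule
  simulation.
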