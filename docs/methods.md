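# Methods

## Scope and model

`fluxtherm` implements steady-state metabolic flux analysis (MFA) from
combined ¹³C and ²H isotope-tracer data, and the conversion of the fitted
forward/backward flux ratios into reaction and pathway Gibbs free energies.
The pipeline is: atom-mapped network model → elementary-metabolite-unit
(EMU) simulation of mass-isotopomer distributions (MIDs) → variance-weighted
least-squares flux fit with χ² goodness-of-fit → profile-likelihood
confidence intervals → ΔG = −RT·ln(J⁺/J⁻) per reaction, with
ΔG = ΔG°′ + RT·ln Q from metabolite concentrations where the flux route is
unbounded.

The shipped fixtures are *reconstructed* reduced models of central carbon
metabolism in two thermophilic, fermentative anaerobes: a
*Clostridium thermocellum*-style glycolysis (PPi-linked
phosphofructokinase, no pyruvate kinase, PEP→pyruvate via pyruvate
phosphate dikinase and/or the malate shunt) and a
*Thermoanaerobacterium saccharolyticum*-style network (ATP-Pfk, Pyk,
bifurcated TCA cycle, sedoheptulose-1,7-bisphosphate bypass in the pentose
phosphate pathway, citramalate route to isoleucine). They are built from
pathway-level knowledge of these organisms, not transcribed from any
published machine-readable model, and should be treated as biologically
plausible test beds rather than curated reconstructions.

## Atom maps and isotope bookkeeping

Each metabolite declares its tracked atoms: carbons 1..n (carbonyl-proximal
numbering) followed by optionally tracked, non-exchangeable hydrogens.
Reactions carry one lowercase letter per tracked atom; a letter present in a
reactant and a product is the same physical atom. Untracked cofactor atoms
(phosphates, CoA) never appear. Reversible reactions must be atom-complete
in both directions; tracked hydrogens that chemistry removes are therefore
routed to an explicit infinite water pool (unlabeled in both directions)
rather than silently dropped.

Hydrogen tracking is restricted to the two glucose positions (H4, H5) whose
fate reports on lower-glycolysis reversibility: H4 travels to the GAP C1
hydrogen that glyceraldehyde-3-phosphate dehydrogenase (GAPDH) abstracts
onto NAD⁺, and H5 to the GAP C2 hydrogen lost at triose-phosphate isomerase
(Tpi) or enolase. The NAD(H) hydride is modeled as a one-atom balanced pool
metabolite so that deuterium transferred by GAPDH can return on reverse
flux; this is an assumption (one shared cytosolic hydride pool, no kinetic
isotope effects), and the lumped PPP/TCA reactions outside the glycolytic
segment shed tracked hydrogens to water, which slightly under-counts ²H
retention in those (unmeasured) branches.

Symmetric metabolites (succinate, fumarate, dihydroxyacetone) are handled
by splitting every producing reaction mode into two half-weight variants,
one with the produced atom string reversed; consumed pools are then
orientation-symmetric automatically.

## EMU simulation and the isotopomer oracle

The simulator decomposes the network backward from the requested fragments
into elementary metabolite units, groups them by size, and solves one dense
linear system per size; condensation reactions enter as convolutions of
smaller EMU MIDs. Forward and backward fluxes of a reversible reaction
contribute separate flux modes, so exchange flux (J_exch = min(J⁺, J⁻))
affects labeling while net stoichiometry sees only J_net = J⁺ − J⁻.

A brute-force verifier solves the full positional-isotopomer balance
(2^atoms states per metabolite) by fixed-point iteration, restricted to
networks with ≤ 16 tracked atoms. It shares only the model parser and flux
containers with the EMU path and is used in randomized equivalence tests
(50 seeded networks, agreement < 1e-8). Its convergence rate degrades as
exchange → ∞ (recycle fraction → 1), so randomized cross-check networks
draw exchange fluxes log-uniform in [0.1, 20].

Boundary pools default to *unlabeled* (p13 = 0), which makes the analytic
tracer predictions exact (e.g. 50/50 M+0/M+1 lower-glycolysis labeling on
[1-¹³C₁]glucose); natural abundance (0.0107 per carbon) and tracer purity
(0.99 typical of commercial tracers) are opt-in for realism, and measured
data are corrected for natural ¹³C abundance before fitting (²H data are
not corrected; ²H natural abundance is ~0.0002).

## Flux fitting

Net fluxes are parameterized on the null space of the stoichiometric matrix
(after pinning reactions whose bounds coincide), so S·v = 0 holds exactly
throughout. Each reversible reaction adds one exchange parameter
x ∈ [0, 1−1e-4] with J_exch = 100·x/(1−x); the cap keeps the per-size EMU
systems well conditioned (J_exch ≤ ~10⁶ on a glucose uptake of 100) and is
far beyond any identifiable exchange. Inequality bounds on net fluxes enter
as hinge penalties. The objective is the variance-weighted SSR over all
*non-zero* measured MID fractions plus extracellular rates; measured zeros
are excluded from the residual set and from the fitted-measurement count n.
Optimization is scipy's trust-region-reflective least squares with
finite-difference Jacobians, 25 random restarts by default (seeded,
deterministic), fewer in the test suite where the problem is
well-conditioned and budgeted.

Goodness of fit: the optimal SSR of a correct model is χ²(n−p) distributed
(p = free parameters); acceptance requires SSR within the central 95% band.
Confidence bounds per flux come from parameter continuation: the flux is
fixed at trial values (a linear constraint on the null-space coordinates
for net fluxes; a pinned transform for exchange fluxes), the remaining
parameters re-optimized, and the bound located where SSR crosses
SSR_min + χ²₀.₉₅(1) = SSR_min + 3.8415. The first step is sized from a
local quadratic estimate of the profile; bisection then resolves the
crossing to ~0.5% of the flux value. A continuation that reaches a model
bound without crossing reports the bound with an at-limit flag; one that
exhausts its step budget reports "not determined" — bounds are never
silently clipped.

Known identifiability limits, surfaced deliberately by the tests: dilution
inflows and the cofactor (NADH) source/sink pair have flat SSR directions;
the PEP→pyruvate split between pyruvate phosphate dikinase and the malate
shunt is degenerate when oxaloacetate/malate labeling is not measured
(their carbon outcomes are identical), which appears as continuation
intervals spanning the feasible range while glycolytic flux ratios are
unaffected (< 1% cumulative free-energy difference between ± malic-enzyme
model variants on the same data).

## Thermodynamics

ΔG = −RT·ln(J⁺/J⁻) in kJ/mol, R = 8.314 J·mol⁻¹·K⁻¹, default
T = 328.15 K (55 °C, the thermophiles' growth temperature; always explicit
in `ThermoContext`). Confidence bounds map the net/exchange flux intervals
through the worst-case rectangle (largest J⁺ with smallest J⁻ and vice
versa), which is conservative. An exchange lower bound of zero makes the
reaction free energy unbounded in the negative direction; the report then
switches to ΔG = ΔG°′ + RT·ln Q when standard free energies (eQuilibrator
convention: pH 7, ionic strength 0.1, supplied as constants) and
concentrations are available, propagating concentration SDs by interval
arithmetic (products at their extremes). Pathway free energies are sums of
the per-reaction best fits with interval-summed bounds — conservative
relative to a joint continuation, and labeled as such.

## Synthetic data

The generator defines the study conditions for every recovery experiment:

* glucose uptake normalized to 100; all fluxes in mol per 100 mol glucose;
* the five-tracer panel [1-¹³C₁]-, [6-¹³C₁]-, [4-²H₁]-, [5-²H₁]glucose and
  an equimolar [U-¹³C₆]/unlabeled mixture;
* measured panel: G6P, F6P, FBP, DHAP, 3PG, PEP, pyruvate (full fragments)
  plus uptake, ethanol and acetate rates;
* MID fraction SD 0.003 (absolute), rate SD 5% (relative) — chosen once as
  representative of replicate scatter in steady-state LC-MS labeling data;
* exchange fluxes for randomly sampled truths drawn log-uniform
  [0.1, 1000];
* two reference truths: a near-equilibrium-Pfk state (J⁺/J⁻ = 1.701,
  ΔG = −1.45 kJ/mol) and an effectively irreversible-Pfk state
  (J_exch = 0.05), the contrast every thermodynamic test exercises.

Noise structure. A measured MID is a composition (it sums to 1), so its
per-bin errors cannot be independent. The generator draws Gaussian noise on
the detectable bins *projected onto the zero-sum subspace and rescaled* so
each bin's marginal SD equals the declared 0.003 exactly; the reported
vector remains a composition and the variance-weighted SSR at the truth has
expectation n, the structure the χ² test assumes. Plain i.i.d. noise with
clip-and-renormalize was evaluated first and rejected for cause: the
spurious positive mass it deposits on structurally-zero bins biases every
large fraction low by ~1 SD, which measurably degraded confidence-interval
coverage. Bins whose true fraction is below a quantitation floor (1e-3) are
reported as exact zeros — this is how undetected isotopomers appear in real
MID tables and is what gives the "all non-zero MIDs" counting rule its
meaning — and a metabolite with fewer than two detectable bins under a
tracer is omitted for that tracer, since a one-bin composition is
deterministic and carries no residual. Negative values left by noise are
clipped at zero and the vector renormalized (rare at the defaults).

What the generator does *not* emulate: correlated chromatographic drift,
ionization suppression, replicate-to-replicate SD heterogeneity,
natural-abundance contamination (unless enabled), isotopic non-stationarity
and compartmentation. Passing recovery tests therefore demonstrate the
estimator's correctness under its own assumptions, not robustness to every
real-data pathology.

## Problem sizes in the shipped studies

The randomized studies run at deliberately modest scale, chosen as the
package's own test design: oracle equivalence on 50 seeded ≤16-atom
networks; recovery and χ²-acceptance on the ~17-reaction glycolysis core
with the five-tracer panel over 20 seeds (2 optimizer restarts — the core
fit is well-conditioned, and restart invariance is tested separately);
confidence-interval coverage on a one-degree-of-freedom EMP/ED route-split
model over 20 seeds, where the interval construction is the same code path
as on the full fixtures. Stochastic assertions use the central 99% binomial
band of their nominal rates so the suite's false-failure probability stays
low.

## Numerical choices

* EMU systems: dense LU per size class; singular systems (an EMU with no
  inflow) raise with the EMU named rather than being regularized.
* Simulated MIDs are validated to sum to 1 within 1e-6 and clipped of
  sub-1e-12 negative round-off.
* Natural-abundance correction inverts the binomial contamination operator
  by non-negative least squares (never a raw matrix inverse), then
  renormalizes; an ill-conditioned operator (formula carbons far exceeding
  fragment length) warns but still returns.
* Optimizer convergence: xtol 1e-12/ftol 1e-12 for fits (max 2500 residual
  evaluations), relaxed to 1e-10/1e-9 (max 600) inside continuation
  re-optimizations.
* Ties and degenerate inputs: empty pathway lists sum to ΔG = 0; route
  weights are clipped to [0, 1]; equilibrium fluxes (J⁺ = J⁻) give ΔG = 0
  exactly.

## Known limitations

* Fixtures are reconstructions; absolute flux values carry no biological
  authority.
* The ²H model ignores kinetic isotope effects and assumes a single
  well-mixed NAD(H) hydride pool.
* Pathway ΔG bounds are interval sums (conservative).
* Exchange fluxes near the detection limit of the data (very small or very
  large) are reported with one-sided or at-cap intervals rather than point
  estimates — an honest reflection of their identifiability.
* The isotopomer oracle is exponential in tracked atoms and exists for
  verification, not production use.
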