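# Methods

This note documents the models, algorithms, defaults and design decisions
behind `comamflux`, and states what the synthetic-data tests do and do not
demonstrate about real measurements.

## The network model

The shipped KF-1 model is a 57-reaction atom-mapped reconstruction of
central carbon metabolism during gluconeogenic growth on 4-hydroxybenzoate
(4HB).  Atom maps are per-reaction lowercase letter strings; position 1 is
the carboxyl carbon as conventionally drawn.  Structure:

- **Funnel**: uptake, PobA (4HB → PCA, −1 NADPH), then the six-step
  4,5-*meta* cleavage PCA → 4CHMS → PDC → OMA(enol) → OMA(keto) → CHA →
  pyruvate + OAA.  The 4CHMS → PDC dehydrogenase regenerates one NADPH, so
  the 4HB → PDC stretch is NADPH-neutral.  The enol/keto tautomerization is
  kept as an explicit reversible step assumed at equilibrium (unconstrained
  exchange), which both preserves the six-step count of the route and
  honors the equilibrium treatment of the pathway's spontaneous reaction.
  The aldol split sends PCA's carboxyl carbon to OAA carbon 1 and the
  ring carbons to pyruvate and OAA positions 2–4, following the ring-
  cleavage chemistry (4,5-dioxygenase opens the C4–C5 bond; the new
  carboxyl and the original carboxyl end up at opposite ends of the CHA
  chain).
- **TCA cycle** with separate Mdh (reversible, NADH) and Mqo
  (malate-oxidizing, quinone-side) steps; oxidative reactions from OAA to
  succinate irreversible; succinate ↔ fumarate ↔ malate ↔ OAA reversible.
- **Glyoxylate shunt** (AceA, GlcB), **cataplerosis** (PckG OAA→PEP, two
  malic enzymes, an OAA→pyruvate decarboxylation), PDH, PEP synthetase,
  the gluconeogenic EMP chain as single-enzyme steps, the non-oxidative
  pentose phosphate pathway (*C. testosteroni* lacks the oxidative branch),
  CO₂ exchange, eleven biomass-precursor effluxes, the six measured
  secretions (PCA, PDC, pyruvate, α-ketoglutarate, malate, glutamate), and
  an ATP-maintenance reaction.

No complete atom-mapped reaction list or strain-specific biomass
stoichiometry is available for KF-1; this reconstruction is therefore
labeled as such, every quantitative default that depends on it is
synthetic, and the structural tests (count, carbon balance, route
topology) are the only claims tied to it.

Symmetric metabolites (succinate, fumarate) carry a `symmetric` flag; the
EMU graph builder splits every producing flux 50/50 between the two carbon
orientations, which is arithmetically identical to inserting explicit
scrambling pseudo-reactions but keeps per-reaction carbon balance exact
and the reaction count meaningful.

Mqo and ME-2 are present in the model but pinned to zero net flux in the
default fit configuration: both proteins are undetected during growth on
4HB, and each is structurally collinear with another reaction (Mdh
reverse; ME-1), so freeing them would only create flat directions.

## EMU simulation and its oracle

Steady-state MIDs are computed by elementary-metabolite-unit
decomposition: target EMUs are traced backward through the atom maps,
condensations become convolutions of smaller EMUs, and each EMU size is a
dense linear system weighted by unidirectional fluxes
(`v_f = max(v,0)+e`, `v_b = max(−v,0)+e` with exchange `e ≥ 0`).  Systems
are solved dense per size block; the networks here stay well under 10³
EMUs.  An EMU with zero total inflow is reported by name as a singular
balance.

Tracer specifications give per-position ¹³C probability *beyond natural
abundance* plus an unlabeled-fraction weight for mixtures; natural
abundance is handled entirely at the measurement boundary (below), so the
simulator works on "label beyond natural" throughout.

The independent reference (`isotopomer_ref`) tracks the full 2ⁿ
positional-isotopomer distribution of every pool and solves the same
steady state by fixed-point iteration, sharing no code with the EMU path.
Equivalence is asserted to 10⁻⁸ on randomized small networks (random
permutation atom maps, a cleavage, a condensation, optional reversibility
and an optional symmetric pool, random feasible fluxes and tracer).

## Natural-abundance correction

Only carbon is corrected.  The forward contamination of a true MID is the
lower-triangular binomial matrix `C[i,j] = C(n−j, i−j)·a^(i−j)·(1−a)^(n−i)`
with `a = 0.0107` by default; correction solves the triangular system,
clips small negative fractions produced by noise and renormalizes (the
unclipped inverse is exact and is what the round-trip property tests).

## Flux fitting

Net fluxes live on the affine steady-state basis `v = v₀ + N·u` obtained
by fixing the measured rates (uptake, secretions, biomass effluxes, plus
any configured zero-flux reactions) and taking the null space of the
remaining stoichiometry.  Free parameters are `u`, log₁₀ exchange fluxes
of the reversible reactions (log scaling because exchange is scale-free
and weakly identified; bounds 10⁻³ to 50× uptake), and optionally the ¹³C
content of the dissolved-CO₂ pool.  The objective is the variance-weighted
SSR pooled by simple summation over all datasets; replicates of the same
tracer scheme share one simulation per objective evaluation.

Optimization is multi-start (seeded; feasible starting points sampled
inside LP-derived bounds of the flux polytope, exchanges started in the
low decades where the objective still has curvature).  Each start runs a
short nets-only stage with exchanges held fixed, then a full
trust-region-reflective least-squares refinement with a hard iteration
budget; irreversibility enters the search as a steep hinge penalty and the
returned solution is verified and, when needed, polished under the exact
linear inequality constraints, so reported flux vectors satisfy steady
state and irreversibility exactly.  The default restart count is 100; the
shipped tests and the acceptance script use 2–6 restarts, which suffices
on the toy and KF-1 synthetic problems at their problem sizes.

Degrees of freedom count each measured MID as (length − 1) independent
channels (closure removes one) and each measured efflux as one
measurement balanced by one pinned parameter (net contribution zero,
which keeps the χ² statistic calibrated while honoring the bookkeeping
convention).  A fit is accepted when SSR ≤ χ²₀.₉₅(dof).

Profile-likelihood CIs rescan one flux (net or exchange), re-optimizing
all other parameters, until SSR exceeds SSR_min + 3.84, with bisection
refinement; a side that never crosses within 20× uptake is reported open.
`linearized_flux_sd` provides the cheap Gauss–Newton approximation used
for whole-flux-map uncertainty screens (e.g. the 3-sd recovery check on
the KF-1 synthetic fit); profile CIs remain the reference on individual
fluxes.  Reported per-flux sd from a CI is (hi − lo)/3.92, a
symmetric-normal approximation.

## Flux-ratio analysis

`infer_positional` allocates a parent's M+1 fraction across carbon
positions from fragment MIDs by non-negative least squares with a closure
row; positions with identical fragment-coverage patterns are reported as
groups, and a rank-deficient system raises rather than returning an
arbitrary allocation.  The low-enrichment (≤ M+1) regime is enforced with
a warning threshold of 5% on M+≥2.

OAA positional labeling is read off citrate fragments through the model's
citrate-synthase atom map (OAA C1→cit6, C2→cit3, C3→cit4, C4→cit5), not a
hard-coded lookup.  The PEP partition solves the two balance equations
jointly across replicates by a closed-form constrained quadratic
(f₁ + f₂ = 1, f ∈ [0,1]); the replicate objective is unweighted SSR.
`solve_two_source` mixes across all mass channels after projecting each
source onto the target's carbon skeleton (`project_mid` assumes
exchangeable positions — hypergeometric — for mass-only inputs;
`project_positional` is exact in the low-enrichment regime; symmetric
targets get orientation averaging).

## Thermodynamics and the cofactor ledger

ΔG = −R·T·ln(v_f/v_b) with R = 8.314×10⁻³ kJ·mol⁻¹·K⁻¹ and T fixed at
303.15 K (30 °C culture temperature); no concentration-based ΔG′ is
attempted.  One-sided flux returns a signed-infinity sentinel (rendered
"<−30 kJ/mol" in reports).  ΔG sds propagate from flux sds by the
first-order delta method.

The ledger pools NADH with FADH₂ at a common P/O ratio (default 1.5),
closes NADPH by transhydrogenase-equivalent transfer in whichever
direction the balance requires (the machinery reports the required
transfer without asserting its mechanism), respires the remaining
NADH/FADH₂ to ATP, and reports the surplus beyond the anabolic demand.
Closure (production + transfer in = consumption + transfer out + surplus)
holds identically for every input; a negative respiration value flags a
redox-infeasible flux vector instead of hiding it.

## Physiology

μ is the least-squares slope of ln(OD) versus time inside a user-chosen
exponential window (window selection is explicit, not auto-detected).
Exchange rates use q = μ·(dC/dX) with X = conversion·OD in g_CDW/L —
under balanced exponential growth concentration is linear in biomass, so
this single regression absorbs the growth-rate and biomass accounting.
Sign convention everywhere: negative = consumption, positive = secretion.
Secretion classification requires a positive concentration trend at
one-sided p < 0.05 (the significance threshold is this package's choice).
Carbon partition uses a configurable biomass carbon content, default
40 mmol C/g_CDW (typical heterotroph value); no shipped numerical result
depends on that default.

## Nonstationary kinetics

`simulate_switch` integrates `P_m·dx/dt = Σ v_in·(x_source − x_m)` in EMU
space with BDF (rtol 10⁻⁸), convolution inputs evaluated from the current
state.  Initial EMU states derive from per-metabolite MIDs by
hypergeometric marginals (positions treated as exchangeable absent
positional information).  Pools of unquantified metabolites default to
0.1 µmol/g_CDW; growth dilution is neglected on the ≤30 min horizon
(μ·t ≪ 1); extracellular pools are infinite sources/sinks.  Simulation
only — no fitting to kinetic data.

## Synthetic data and what the tests show

The default scenario uses the standard parallel-labeling layout: two
labeling schemes
([1-¹³C]-carboxyl-4HB and [¹³C₆]-phenyl-4HB), three replicates each, MID
noise sd 0.005, efflux rate noise 10% relative (switchable off).  The
truth flux vector is an invented, documented stand-in chosen to express
the physiology of 4HB-grown cells quantitatively: uptake normalized to
100 with ~92% reaching the aldol split, glyoxylate shunt 3%, OAA→PEP 5.6%,
cataplerosis through ME-1 (net 66, exchange set so ΔG ≈ −3.95 kJ/mol), a
near-equilibrium succinate↔OAA arm (large exchanges; |ΔG| < 2 kJ/mol)
that yields ≈40% OAA-derived fumarate in the two-source readout, zero
Mqo/ME-2/OAA-decarboxylase flux, and biomass demands that place the PEP
source split at 82% pyruvate / 18% OAA.  Dissolved CO₂ is 5% labeled.
Generated file headers carry a synthetic-provenance note.

Measurement noise is zero-sum Gaussian in the simplex-orthogonal subspace
(per-channel scale 0.005, then clipped and renormalized — clipping is
rare at that scale).  Keeping the noise inside the closure constraint is
what makes the χ² statistic exactly χ²(length−1) per MID and hence the
acceptance-rate and coverage calibrations exact; real instruments add
further structure (correlated drifts, intensity-dependent variance) that
this model deliberately omits.  Calibration scenarios run with natural
abundance 0 so that the linear correction does not reshape the noise
covariance; the KF-1 scenario applies the full forward/inverse
natural-abundance cycle.

Passing tests therefore demonstrate internal correctness — solver
equivalence, statistical calibration under the stated noise model, and
round-trip identifiability at the stated problem sizes — not agreement
with real measurements, which would require archived LC–MS data.  The fitted-flux values printed by the acceptance script are
estimates on synthetic data; they are not re-derivations of any measured
flux map.

## Numerical choices and limitations

- EMU/linear algebra: dense solves per size block; zero-throughput EMUs
  raise with the EMU named.
- Exchange fluxes below 10⁻³ (the search floor) are numerically
  indistinguishable from irreversible; self-consistency tests that need
  exact zero exchange lower the floor to 10⁻⁶.
- The fit landscape has genuine flat directions (e.g. OAA→PEP versus
  OAA→pyruvate→PEP, and CO₂-recycle magnitude); these appear as wide
  linearized sds and open profile bounds rather than being suppressed.
  Anchoring the CO₂ labeling (measurable via N-carbamoyl-aspartate) removes
  the worst of them, and the acceptance fit does so.
- The exhaustive isotopomer reference is exponential in carbon count and
  is only used on networks with small metabolites (≤3 carbons each in the
  randomized instances; the cross-check covers networks of ≤8
  tracked carbons per molecule).
- Vanillate and terephthalate funneling, the *ortho* and 2,3-*meta*
  cleavage routes, instationary MFA fitting, Bayesian uncertainty, and
  genome-scale modeling are out of scope.
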