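# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic data can and cannot show.

## Flux balance analysis

All analyses solve linear programs of the form max/min c'v subject to
S·v = 0, lb ≤ v ≤ ub, plus extra linear rows. The backend is the HiGHS
simplex solver (SciPy), which returns a basic optimal solution — a vertex
of the flux polytope. Optimal flux vectors are generally non-unique;
every statement of the form "reaction X carries (no) flux at the optimum"
is therefore made through flux variability analysis (per-reaction min/max
subject to retaining a fraction of the optimum), never by inspecting a
single returned vertex.

Numerical conventions: solver primal feasibility 1e-9; objective values
compared across methods/backends at 1e-6; FVA performed at fraction 1.0
with the objective locked by an extra row (so ratio couplings compose with
it). Reversible reactions are single variables with negative lower bounds;
the default bound magnitude is 1000 mmol gDW⁻¹ h⁻¹. Flux-ratio couplings
are extra matrix rows (v_target − k·v_reference {≤,=,≥} 0), not bound
substitutions.

For fixtures of ≤ 8 reactions an independent oracle enumerates every
polytope vertex by trying all active-constraint combinations
(`cyanoflux.oracle`); FVA ranges at fraction 1.0 follow as coordinate
extrema over the optimal vertices. The engine is tested against this
oracle, and on the core network against cobrapy (GLPK) reading the emitted
SBML.

## The scenario parameters

The reference condition for growth under constant light fixes, per the
study conditions the package encodes:

| parameter | default | unit | rationale |
|---|---|---|---|
| growth rate target | ln 2 / 24 ≈ 0.0289 | h⁻¹ | 24 h doubling time |
| carbon source | bicarbonate only | — | net exchange; no Ci cycling |
| maintenance ATP | 0.13 | mmol gDW⁻¹ h⁻¹ | common value in cyanobacterial FBA models |
| oxidase coupling | O₂ uptake = 10% of PSII O₂ evolution | — | residual light respiration, as an equality |
| Mehler-like coupling | O₂ uptake = 10% of PSII O₂ evolution | — | flavodiiron water–water cycle, no ROS |
| superoxide | 0.5% of PSII and PSI electron flow | — | detoxified via SOD + NADPH peroxidase |
| oxygenase bound | v_oxy ≥ 3% · v_carb | — | imposed only in photorespiration scenario 3 |
| storage flux | 0.01 | mmol gDW⁻¹ h⁻¹ | modest glycogen accumulation in the light |
| light bound | calibrated | mmol photons gDW⁻¹ h⁻¹ | set so the optimum hits the growth target |

Electron bookkeeping for the couplings: 4 e⁻ per O₂ evolved at PSII, 1 e⁻
per PSI turnover, 1 e⁻ per superoxide. The couplings are tied to PSII
activity and are dropped when PSII cannot run (dark, or DCMU), since they
describe *light-phase* residual respiration; dark respiration is
constrained separately. The literature also reports ~20% of water-derived
electrons reaching O₂; the coupling fractions are plain config fields, so
that variant is available by setting `mehler_like_fraction=0.2`.

Light calibration iterates a proportional update (growth is linear in the
light bound in the light-limited regime; the fixed maintenance/storage
demands make the relationship affine, hence 2–3 iterations converge to
1e-9).

Dark metabolism maximizes the biomass objective under a glycogen budget of
(1 + ε)·(maintenance equivalent), ε = 0.1, where the maintenance
equivalent is the minimal glycogen mobilization covering maintenance ATP
with growth switched off. When TCA-closure variants are compared, the
budget is derived once from the base configuration and shared, so the
variants differ only in topology. Glutamate dehydrogenase is irreversible
(toward glutamate) by default to exclude transhydrogenase-mimicking
cycles.

## The synthetic core network

`build_core_model` emits a ~100-reaction, two-compartment network that
stands in for a genome-scale reconstruction: photon capture, PSII, the
PQ/b6f/PC/PSI chain with cyclic electron flow, FNR, NDH-1 (NADPH-specific,
with an optional NADH-accepting mode), terminal oxidase, the Mehler-like
reaction, a superoxide branch with SOD and peroxidase, ATP synthase driven
by a massless proton-motive token, the CBB cycle with separate RuBisCO
carboxylase/oxygenase, photorespiratory salvage (2PG → glycolate →
glyoxylate → glycine → serine, plus the glycerate re-entry), an optional
phosphoserine branch, lower glycolysis, an optional phosphoketolase and
malic enzyme, the OPP lump, TCA reactions with all four closure options,
glycogen synthesis/degradation, nitrate/sulfate assimilation, and a
biomass function over protein/DNA/RNA/cell-wall/lipid/pigment/ion
component pseudo-metabolites.

Design choices that matter for its behavior:

* **Balancing.** Every chemical reaction is elementally balanced for C, N,
  O, P and S and charge-balanced; biomass-component formulas are computed
  as the exact residual of their synthesis reactions, so balance holds by
  construction. Hydrogen is tracked loosely through the massless photon
  and proton-motive tokens, and the checker reports H separately —
  protonation conventions are pH-dependent and deliberately out of scope.
* **Inorganic carbon is not cycled.** Uptake is bicarbonate-only;
  bicarbonate is dehydrated in a carboxysomal pool feeding the
  carboxylase; PEP carboxylase consumes bicarbonate directly; respiratory
  CO₂ can only diffuse out. Without this separation, a burn-and-refix
  route (oxidize acetate, lift the electrons to NADPH through the shared
  PQ pool and PSI, refix the CO₂) makes photoheterotrophic growth on
  acetate possible *without* a glyoxylate shunt, contradicting the
  reference behavior the network is meant to reproduce.
* **No NDH-2.** The dark redox-routing alternatives (cyclic TCA versus
  OPP, depending on transhydrogenase and NDH-1 substrate assumptions)
  require that TCA-derived NADH has no quinone-level sink other than the
  toggled routes; a non-pumping NADH dehydrogenase would create a mixed
  optimum with residual cyclic flux in the no-transhydrogenase case.
  Acetyl-CoA remains reachable without NADH production via the
  phosphoketolase, so dark biomass synthesis stays feasible.
* **Protein composition.** The protein-equivalent is a 71-residue unit
  with a realistic serine-family share (7% Gly, 7% Ser, 1.4% Cys). The
  ~5% optimal photorespiration rate in scenario 1 *emerges* from this
  demand; it is not pinned anywhere.
* **Stoichiometric lumping.** Quantum yields, P/O-type ratios (4 pmf per
  PSII turnover, 2 per b6f/oxidase/NDH-1, 3 pmf per ATP) are nominal.
  Only relative and qualitative flux statements are meaningful on this
  network; absolute flux magnitudes are not comparable to measured data.

Known deviations from the genome-scale behavior, accepted as limitations
of the lumped topology: (i) in photorespiration scenario 3 the glycine
route is strictly preferred over the glycerate re-entry (their exact yield
degeneracy is a property of the full network's stoichiometry, so the FVA
check of two simultaneously open routes applies only there); (ii) in dark
scenario 1 the residual serine demand is met through the oxygenase route
rather than by proline degradation (the proline synthesis/degradation
reactions exist, but the lumped network lacks the full amino-acid
catabolism that makes proline the optimal donor).

## Diurnal simulation

The day is discretized into n steps (default 48, i.e. 30 min); light
follows a triangle from dawn (CT 0) to an apex at mid-day to zero at dusk
(CT 12). Each step solves one LP; steps are coupled only through the
glycogen pool.

Synthesis rules, per component: DNA and inorganic ions at a constant rate;
protein, RNA, cell wall and lipid at rates proportional to light; pigment
in a window from CT 22 to CT 10 with linear ramps over
`smoothing_steps` steps. Per-component daily totals default to the
reference biomass composition times the reference growth rate times 24 h,
and the per-step rates are imposed as equality constraints — "a new
biomass function each step" realized as fixed synthesis proportions.
The step objectives are then: before mid-day, minimize photon uptake
(meet the targets parsimoniously); from mid-day to dusk, maximize glycogen
storage; at night, maximize ATP production subject to maintenance, with
glycogen drawn down evenly toward dawn (per-step mobilization bounded by
pool / time-remaining) and residual oxidase activity at
`dark_respiration_fraction` (default 0.1) of the observed light-phase
maximum. Day-phase glycogen mobilization is closed, reflecting the
dark-induced regulation of glycogen phosphorylase.

The default light peak is 10× the calibrated constant-light bound. This is
deliberately generous: the thin-light steps adjacent to dawn and dusk
still carry the constant DNA/ion (and windowed pigment) demand, so edge
steps become infeasible if the peak is too low; 10× keeps discretizations
up to roughly 100 steps/day feasible. An infeasible step truncates the
trajectory with a diagnostic rather than raising.

Carbon bookkeeping integrates exchange fluxes (left-Riemann, matching the
pool update) and compares imported carbon against carbon accumulated in
components plus the glycogen pool change; on the synthetic network this
closes to machine precision, and the acceptance check requires 1%.

## Transcript-rhythm statistics

Oscillation strength is the power spectral density at 1/24 h⁻¹,
pd = |Σₖ xₖ e^(−2πi tₖ/24)|²/n on mean-centered values — a direct Fourier
projection valid for uneven designs (an unnormalized single-frequency
Lomb–Scargle for centered data). Replicates enter as independent samples
at their recorded times. Significance is a permutation test (shuffle
values over the fixed time multiset), p = (1 + #{pd* ≥ pd})/(n_perm + 1);
the production default is 10⁵ permutations, tests use 10²–10³.

The Least-Oscillating Set is the genes with p above a threshold on the
*raw* matrix; the threshold is a required analysis parameter (default 0.5
in the CLI). Normalization fits, per array, a lowess curve (tricube
weights, local linear, default span 0.75, deterministic jitter on tied
anchors) of the array's LOS deviations against the LOS cross-array means,
and subtracts the interpolated curve from all genes on that array. A
narrow span (~0.2) is appropriate when the technical distortion varies on
a scale comparable to the intensity range.

Phase is the peak time of the least-squares cosine fit at 1/24 h⁻¹,
solved from the 2×2 normal equations. On uneven designs the raw Fourier
argument is biased by spectral leakage (≈1 h on the six-point design used
here); the least-squares phase is exact for noiseless cosines on any
design and reduces to the Fourier argument for even sampling.

The expression simulator writes oscillators as
baseline + A·cos(2π(t − φ)/24) with uniform phases, plus Gaussian noise,
an additive array-level trend rising over the subjective day, and an
optional smooth intensity-dependent distortion. It emulates the
six-timepoint, two-replicate circadian design (CT 0.5, 5.5, 11.5, 12.5,
17.5, 23.5). It does not emulate spot-level artifacts, count noise,
missing values or gene–gene correlation, so passing tests demonstrate
calibration and recovery under an idealized technical model, not
performance on raw array data.

## Problem sizes used in checks

Self-tests and the acceptance script use: the ~100-reaction synthetic
network for all scenario properties; 48-step (plus 24- and 96-step)
diurnal runs; 2000 simulated null genes at 999 permutations for test
calibration; 400 oscillators at signal-to-noise 3 for phase recovery; and
800-gene matrices for normalization checks. The published genome-scale
network (677 genes / 759 metabolic reactions) is supported through the
same role-map interface but must be provisioned separately
(`data/external/README.md`).
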