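# Methods

## Model

The package reconstructs ABA-dependent *RD29A* expression as a mass-action
reaction network in a single cell of 50 µm³. State variables are
concentrations (µM); time is in hours. The network has 45 species and 77
reactions: the ABA input (clamped), 19 protein/complex species, promoter
occupancy states for the eight gene loci, and 11 mRNA pools.

Modelling assumptions, stated once:

- One representative protein stands for each redundant family (one PYR,
  one PP2C, one SnRK2, one ABF); no spatial structure; free diffusion.
- Enzymatic steps are resolved into elementary mass action: reversible
  binding (second-order association, first-order dissociation) followed by
  an irreversible first-order catalytic step, so that K_M = (kr + kcat)/kf.
- Every association uses the generic diffusion-limited constant
  1000 µM⁻¹ s⁻¹ except DREB2A–proteasome (5 µM⁻¹ s⁻¹, curated
  separately); dissociation constants encode the curated affinities.
- ABA is a boundary species: clamped to the dose, never consumed. The
  doses of interest (1–200 µM) dwarf the ~0.1 µM protein pools, so
  depletion would be negligible anyway.
- Genes are expressed from a pair of loci (2 copies in 50 µm³ =
  6.64×10⁻⁵ µM). Constitutive transcription kf29 = 1 h⁻¹ and translation
  kf30 = 4.5 h⁻¹ against protein decay 0.05 h⁻¹ and mRNA decay 0.06 h⁻¹
  place each constitutively expressed protein pool at
  (6.64e-5 · 1/0.06) · 4.5/0.05 ≈ 0.0996 µM — the 0.1 µM design value.
  This holds for the *total pool* of a protein identity; tight binding
  (e.g. the 100 pM PP2C–SnRK2 interaction) necessarily redistributes the
  free forms, and DREB2A is deliberately sub-baseline because its
  proteasomal proteolysis is active even without ABA.
- The *PP2C*, *ABF* and *DREB2A* genes carry one ABRE each (shared
  binding constants kf10/kr10, K_D 2 nM) driving a feedback channel
  (transcription kf26, translation kf28) through a second mRNA pool per
  gene; the constitutive promoter of these genes fires regardless of ABRE
  occupancy.
- The *RD29A* promoter has four micro-states — free, ABRE-bound,
  DRE-bound, doubly bound — with binding rows kf14/kr14 (ABRE from free),
  kf11/kr11 (DRE from free), kf12/kr12 (ABRE when DRE occupied),
  kf13/kr13 (DRE when ABRE occupied). Only the doubly bound state
  transcribes (rate kf27). All four affinities are 2 nM; the allocation of
  the rows to micro-states is a reconstruction choice, since only their
  roles (feedback ABREs vs *RD29A* ABRE) are pinned down externally.
- Degradation at 0.05 h⁻¹ applies to every free protein and
  protein-containing complex (whole-complex removal). DNA-bound
  transcription-factor states are exempt: locus conservation (the four
  *RD29A* states, and free/bound states of each feedback gene, each sum to
  6.64×10⁻⁵ µM for all time) is structurally required, and the bound
  factor re-enters turnover on dissociation. All mRNA pools decay at
  0.06 h⁻¹.
- DREB2A proteolysis: DREB2A + 26S ⇌ complex (kf16 = 5 µM⁻¹ s⁻¹,
  kr16 = 50 s⁻¹) → 26S (kcat16 = 10 s⁻¹, the generic enzymatic kcat).
  kr16 and kcat16 are not curated anywhere; both are taken from the
  model's own generic conventions (kr16 mirrors the assumed ABA–26S
  dissociation, kcat16 the generic catalytic rate). ABA–26S binding
  (K_D 0.05 µM) sequesters the proteasome and thereby stabilizes DREB2A
  during ABA exposure; the sequestered proteasome does nothing else.

The three expression parameters kf26, kf27, kf28 are the only non-fixed
entries in the parameter table (defaults 10, 10, 200 h⁻¹).

## Simulation protocol

All experiments use a two-phase protocol: integrate 300 h from the all-zero
initial state (gene loci excepted) with ABA clamped at 0 µM to reach the
quasi-steady pre-stimulus state, then clamp ABA to the dose and follow the
response for 300 h. Reported time starts at the step. The equilibration
result carries max |dx/dt| / max(|x|, atol) as a convergence diagnostic;
doubling the equilibration to 600 h moves the wild-type peak by under 1%
(tested), so 300 h is treated as converged.

## Numerics

- Integrator: LSODA (via `scipy.integrate.solve_ivp`) with an analytic
  Jacobian assembled from the flux structure; rtol 1e-8, atol 1e-12 µM.
  The tight absolute tolerance is needed because meaningful outputs sit at
  1e-6–1e-4 µM. The system is very stiff (fastest dissociation ~2.5e8 h⁻¹
  against expression dynamics over hundreds of hours), so a fixed implicit
  BDF integrator also works in principle; in practice, near chemical
  equilibrium the opposing binding fluxes (each ~1e6 µM/h, net ~1e-7)
  leave floating-point cancellation noise in the derivative that stalls
  scipy's BDF error control at these tolerances, while LSODA's step/order
  control rides through it. Halving both tolerances moves the wild-type
  peak by < 1e-6 relative (tested at the 1e-3 level).
- Reporting grid: 0.05 h steps over the first 24 h (the transient of
  interest), 1 h steps thereafter. Peaks are read off this grid.
- Negative concentrations within 100×atol of zero are clipped to zero in
  reported states (solver noise); anything larger raises an error naming
  the species, since that indicates a model defect, not roundoff.
- Zero is absorbing and exact: knockouts that structurally eliminate a
  species keep its trace at 0 up to solver noise (≲1e-29 µM in practice).

## Experiments

- Knockouts silence a gene's translation reactions (the kf30 channel; for
  PP2C and ABF also their kf28 feedback channel) rather than zeroing the
  shared rate constants, so other genes are untouched. Feedback ablation
  silences only the gene's kf26 transcription reaction.
- Dose–response runs the protocol per dose ({0, 1, 5, 10, 25, 50, 100,
  200} µM by default) with one shared equilibration (the pre-phase does
  not depend on dose).
- Local sensitivity: for each parameter p, the index is
  ∫₀²⁴ |∂ln y(t)/∂ln p| dt for the RD29A message y, estimated by central
  finite differences at p·(1±0.01) with two full protocol runs per
  parameter. The log-log form reproduces fully normalized
  (dedimensionalized) sensitivities without solving the forward
  sensitivity system, keeping every run an ordinary simulation. Grid
  points where y ≤ 1e-10 µM are excluded from the integral (logarithms of
  numerical zeros); halving the perturbation changes indices by < 5%
  (tested). The default scan covers the fourteen binding, catalytic and
  turnover constants of the signalling layer.
  A known regime limitation: with the curated affinities, ABF-P and
  DREB2A exceed the 2 nM DNA-binding K_D during the response, so both
  promoter arms run near saturation and the ranking is dominated by
  parameters controlling *when* the pulse is shut off (feedback-ABRE
  binding, phosphocycle rates, receptor turnover) rather than by the
  *RD29A*-promoter binding constants themselves.

## Calibration

Grid search over kf26 ∈ [1, 20], kf27 ∈ [1, 20], kf28 ∈ [50, 500] h⁻¹
(default steps 1, 1, 25; tests and examples use coarser, symmetric grids —
e.g. 5×5×5 — to keep run counts in the low hundreds). Each point runs the
full 100 µM protocol and is *feasible* when the response is transient:
peak between 1 and 12 h, decline to ≤ 0.8 of peak by 24 h, induction
> 10-fold over the pre-stimulus baseline. The peak-window and
decline-ratio thresholds are fresh choices — generous boxes around the
observed shape (peak near 5 h, clear decline by 24 h) rather than fitted
quantities. Feasibility never looks at data.

With data, the best point minimizes the RMSE between model and
replicate-mean curves after each is rescaled to unit maximum (luminescence
units are arbitrary). Because the RD29A message is terminal, its trace is
exactly proportional to kf27, so shape-only data cannot identify kf27 (and
kf26·kf28 forms a soft ridge: the feedback protein flux depends mainly on
the product). The fitter therefore groups grid points whose RMSE ties the
minimum within 1e-6 (solver noise is orders of magnitude below, one
identifiable grid step orders of magnitude above) and reports the central
tied value per parameter — the minimax representative of an interval the
data cannot resolve, rather than an arbitrary element of it.

## Synthetic luminescence data

The generator emulates reporter-plant luminescence kinetics: mean curve
baseline + A(dose)·g(t), with g a log-normal pulse with mode at 5 h
(width 0.6) and A a saturating Michaelis/Hill amplitude (half-max 75 µM,
Hill 1, so near-saturation by 200 µM); replicates (default 3) get
independent mean-preserving multiplicative log-normal noise (default CV
0.1). Luminescence is positive with signal-proportional scatter, which the
log-normal reproduces; the specific pulse family, width, half-max and CV
are fresh choices, as no numeric reporter data are published to fit.

The generator is deliberately *not* the ODE model, so comparing the model
to these data is not circular. A second constructor wraps the simulator's
own RD29A trace in the same noise model for parameter-recovery
experiments; recovery tests therefore probe the fitting machinery, not the
generator's realism. What passing tests do **not** show: real reporter data
add luciferase maturation/decay kinetics, multicellular averaging, diurnal
and handling effects, and plant-to-plant variability structure, none of
which are emulated.

## Interfaces

Trajectories, experiment tables and calibration grids serialize as CSV
with JSON sidecars; the parameter table as a flat text file; every CLI run
directory contains config.json, parameters.txt and run.log (full
provenance). The model exports as SBML Level 3 core (hour/micromolar unit
definitions, boundary conditions for clamped species, explicit mass-action
MathML) with a small annotation block that lets the package re-import its
own dialect; re-imported models simulate identically to 1e-9 relative.

## Known limitations

- Single cell, single representative per protein family: quantitative
  comparison to whole-plant data is out of scope by construction.
- The reaction inventory is a reconstruction: the allocation of the four
  promoter-binding rows to micro-states, the kr16/kcat16 values, and the
  per-species assignment of the generic degradation-rate names are
  choices that functional outputs cannot fully pin down.
- The promoter-saturation regime noted under *Experiments* limits the
  informativeness of the DNA-binding constants in the sensitivity scan.
- No stochastic (SSA) simulation and no time-varying ABA inputs; the ABA
  step is the only event.
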