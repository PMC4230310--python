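# Methods

This note records the modelling assumptions, default parameter choices,
numerical conventions and known limitations behind `popsim`. It states
no empirical result that the test suite does not itself compute.

## Units and conventions

Amounts in mg, volumes in L, times in h, concentrations in mg/L,
clearances and flows in L/h, binding constants and target pools in µM.
Molar conversion happens only at model boundaries through the
molecular weight: C[µM] = 1000·C[mg/L]/MW. All concentrations exposed
as observables are plasma-referenced; the blood/plasma ratio enters
only through fu_B = fu/BP in the well-stirred clearance term and the
in-liver elimination term. This keeps every flow term written against
one concentration scale at the cost of ignoring the blood-plasma
partitioning of the transport terms themselves — a deliberate
simplification, documented here rather than hidden.

## PK model inventory

State layout per compound, in order: absorption states (first-order
depot, or n transit segments), distribution states (central; or
central/portal/liver; or central + selected perfusion-limited organs),
TMDD target and complex (µM), optional bookkeeping states (cumulative
eliminated; unabsorbed for oral routes), then each metabolite's
disposition states. PD link-unit states follow all compounds; a
user-scripted block is always last and re-indexed into the full state
array.

- **Transit absorption** uses k_tr = (n+1)/MTT with MTT a compound
  field (default 3.5 h, human small-intestinal transit). The absorbed
  fraction of a transit model *emerges* from the k_a/k_tr competition;
  the `fa` field partitions the dose only for the first-order depot.
- **Minimal PBPK** is central + portal vein + liver, perfusion-limited,
  with the central volume V_c = V_ss·BW − K_p,liver·V_liver − V_pv
  (floored at 10% of V_ss·BW for very small V_ss). This compartment
  inventory is original to this package.
- **Full PBPK** uses a blood central compartment (5.6 L at 70 kg) and
  perfusion-limited organs dA_T/dt = Q_T·(C − A_T/(V_T·K_p,T)); liver
  receives oral absorption and hepatic elimination when selected.
- **Metabolites** are tracked in *parent-equivalent mg*: the formation
  flux equals fm × the predecessor's elimination flux, so total mass is
  conserved exactly and the mass-balance invariant closes to solver
  precision; the metabolite's own molecular weight enters only in its
  concentration observable. Chains run parent → M1 → M2 → M3, each
  link taking `fraction_formed` of its predecessor's elimination flux.
- **DDI** scales each enzyme's intrinsic clearance by
  1/(1 + Σ_i Cu_i/K_i). The inhibitor site concentration is the unbound
  liver-compartment concentration when the inhibitor has a liver
  compartment, otherwise unbound central — the simplest defensible
  site model.
- **TMDD** is the full model (kon/koff/kint/ksyn/kdeg) with target and
  complex in µM in the central compartment; drug mass bound into the
  complex is debited from central, and internalisation feeds the
  eliminated bookkeeping state.

Bookkeeping (eliminated/unabsorbed) states are appended only when
`ModelSelection.track_balance` is set: they are free of dynamics of
their own and exist to make the mass-balance property testable without
changing the advertised state count of the plain selections.

## Virtual population

Body weight is lognormal by sex (defaults: male median 78 kg, female
65 kg, CV 20% — ordinary adult anthropometry). Organ volumes scale as
(BW/70)^1 and flows as (BW/70)^0.75 before residual lognormal
variability, so weight mediates the volume-flow correlation; no other
correlation structure is imposed. Lognormal parameters are
median-parameterised: a stated mean m with coefficient of variation cv
samples as m·exp(N(0, ln(1+cv²))), so the stated value is the
geometric mean/median. The representative subject takes every
parameter at its central value (lognormal median, normal mean) and is
deterministic by construction. Default organ volumes/flows and enzyme
abundances (e.g. CYP3A4 137 pmol/mg, CV 41%; MPPGL 40 mg/g) are
ordinary adult reference values.

Per-subject random substreams are derived from (seed, trial, subject)
counters, so subject k is invariant to cohort size — the property the
regression harness depends on.

## Solvers

`rk5` maps to the Dormand–Prince 5(4) adaptive pair; `lsoda` and
`auto` map to the Livermore automatic stiff/non-stiff solver. Both are
scipy's implementations; this package adds dosing-schedule segmentation
(integrator restart at every bolus and infusion boundary, constant
infusion rate terms inside their window), a cross-segment internal
step budget, and dense-output interpolation to the observation grid. A
dose coinciding with an observation time is applied *before* the
observation. TMDD selections and long transit chains combined with
full PBPK are stiffness-prone; under `rk5` they warn and run `auto`
instead. scipy does not expose lsoda's internal switch counter, so the
solver log records methods and step counts per segment but no switch
tally.

## Pharmacodynamics

Transduction modes for chained basic units: *empirical* composes the
plain transforms; *operational* has the upstream unit emit receptor
occupancy C/(K_A+C) and the downstream unit apply
E = E_m(τ·occ)ⁿ/(1+(τ·occ)ⁿ), which is algebraically the
concentration-form operational model; *intrinsic efficacy* forms a
stimulus S = ε·R₀·occ with the receptor abundance R₀ taken from the
population spec and applies the hyperbolic E = E_m·S/(1+S). The
intrinsic-efficacy arithmetic beyond "explicit receptor abundance" is
an original, deliberately simple choice. Unit fan-out (one output
feeding several units) and PD→PK feedback are rejected as unsupported.

Long-timescale units take a time-summarised (hence constant) drive and
use the resulting closed forms (e.g. S(t) = exp(−h₀e^{β·drv}t));
validation requires their upstream unit to be a summary unit.

## Sensitivity analysis

SI and EI are *secant* differences against the workspace's baseline
value, not per-step differences — chosen for interpretability and
declared, since both readings of "ratio of change" are defensible. A
baseline endpoint of zero reports EI as missing rather than infinite.
For two-parameter scans the indices are taken along the first axis
that moved relative to baseline; endpoint values are exact on the full
Cartesian grid regardless. Scans run the representative subject only.

## Parameter estimation

WLS weightings: uniform, 1/|obs|, 1/obs². ML objectives are −2·log L
under additive, proportional or combined residual error with σ fixed
at the user-specified value (σ is not co-estimated). Parameters with
strictly positive bounds are log-transformed internally. A failed
simulation at a candidate θ returns a finite penalty (1e12).

Optimizer settings: Nelder–Mead is scipy's bounded simplex.
Hooke–Jeeves is the classic exploratory/pattern-move search with
initial step 10% of each (transformed) range, halving on failure, and
a stop at 1e-5 of the range — finer than the 10⁻⁴ that a first
implementation used, because coordinate search in the correlated
clearance-volume valley leaves ~0.15% parameter error at the coarser
stop. The genetic algorithm is real-coded: population 40, tournament
selection (k=3), BLX-0.5 blend crossover, Gaussian mutation (sd 10% of
range, rate 0.2), 2 elites, fully determined by its seed.

Population estimation is MAP-EM: the E-step finds each subject's
posterior mode of the lognormal random effects (penalised −2LL), the
M-step updates the population value by the geometric mean of the
modes and ω² by the moment estimator mean(η̂² + var̂) with var̂ the
Laplace (curvature) variance — the shrinkage correction that keeps ω
from collapsing under mode-based updates. An effective floor of
ω = 0.05 in the E-step keeps the algorithm mobile when the variability
estimate collapses (the reported ω is unfloored). Priors on population
parameters (MAP variant) are lognormal and enter the M-step as a
precision-weighted average in log space. The convergence monitor is
the summed penalised −2LL plus n·ln ω²; it is monotone to within the
E-step precision, so the plateau can jitter at the stopping tolerance —
more than `monitor_patience` consecutive increases flag
non-convergence but still return a result.

## Workspace files and the codec

The XML vocabulary is original (no public schema exists for the file
family emulated here). The root carries an integer schema version;
loading an older file fills every missing optional field from the
documented default table (`popsim.xmlio.FIELD_DEFAULTS`) and returns
one warning per fill; newer versions are refused. Numbers are
serialized with `repr`, which round-trips doubles exactly and is
locale-independent, as is the RFC-4180 CSV output.

The profile codec reinterprets float32 bit patterns as unsigned
integers and stores first value + consecutive differences (mod 2³²)
before zlib compression. Bit-pattern reinterpretation (rather than
truncation to integer values) was chosen because it is exactly
invertible; simulation doubles are down-converted to float32 only in
this storage layer. The results bundle embeds the verbatim workspace
bytes with a SHA-256 digest — an open tamper-evidence mechanism in
place of encryption.

## Synthetic data and what a green test establishes

The estimation benchmarks self-simulate their data: noise-free
single-subject oral profiles for optimizer recovery, and a population
of 100 subjects with 30% lognormal IIV on clearance plus 10%
proportional residual error (fixed seed) for EM recovery. These
emulate rich, balanced sampling with a correctly specified model; they
do not emulate sparse/unbalanced designs, censoring (BLQ),
model misspecification, or covariate effects — recovery there
establishes the estimator's correctness, not its field robustness.
Note one inherent property the degenerate EM test documents: with a
proportional error model, the ML optimum of noise-free data sits
slightly off the generating value because of the ln σ(pred) term; the
test therefore compares EM against the individual fit of the same
objective, not against the generating value.

## Numerical choices

- Default tolerances rtol 1e-6 / atol 1e-9; analytic-agreement tests
  run at rtol 1e-8 and stiff comparisons set atol below the smallest
  state magnitude of interest.
- Bolus events are applied exactly (state increment), not as narrow
  rate pulses.
- The comparison harness flags a cell iff it differs by more than the
  absolute floor *and* by more than the relative threshold of the
  benchmark value; near-zero benchmark cells are judged against the
  floor, so denominators never blow up.
- Wall time and memory are advisory metrics (hardware-dependent);
  state counts, step counts and stored bytes compare exactly.

## Known limitations

Permeability-limited organs, mechanistic gut dissolution/absorption,
multi-compartment liver/kidney/brain models, age-varying physiology
(paediatrics, pregnancy), genotype assignment, PD interaction units,
response splitting, PD→PK feedback, BLQ handling and FOCE/SAEM
estimation are out of scope. The estimator assumes the residual σ is
known; the EM flavour is mode-based (MAP-EM), which is known to
underestimate ω when per-subject information is poor — the Laplace
correction mitigates but does not remove this.
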