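# Methods

## Scope and formalism

`musclesim` simulates the molecular response of human skeletal muscle to
aerobic exercise on three linked levels — energy metabolism, Ca²⁺/AMPK
signal transduction, and early/delayed gene expression — under an
organism-level capillary-blood supply. The model is *modular*: each
functional unit (blood, per-fiber transport, cytosol, mitochondria,
intra-fiber transport, signaling, gene expression) is a self-contained set
of variables, reactions, algebraic assignments, rate rules and discrete
events, exposing a typed interface of ports:

- `input` — read here, computed in another module;
- `output` — computed here, readable elsewhere (directed connections run
  output → input);
- `contact` — a shared state that several modules modify simultaneously;
  its derivative is the sum of all attached contributions.

Named **buses** fan a port out to many consumers without changing
semantics: all ports attached to clones of one bus resolve to one flat
variable. `flatten` performs union-find over the connection/bus graph,
names each equivalence class by its common local name (module-prefixed
only on collision), carries reactions/rules/events over with renamed
symbols, and records a total provenance map. Merges with conflicting
units, initial values or compartments are errors rather than silent
choices. Events from different modules that fire at the same instant
execute in module-name order — an arbitrary but deterministic tie-break.
Only flattening is implemented as an execution strategy; module-by-module
co-simulation is out of scope.

The flat model compiles to a single generated Python right-hand side
(parameters inlined as constants, assignments topologically sorted,
reaction contributions divided by their compartment volumes), integrated
with SciPy's stiff LSODA solver. The default muscle model flattens to 105
ODEs and 64 reactions from 13 modules. This is a deliberately *reduced*
kinetic core: the full legacy muscle-metabolism kinetics (hundreds of
parameters) are not ported; the configuration schema is expressive enough
to host them later.

## Exercise activation

Every exercise-sensitive process carries the activation multiplier
`f = 1 + α·W·(1 − e^{(t_start−t)/τ})` with a process-specific coefficient α
(1/W) and time constant τ (min). Internally each activation is a state
`da/dt = ((1 + α·W(t)) − a)/τ`, which equals the closed form exactly for a
constant-W step from rest and extends it symmetrically to interval
protocols: at every power change the state relaxes toward the new
asymptote with the same τ. Blood flow and muscle volume use
`Q₀ = 0.9 L/min`, `V_mus0 = 5 kg w.w.` and `τ_Q = τ_V = 0.4 min`; the
blood + interstitial compartment is lumped (assumed equilibrated) with
`V_bl = 0.2·V_mus`, and arterial concentrations are constant boundary
conditions (the cardiorespiratory system is not modeled). Fiber volumes
are fixed at `V_I = V_II = 2 kg w.w.` with cytosolic fractions 0.88
(type I) and 0.92 (type II); only the blood volume tracks `V_mus(t)`.

ATPase activation is faster (τ = 0.15 min) than the oxidative-supply
activation (τ = 0.6 min). This ordering is what lets phosphocreatine
recover partially during the rest phases of interval work — demand
collapses quickly at each bout edge while supply, driven by the still
elevated free-ADP signal, lags — producing one PCr minimum per bout.

## Recruitment and fatigue

Total power W splits into fiber-type contributions: all of W to type I up
to the onset threshold `θ·W_max` (θ = 0.24, W_max = 250 W); above it both
grow linearly so that type I and type II reach their caps (125 W each)
simultaneously at W_max, where full recruitment terminates the test
(exhaustion). With the default 10 W/min ramp the type-II onset falls at
minute 6 — the slope is a derived default chosen so the printed pair (24%
of 250 W; minute 6) holds, not an independent constant. Short
supra-maximal bouts (e.g. 500 W intervals) are allowed by capping type I
at 125 W and assigning the remainder to type II. Fatigue is prescriptive,
not mechanistic: type-II power declines linearly with accumulated
time-under-load at a configured rate, so successive bouts start lower;
type I is unaffected.

Per-fiber *relative intensity* (fiber power over its 125 W cap) drives the
calcium input; per-fiber power drives the metabolic activations.

## Metabolism

Per fiber type, the cytosol carries ATP, PCr, Cr, Pi, H⁺, glycogen,
glucose, a lumped hexose-phosphate pool, pyruvate, lactate, alanine,
glycerol, FFA, fatty acyl-CoA, CoA, O₂ and CO₂; the mitochondrion carries
pyruvate, O₂, CO₂, Pi, NADH (against a fixed NAD(H) pool), acyl-CoA, CoA
and acetyl-CoA. Rate laws are Michaelis–Menten products times the
activation factor: glycogen phosphorylase and lumped glycolysis (with
free-ADP and Pi feedback), hexokinase (product-inhibited), glycogen
synthase (decreasing in glycogen, activation identical in both fiber
types, driven by total power), near-equilibrium LDH and alanine
transaminase, lipolysis with glycerol release, fatty-acid activation,
fast reversible creatine kinase, ATPase, PDH (fiber-specific activation;
the type II coefficient is smaller so pyruvate oxidation saturates at
moderate intensity), a lumped PDH→TCA NADH yield (5 NADH per pyruvate in
two steps), β-oxidation (14 NADH per acyl-CoA, lumped), and oxidative
phosphorylation consuming mitochondrial NADH and O₂ while regenerating
cytosolic ATP from ADP and Pi at P/O = 2.5 (the adenine translocase and
phosphate carrier are folded into this step).

Two bookkeeping choices matter:

- **Free nucleotides.** The adenine pool is `A_tot = ATP + ADP_free`
  (6.22 mmol/kg); ADP is the algebraic remainder, kept near the creatine
  kinase equilibrium by an explicit fast CK reaction whose apparent
  constant scales with H⁺ (`K_app = K_CK·[H⁺]`, K_CK = 1.66·10⁹ L/mol).
  The signaling level independently evaluates the CK/AK equilibrium
  formulas, so the AMP signal is exactly the near-equilibrium free AMP.
  Acidosis lowers free ADP at a given PCr — the model reproduces the
  damping of the AMP signal by low pH.
- **Protons.** H⁺ states (mol/L) are buffered: an acid flux J
  (mmol/min/kg) moves pH at J/β with β = 45 mmol/kg/pH in muscle water,
  so `dH/dt = ln10·H·J/(β·V)`. Lactate accumulation contributes 1 H⁺ per
  lactate, ATP hydrolysis ν = 0.4, net CK flux toward Cr consumes 0.9,
  oxidative phosphorylation consumes 1 per NADH; monocarboxylate-like
  facilitated H⁺ transport links cytosol, blood and mitochondria, and
  perfusion washes blood acid toward arterial pH 7.4 with an effective
  carrying capacity of 30 mmol/L/pH (lumped bicarbonate).

Exact invariants by construction: PCr + Cr per fiber; total CoA units
(CoA + acyl-CoA + acetyl-CoA across compartments); with perfusion and all
reactions off, the volume-weighted total of every transported species.
These are asserted in the test suite.

The resting steady state is found by integrating the rest system for
1500–2000 model minutes and polishing with damped (Levenberg–Marquardt)
Newton iteration on the scaled right-hand side — damping is required
because the conserved moieties make the steady state non-isolated and the
Jacobian singular along those directions. The solved rest state has
ATP ≈ 6.19, PCr ≈ 28.8, glycogen ≈ 124 mmol/kg and pH ≈ 7.3–7.4; resting
pH sits at the high end of the physiological range because the model has
no resting acid load beyond its small basal lactate turnover.

## Signaling

Protein pools are normalized to 1 (states are phospho-fractions), equal in
both fiber types. Mean myoplasmic Ca²⁺ relaxes (τ = 0.3 min) toward
`Ca_rest + slope·intensity` (0.1 + 1.2·intensity µM); calmodulin activation
is a Hill function with coefficient 4 (cooperative Ca²⁺ binding), which
keeps the resting drive low while saturating during exercise. CaMKII,
CRTC (via calcineurin) and CREB1 follow two-term
phosphorylation/dephosphorylation kinetics; CREB1 is driven by both
CaMKII and total AMPK activity.

Each AMPK heterotrimer h obeys

    dp_h/dt = (k_LKB1·LKB1 + k_CaMKK2·CaMKK2_act)·(1 − p_h)
              − k_pp,h · (ATP/ATP_ref) / (1 + AMP_free/K_AMP,h) · p_h,

i.e. Thr172 phosphorylation by LKB1 (constant activity by default, with a
config hook) and Ca²⁺-activated CaMKK2, against a phosphatase that AMP
binding suppresses and ATP promotes. Heterotrimers differ only in
parameters: the γ3 complex has the small `K_AMP` (10⁻⁴ mmol/kg — strong
nucleotide protection), the large CaMKK2 coupling and the low baseline
activity; the two γ1 complexes are nearly insensitive (`K_AMP` = 0.02).
Pool shares are 0.65/0.20/0.15 for α2β2γ1/α2β2γ3/α1β2γ1 — the γ3 trimer is
a minority of the α2 pool, which is what makes "≈30% of γ3 phosphorylated"
compatible with "≈10% of all α2-containing AMPK phosphorylated"
simultaneously. Total AMPK activity is the share-weighted sum over
heterotrimers of baseline + phospho-fraction with a direct AMP allosteric
factor (Hill coefficient 1).

All signaling rate constants are calibration parameters. They were tuned
once against the moderate-intensity working point — 30 min at 70% VO₂max,
mixed-muscle γ3 phosphorylation ≈ 30% and α2-pool ≈ 10%, with the γ1
complexes nearly unchanged and all phospho-fractions returning to within
1% of baseline inside an hour of recovery — and then frozen in
`data/defaults.yaml`. `scripts/calibrate.py` reproduces the calibration
report.

## Gene expression

Each gene has a constitutive transcription rate k₀ plus an activated Hill
term, and first-order mRNA decay; mRNA is normalized so the resting level
is k₀/k_deg = 1 and fold change equals the state itself. Early genes
(*NR4A3*, *NR4A2*) and factor X respond to
`max(CREB1p·CRTC − ref, 0)` — multiplicative coactivator logic; `ref` is
the resting product (written by the calibration script, stored slightly
above it), so the resting rate is exactly k₀ and the resting fold change
exactly 1. X protein is translated from X mRNA and degrades slowly
(half-life ≈ 2.3 h); *PPARGC1A* responds to `max(X_protein − 1, 0)`. The
two-stage relay is the entire source of the delay: early mRNAs peak
minutes after exercise ends (degradation half-lives 30–50 min), X protein
peaks ≈ 1.2 h later, and *PPARGC1A* mRNA (half-life ≈ 2.3 h) peaks ≈ 3.5 h
after a 60-min moderate bout. Two model variants exist for hypothesis
testing: `x_factor_enabled: false` removes the relay (the delayed response
collapses to the constitutive level), and `direct_creb_regulation: true`
wires *PPARGC1A* directly to CREB1·CRTC (it then peaks early). The
biological identity of X (AP-1/EGR1-class candidates) is documentation,
not code. Measured fold-change magnitudes are not calibration targets —
only timing and ordering are asserted; magnitudes follow from the chosen
vmax/k₀ ratios and are reported, not fitted.

## Numerics

- Solver: LSODA (stiff BDF switching), rtol 10⁻⁸, atol 10⁻¹⁰; the
  integration restarts at every protocol discontinuity so no bout edge is
  stepped over; a terminal event stops exercise at full recruitment when
  requested. Halving the tolerances changes ramp trajectories by < 0.1%
  (asserted).
- The compiled right-hand side evaluates in ≈ 60 µs; a 30-min exercise
  plus recovery simulates in ≈ 2 s and the 7.3-h gene-expression horizon
  in ≈ 3 s on one CPU.
- Rate laws vanish with their consumed substrates (Michaelis factors), so
  states stay nonnegative to solver tolerance without clipping.
- Determinism: repeated runs produce byte-identical result tables; there
  is no randomness anywhere in the model.
- SBML export writes Level 3 Version 2 with a content-MathML subset
  (arithmetic, exp/ln/log₁₀/sqrt/min/max, comparisons in triggers),
  implemented in-package on lxml; the reader inverts it exactly, and
  export→import round trips reproduce trajectories to solver tolerance.
  External protocol drivers are not representable in SBML and must be
  mapped to constants at export. A structural consistency checker
  validates namespaces and symbol references. COMBINE-archive export
  packs the SBML with a manifest and a plain-text simulation stub.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full 105-state model:
rest equilibration (≈ 1500–2000 model minutes + Newton polish), a 25-min
ramp, 30-min continuous bouts at 50% and 70% VO₂max with 30 min recovery,
a 60-min bout with 6.2 h recovery, and 4–6-bout interval fixtures. These
horizons were chosen as the shortest that contain every asserted feature
(steady signaling plateaus, full post-exercise relaxation, the delayed
expression peak).

## What the model does and does not represent

The simulated "subject" is an untrained male on a cycle ergometer:
5 kg w.w. of active two-leg muscle, equal type I/II volumes, exhaustion at
250 W. Hormonal regulation, central-nervous drive, feeding, temperature,
mechanistic fatigue, motor-unit-level recruitment, subcellular kinase
localization, O₂–hemoglobin binding and promoter-level transcription
detail are all outside the model. Glycogen-synthase activity depends on
glycogen content only, so post-exercise glycogen resynthesis sits between
fasted and fed literature values and is not tuned to either. The reduced
kinetic core reproduces directions, orderings and calibrated working
points — not species-by-species concentration curves of the full legacy
kinetics; passing tests therefore certify the integrated architecture and
its calibrated signaling/gene behavior, not quantitative agreement of
every metabolite trajectory with experiment.
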