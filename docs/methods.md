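# Methods

## The model

`sinusim` simulates hepatic glucose, lipid and energy metabolism with the
liver **sinusoid** — not the single hepatocyte — as the repeating unit of
the organ.  Blood plug-flows through `N` (default 8) well-mixed
compartments from the periportal inlet to the pericentral outlet; each
compartment holds a hepatocyte pool with 17 intracellular state
variables (glucose, G6P, glycogen, pooled triose phosphates G3P/GADP,
pooled pyruvate/lactate, acetyl-CoA, free fatty acids, triglyceride,
glycerol, and the adenine/uridine/guanine nucleotide species plus
inorganic phosphate) exchanging with its local blood (glucose, lactate,
FFA, TG, glycerol, insulin, glucagon, oxygen).  Draining blood returns
to a systemic pool that carries simple representations of the pancreas
(sigmoidal glucose-dependent insulin/glucagon secretion), adipose tissue
(de novo lipogenesis and insulin-suppressed lipolysis of the plasma TG
pool), the gut (re-esterification of plasma FFA to TG) and bulk
glucose/FFA consumption by muscle and other tissues.  Feeding enters the
pool as glucose and palmitate-equivalent FFA with a `sin^6(pi t / 4 h)`
waveform delivering 78.1 g carbohydrate and 22.2 g lipid per 4-hour
cycle on the moderate diet.

### Rate laws

Every process rate has the form

    R = v_b * m_i * prod_k f_k,

with `v_b` the zone-independent base rate constant (uM/s), `m_i` the
zonation multiplier of compartment `i`, and each factor `f_k` a Hill
term: substrate activation `c^n/(K^n+c^n)`, allosteric inhibition
`K^n/(K^n+c^n)`, an affine hormone response `b + a*h(insulin_eff)` (or
glucagon), or the oxygen dependence of the oxidative processes.
Reversible membrane transports, adenylate kinase and the
inorganic-phosphate regulator are differences of two saturable
unidirectional parts.  Stoichiometries — including the fractional ATP
coefficients (3.25, 2.25, 2.5) that lump NADH-derived phosphorylations
and the 8:1 acetyl-CoA:palmitate ratio of lipogenesis/beta-oxidation —
are hard-coded and audited: the adenine (ATP+ADP+AMP), uridine (UTP+UDP)
and guanine (GTP+GDP) pools are exactly conserved by the reaction
network for any state.

### Zonation

Enzyme expression varies continuously along the porto-central axis:
`m_i = 1 + k_n * x_i`, with `x_i` falling linearly from +1 (periportal)
to -1 (pericentral), so the endpoint activity ratio is
`(1+k_n)/(1-k_n)` and `v_b` is the sinusoid mean.  The zonation
constants are fixed by measured periportal:pericentral activity ratios
(glucokinase 1:2.5, G6Pase 1.9:1, glycogen synthase 3:1, stage-2
glycolysis 1:2.1, PEPCK 2.4:1, FBPase 1.75:1, beta-oxidation 1.6:1,
oxidative phosphorylation 1.5:1, lipogenesis 1:1.6, FFA uptake 1.5:1;
all other processes 1:1).  Hormone *reception* is zonated the same way
(insulin 1:1.35 pericentral-dominant, glucagon 1.35:1), implemented as a
multiplier on the hormone concentration sensed by the hepatic rate laws.

### Hormones, insulin resistance, SREBP-1c

Insulin resistance scales the insulin concentration detected by every
insulin-sensitive process (hepatic and peripheral) by a constant
`K_IR <= 1`: 1 is metabolically healthy, 0.05 developing resistance,
0.015 severe resistance.  SREBP-1c over-expression — observed in
insulin-resistant NAFLD livers despite the loss of insulin signalling —
is modelled by clamping the insulin seen by de novo lipogenesis and
triglyceride synthesis to a high 1 nM, regardless of `K_IR`.

### Oxygen

A constant systemic input and a zero-order per-compartment consumption
fix the oxygen tension profile at the measured healthy gradient, 65 mmHg
at the inlet falling linearly to 35 mmHg at the outlet.  Oxidative
phosphorylation and beta-oxidation carry Hill-type oxygen dependences,
which is one of the three mechanisms that concentrate fat oxidation in
the periportal compartments (the others being the explicit zonation
constants and the acetyl-CoA inhibition of beta-oxidation, which bites
harder pericentrally where oxidative phosphorylation is slower).

## Numerics

The reference integrator is classic fixed-step RK4 at `dt = 0.05 s`
with 8 compartments.  A step that would drive any concentration
negative is rejected and re-taken with locally halved sub-steps (down to
dt/128) rather than clipped, so the conservation audits stay exact; an
unrecoverable negative aborts with a diagnostic naming the species and
compartment.  The scheme is stable for `dt <= 0.4 s`; long feeding-cycle
equilibration phases therefore run at `dt = 0.2 s` with the final,
reported cycle always re-integrated at the reference step (the two
differ by far less than 0.1% in cycle averages — see the refinement
study).  Feeding simulations iterate 4-h cycles until the maximum
relative change of any state between consecutive cycle ends is below
`1e-4` (`|dx|/(|x|+1e-9)`); because hepatic triglyceride and glycogen
relax over days of simulated time, the equilibration loop optionally
applies a secant extrapolation of the dominant slow mode every third
cycle (convergence is always judged on plain, unextrapolated cycles).
Near-equilibrium states for the standard scenarios produced by the
calibration module ship with the package so that standard runs converge
in a handful of cycles; they are starting points only — every reported
figure is recomputed by integration.

Verification oracles: with first-order hormone degradation and
zero-order oxygen consumption the steady sinusoidal profiles have exact
closed forms (geometric decay `c_in * f^i`; linear decline
`c_in - i * delta`); the simulated profiles match these to round-off,
and the conservation audit checks the nucleotide-pool and advective
mass-balance identities on 1000 random states.

## Calibration

Only part of the parameter set is pinned by published numbers: the
stoichiometry, the zonation and hormone-reception ratios, K_IR levels,
the SREBP-1c clamp, the oxygen gradient, the feeding composition, the
glycerophosphate-acyltransferase K_M for the glycerol backbone (460 uM)
and the plasma baselines of the sensitivity protocol (glucose 5.03 mM,
TG 1.05 mM, FFA 432 uM).  The remaining Hill constants and every base
rate constant are the package's own calibrated defaults, produced in
three documented stages:

1. **Flux anchoring.**  A reference ("anchor") state — plasma at the
   baselines above, hepatocyte concentrations at standard textbook
   levels (ATP 2.5 mM, glycogen 250 mM glucose-equivalent, TG at 2.3%
   of cell mass, FFA 21.5 uM, ...) — is combined with a set of design
   fluxes chosen at physiological hepatic turnover (glucose
   phosphorylation 6.3 uM/s, pyruvate oxidation 12 uM/s, beta-oxidation
   0.9 uM/s, de novo lipogenesis 0.42 uM/s, triglyceride synthesis
   0.065 uM/s, ...).  Dependent fluxes are derived so every hepatocyte
   species balances exactly at the anchor, and each `v_b` is then solved
   from its rate law evaluated there.  Near-equilibrium enzymes
   (adenylate kinase, the nucleoside diphosphate kinases) instead get
   fixed high capacities and follow demand.
2. **Baseline solve.**  The constant-input scenario's glucose/FFA input
   rates and the gut TG-synthesis constant are solved (deterministic
   root find on the full steady state, with the conserved nucleotide
   pools pinned to their reference totals) so that systemic glucose, TG
   and FFA sit exactly at 5.03 mM / 1.05 mM / 432 uM; pancreatic maxima
   are solved in closed form so insulin and glucagon rest at 0.06 and
   0.05 nM there.
3. **Cyclic refinement.**  Hormone-response amplitudes and a small set
   of Hill constants were adjusted against the feeding-cycle and disease
   observables (healthy sinusoid-average TG near 2.3% of cell mass with
   a pericentral triglyceride-synthesis bias, steatosis under severe
   insulin resistance, the NAFLD shifts in ATP and beta-oxidation).
   Because these printed outcome values were used to select the shipped
   parameter set, the scenario outputs function as calibration targets,
   not independent predictions; the split is noted here deliberately.

### Reproduction status

With the shipped set, the structural checks (conservation, gradient
oracles, step/grid robustness, zonation ratios), the solved plasma
baseline, the outlet oxygen tension, the healthy liver-fat fraction and
the NAFLD beta-oxidation rise all land on the published values
(`scripts/acceptance.py` recomputes them; `tests/test_acceptance.py`
asserts them at 15% relative tolerance).  The *magnitudes* of
insulin-resistant steatosis, the pericentral:periportal synthesis
ratios, the NAFLD ATP fall and the two tabulated sensitivity rows are
reproduced in sign and ordering but not in size, and their acceptance
tests fail at that tolerance by design.  The gap is structural rather
than a tuning residue: with this package's re-derived kinetic constants,
the product-inhibition of lipogenesis, the substrate response of
beta-oxidation and the export feedback recover most of a perturbation's
lipid flux, which compresses the disease:healthy contrast.  Matching the
published magnitudes would require the original study's full (not
publicly printed) constant set, which fixes those feedback stiffnesses.

A structural lesson from calibration is recorded as a design rule: every
metabolite pool keeps at least one disposal path that remains
near-linear over its pathological range (glucose-6-phosphatase for G6P,
the lactate carrier for pyruvate/lactate, VLDL export for triglyceride),
otherwise saturation of all sinks lets the pool run away under disease
stress.

## What the generator does and does not emulate

The feeding waveform is smooth and strictly periodic; meals are
identical, sleep/fasting cycles, exercise, and mixed meal composition
beyond the carbohydrate/lipid split are not represented.  There is no
adipose storage compartment, so high-fat diets raise plasma lipids more
than in vivo (diet multipliers are therefore matched to observed plasma
concentrations, not intake); cholesterol, amino-acid and fructose
metabolism, NADH/FADH2 as explicit species, ETC decline/ROS and
inflammation are out of scope.  Passing the scenario checks shows the
calibrated network reproduces the *relative* disease shifts under these
idealised conditions, not that the parameters are uniquely identified —
parameter non-uniqueness is acknowledged; the shipped set is one
documented reference individual.

## Sensitivity protocols

* **Rate sweep** (inter-individual susceptibility): from the
  constant-input baseline steady state, each hepatic `v_b` is scaled by
  ±10% and the model integrated 36 h with inputs held constant; the
  report gives the change in cellular/plasma FFA and TG at the horizon
  (point-in-time, not time-averaged).  A control run guards that the
  provided baseline is genuinely stationary.
* **Zonation sweep** (steatosis location): under the NAFLD scenario each
  lipid-relevant `k_n` is shifted by ±0.2 (a 20% periportal increase and
  20% pericentral decrease, or vice versa), the feeding cycle is
  re-equilibrated, and the compartment-1 : compartment-8 cycle-average
  TG ratio is reported together with `(dTG_pc - dTG_pp)/TG_av` between
  the two shifts.  Shifts that would leave `|k_n| >= 1` are skipped.

## Parameters that matter most

| parameter | units | default | role |
|---|---|---|---|
| `n_compartments` | – | 8 | porto-central resolution |
| `dt` | s | 0.05 | reference RK4 step (stable to 0.4) |
| `K_IR` | – | 1 / 0.05 / 0.015 | insulin-resistance severity |
| SREBP-1c clamp | nM | 1.0 | lipogenic insulin clamp in NAFLD |
| diet multipliers | – | 1.05 / 1.125 / 1.25 | raised / high / very-high intake |
| blood flow | L/s | 0.024 | sets transit (~8 s) and plasma turnover |
| volumes (hep / sinusoid / body) | L | 1.5 / 0.2 / 10 | rate-to-concentration scaling |
| O2 inlet/outlet | mmHg | 65 / 35 | fixed zonation signal |
| hormone survival per compartment | – | 0.928 / 0.968 | insulin/glucagon sinusoidal extraction |

## Resolved design questions

* The feeding waveform argument is taken as `sin^6(pi t / 4 h)` — the
  4-hour period is the binding constraint, giving a cycle mean of 5/16.
* Sinusoid averages weight compartments equally (they share one volume);
  a volume-weighted variant would coincide for the default geometry.
* Where the process table's prose conversion strings and the
  rate-equation table disagree (the inorganic-phosphate coefficient of
  beta-oxidation), the rate-equation table is authoritative; the ATP
  yield of acetyl-CoA oxidation is 12 per turnover.
* Zonal ratios are computed in both conventions — pericentral-half mean
  over periportal-half mean, and compartment-N over compartment-1 — and
  both are reported, since published comparisons alternate between them.
* The pancreatic sub-model is a generic pair of bounded glucose
  sigmoids; its maxima are solved in closed form so the hormone
  baselines sit at 0.06 / 0.05 nM at the reference glucose level.

## Known limitations

Single representative sinusoid (no lobule geometry, no heterogeneity
between sinusoids); plasma TG pool does double duty as the adipose
substrate for lipolysis; hormone action is instantaneous (no receptor
kinetics); the glycogen capacity bound is phenomenological.  Observables
that depend on absolute plasma hormone excursions should be read
qualitatively.
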