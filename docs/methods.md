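# Methods

`cardiotrans` implements a computational pipeline that translates inotropic
(contraction-strength) and lusitropic (relaxation-quality) drug effects
measured in rat left-ventricular cardiomyocytes into predictions for human
cardiomyocytes.  This note documents the models, the numerical choices and
the deliberately scaled-down study presets, and states what the synthetic
closed-loop evaluations do and do not demonstrate.

## Cell models

Two paced single-cell models (rat and human) couple a minimal
action-potential layer to a compartmental Ca²⁺-handling subsystem and a
Land-type contraction component.  They are *reduced-but-mechanistic
reference implementations*: every drug-targetable protein is represented by
a dedicated maximal conductance or rate, the coupling equations (calmodulin
buffering of dCa/dt, troponin-C binding feedback) follow the standard
forms, but the gating formulations are deliberately compact
(fixed-time-constant Hodgkin–Huxley gates with sigmoid steady states)
rather than ports of the published Gattoni or ToR-ORd-dynCl CellML models.
A full CellML port can be substituted behind the same interface
(`CellModelParams` / `run_paced`).

Drug-scalable currents and fluxes:

| protein | parameter | rat | human |
|---|---|---|---|
| Nav1.5 (late) | `g_NaL` | ✓ | ✓ |
| Nav1.5 (peak) | `g_Na` | – | ✓ |
| Cav1.2 (L-type) | `g_CaL` | ✓ | ✓ |
| Kv4.3 (Ito) | `g_to` | ✓ | ✓ |
| hERG (IKr) | `g_Kr` | – | ✓ |
| KvLQT1/minK (IKs) | `g_Ks` | – | ✓ |
| Kir2.1 (IK1) | `g_K1` | ✓ | ✓ |
| RyR2 (SR release) | `g_RyR` | ✓ | ✓ |
| SERCA2 (SR uptake) | `V_SERCA` | ✓ | ✓ |
| NCX1 | `g_NCX` | ✓ | ✓ |
| NKA | `g_NaK` | ✓ | ✓ |

Scaling a protein that a species does not possess raises an error; batch
tools drop such targets before simulating (the rat model cannot receive
hERG, IKs or peak-Na block).

Structural choices that matter:

* **Graded SR release (local-control approximation).**  RyR2 release flux is
  `g_RyR · w · d · (Ca_SR − Ca_trigger)`: gated by the L-type activation
  gate `d` (the trigger) and a Ca²⁺-dependent recovery gate `w`, not by a
  regenerative Ca²⁺-activated open probability.  This makes release graded
  with trigger influx and unconditionally stable — a two-compartment model
  with free-running Ca-induced-Ca-release either avalanches or needs much
  finer spatial structure.
* **Clamped intracellular Na⁺ and K⁺.**  Na⁺ accumulation equilibrates over
  minutes, far beyond the 100-beat pacing protocol; clamping removes the
  slowest timescale so the limit-cycle protocol genuinely converges
  (final-beat Ca²⁺/SL peaks change by < 1 % between 100 and 300 beats in
  both species).  The price: NKA block acts only through membrane
  potential, so its potency is essentially non-identifiable from SL/Ca
  biomarkers — consistent with the published identifiability outcome this
  package mirrors.
* **Rat upstroke.**  The rat model carries a non-druggable fast Na⁺
  conductance (`g_NaF`); the underlying electrophysiology models include a
  fast Na⁺ current even though it is not among the rat drug targets.  The
  druggable late component `g_NaL` is small, matching the published
  sensitivity analyses in which the rat late Na⁺ current is insensitive.
* **SR leak in both species.**  A gradient-driven leak balances diastolic
  SERCA uptake; without it the SR load equilibrates over many hundreds of
  beats.
* **Contraction and sarcomere length.**  Troponin-C occupancy follows the
  published binding ODE (`kTRPN`, `nTRPN`, `Ca50ref` with length-dependent
  Ca₅₀ via `beta1`); a first-order crossbridge state with permissivity
  `CaTRPN^n_xb` produces normalised active tension with length dependence
  `1 + beta0(λ−1)`; the unloaded sarcomere shortens against a linear
  restoring stiffness with a viscous element,
  `η dλ/dt = k_p(1−λ) − c_a·Ta`, and `SL = λ·SL0`.  The viscous constant
  shapes the contraction/relaxation rate biomarkers.

### Parameterisation

The published recalibrated parameter values are not printed in the source
literature, so the reference parameter sets here are repo-chosen and
calibrated so that, at 1 Hz with the default protocol:

* all seven sarcomere-length biomarkers of each species lie inside the
  printed experimental min–max ranges (`calibration.RAT_SL_RANGES`,
  `HUMAN_SL_RANGES`),
* APD50/APD90 lie inside the printed experimental ranges,
* the pacing-frequency relationships of Short and CaAmp over 0.5→2 Hz are
  negative in rat and positive in human,
* the soft Ca²⁺ biomarker targets (mean ± SD) are met where possible
  (rat 3/4; human 2/4 — the published recalibration met rat 3/4 and
  human 0/4, so this is comparable fidelity).

The fitted Ca²⁺ sensitivities come out at Ca₅₀ ≈ 1.9 µM (rat) and
≈ 0.6 µM (human), reproducing the strong rat/human sensitivity difference
reported for the recalibrated models (1.6 vs 0.7 µM).

## Numerics

Fixed-step integration: Rush–Larsen exponential updates for all gating
variables, forward Euler for the remaining states; default solver step
0.01 ms, output decimated to 1 ms; monophasic stimulus of 50 µA/cm² for
1 ms (the stimulus time integral of 50 µA·ms/cm² is preserved when the
duration changes).  Voltage-dependent gate steady states and the NCX/NaK
voltage factors are tabulated on a 0.05 mV grid and linearly interpolated
inside the numba kernel; the tables are accurate to ~10⁻⁶ and remove
almost all per-step transcendentals.

Biomarkers are extracted from the last beat: the resting value is the
sample at the beat's stimulus instant, the peak is the first within-beat
extremum, return times are interpolated linearly between samples, rates
are central differences on the output grid.  Abnormality screening
(alternans ratio > 1.1 strictly; fluctuation rates beyond ±0.001 units/ms
in the pre-/post-peak windows of each of the last two beats separately)
excludes the stimulus and peak samples from the rate windows to avoid
stimulus-artefact false positives.

The per-beat stimulus-referenced return times SLTD70/SLTD90 are computed
as `SLTP + SLTR70/90`; the printed table caption describing them as
"50 % and 90 % return" conflicts with the symbols and the 70 %
interpretation is used.

## Penalties and recalibration

The transient penalty is
`Pen = c1[(minAmp/maxAmp − 1)² (SL) + (minAmp/maxAmp − 1)² (Ca)] +
c2[clip⁺(max pre-peak dSL/dt)² + clip⁻(min post-peak dSL/dt)² +
clip⁻(min pre-peak dCa/dt)² + clip⁺(max post-peak dCa/dt)²]`
with (c1, c2) = (10², 10⁶) for recalibration and (10⁴, 10⁸) for potency
inference, so touching a fluctuation threshold contributes ≥ 1 and ≥ 10²
respectively.  The published amplitude term appears once as max/max
(a typo) — the min/max − 1 form symmetric with the SL term is the default;
the max/min − 1 variant (whose threshold contribution is exactly c1/100)
is available via `PenaltyConfig(amplitude_form="max_over_min")`.

The recalibration cost weights seven squared relative SL errors against
medians and four squared relative range distances (mean ± SD) with a
joint 1/11 factor, plus the penalty.  Candidates with missing biomarkers
or unstable simulations receive a large finite sentinel (10⁶) so the
population optimiser continues.  Differential evolution uses strategy
best1bin, recombination 0.7, mutation (0.5, 1), Latin-hypercube
initialisation and relative tolerance 0.01 throughout.

## Translation pipeline

Step 1 medians per-cell drug effects (effects outside [−100, 500] % and
abnormal transients excluded).  Step 2 minimises the squared mismatch of
14 biomarker effects over all concentrations plus per-concentration
penalties over pIC50 vectors inside
[6 − log10(100·C_top), 6 − log10(C_low/100)] (the printed bound labels are
inverted; sorted).  The Hill coefficient is fixed at 1 in the pipeline.
Step 3 applies the inferred potencies to the human model (equal-potency
assumption).  For the identifiability analysis all eight shared-target
potencies are inferred jointly; abnormal or out-of-range virtual-drug
datasets are re-drawn with fresh sub-seeds rather than shrinking the
batch.

### Study presets and problem sizes

The batch analyses default to a *desk-scale* preset chosen to keep a
complete closed-loop study on a single CPU within minutes:

* solver step 0.05 ms (biomarkers agree with 0.01 ms to well under 1 %,
  asserted by a refinement test);
* baseline limit cycle of 100 beats per species, cached and shared;
* drugged runs restart from the cached baseline state and pace 40 further
  beats — identical in dataset generation and inside the inference
  objective, so the inverse problem is exactly self-consistent;
* differential evolution budgets: 3-target inference restarts = 1,
  maxiter = 12, popsize = 3; joint 8-target identifiability restarts = 2,
  maxiter = 12, popsize = 3 (the single-concentration 8-dimensional
  objective has secondary basins, so independent Latin-hypercube
  populations are required — the reason the full study design restarts ten
  times).  Restarts run without per-restart polishing; a single bounded
  Nelder–Mead refinement (600 evaluations) is applied to the best restart.
  Nelder–Mead, not a quasi-Newton method: the objective is kinked
  (linear-interpolation crossings and peak-index switches inside the
  biomarker extraction), which defeats finite-difference gradients in the
  shallow valleys, whereas the simplex search reliably descends them.
  The full-scale configuration (ten restarts, larger populations, 0.01 ms
  step) is available through `InferenceSpec` and an explicit
  `StimulusProtocol`.
* evaluation batches of 10 virtual drugs (the identifiability batch size
  of the study design; the synthetic evaluation is a scaled-down version
  of the 100-drug batch).

Because drugged runs pace a finite number of beats, the last two beats are
never exactly periodic and the inference objective at the ground truth is
not exactly zero — a small residual penalty (≲ 1 with the desk preset)
remains.  This floor is candidate-dependent and was the main accuracy
limit for the joint 8-target inference; 40 post-drug beats push it well
below the identifiability signal.

## What the synthetic studies show — and what they do not

The virtual-drug generator draws potencies uniformly on the pIC50 scale in
[5, 6] per target and simulates both species with the same models used for
inference.  The closed loop therefore demonstrates that the inverse
problem is well-posed and the optimiser recovers generating potencies
(MAE ~10⁻⁴ for RyR2/SERCA2/NCX1 with four concentrations; ≤ 0.05 in the
joint 8-target single-concentration setting), and that translation through
inferred potencies dominates naive rat-to-human extrapolation.  It does
*not* demonstrate accuracy against wet-lab data: there is no model
discrepancy, no measurement noise and no intercellular variability in the
loop (medians of a single virtual cell).  Real translations inherit all
three, as the published thapsigargin evaluation illustrates.

## Known limitations

* Reduced gating (constant time constants) distorts AP morphology details;
  rat CaTP sits slightly below the experimental mean − SD band (as did the
  published recalibrated model).
* No CaMKII or β-adrenergic signalling; mechano-electric feedback is
  limited to troponin-C buffering.
* State-dependent (Markov) drug binding is out of scope; block is a pure
  conductance scaling via the Hill equation.
* Clamped Na⁺ removes rate-dependent Na⁺ accumulation; the positive human
  staircase here arises from SR loading and RyR recovery kinetics alone.
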