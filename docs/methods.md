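# Methods

`mwaplan` implements a model-based planning pipeline for percutaneous
microwave ablation (MWA) of liver tumors, together with the synthetic-phantom
validation machinery used to exercise it end to end. This note documents the
model, its numerical treatment, the defaults and why they were chosen, and
what the synthetic experiments do and do not demonstrate.

## Biophysical model

### Bioheat equation

Tissue temperature T(x, t) (°C) obeys the Pennes bioheat equation

    ρ Cp_eff(T) ∂T/∂t = ∇·(λ ∇T) + ω_eff ρ_b c_b (T_b − T) + Q_appl

with tissue density ρ, thermal conductivity λ, blood density ρ_b, blood
specific heat c_b and body temperature T_b = 37 °C. Note that the perfusion
sink is sometimes written without the blood specific heat; that form is
dimensionally inconsistent, so the solver carries an explicit `c_b` factor
(literature blood value, 3617 J/(kg·K)) and offers
`TissueProperties(omit_sink_blood_heat=True)` to reproduce the c_b-less
variant (c_b ≡ 1 numerically) when comparing against implementations that
use it.

All tissue constants are generic literature liver/blood values collected in
`mwaplan/constants.py`, each overridable via `TissueProperties`:
ρ = 1079 kg/m³, Cp = 3540 J/(kg·K), λ = 0.52 W/(m·K), ω_b = 6.4·10⁻³ 1/s,
ρ_b = 1060 kg/m³, c_b = 3617 J/(kg·K).

### Evaporation-effective heat capacity

Tissue water vaporization around 100 °C is modelled through an effective
heat capacity: Cp_eff(T) = Cp + w·L·N(T; 100 °C, 3 °C), where w = 0.778 is
the tissue water mass fraction, L = 2.26 MJ/kg the latent heat and N a
normalized Gaussian, so the added bump integrates over temperature exactly
to w·L. This produces the characteristic temperature plateau near 100 °C.
`enthalpy_density` provides the closed-form antiderivative used in energy
audits.

### Perfusion sink and the vessel subdomain

The effective perfusion coefficient per voxel is

    ω_eff = ω · max(0, 1 + s·(T − T_b)) · exp(−Ω)

with baseline ω = ω_b on liver tissue and ω = ω_vessel on the segmented
vessel subdomain. The linear sub-lethal term (s = 0.02 1/K) encodes
hyperaemic perfusion increase with mild heating; the exp(−Ω) factor shuts
perfusion down as Arrhenius damage Ω accumulates (coagulation).

`ω_vessel = 2.0 1/s` is an effective convective-exchange rate standing in
for resolved blood flow in vessels of radius ≥ 1 mm; it was sized so that
the wall of a ~6 mm vessel a few millimetres from a full-power active zone
stays below 50 °C, which reproduces the qualitative heat-sink behaviour
(flowing blood pins large-vessel walls near body temperature). It is a
perfusion term, not a hard temperature clamp, so vessel-occlusion scenarios
(sink collapse under accumulated damage) remain representable. Voxels
outside the liver mask are treated as tissue with baseline perfusion.

### Applicator heat source

A full electromagnetic solve is out of scope. The antenna is a line segment
(active zone, default length 20 mm, extending proximally from the tip) with
a separable deposition density

    q(x) ∝ exp(−d_ax(x)/L_ax) · exp(−d_rad(x)/L_rad),

normalized to sum to 1 over the simulation grid; d_ax is the axial distance
beyond the segment ends and d_rad the radial distance from the axis.
Deposited power is P·η(T(x))·q(x), where the absorption multiplier
η(T) falls logistically from η_baseline (default 0.75) to a floor of 0.1
around T_dry = 100 °C (width 5 °C), encoding the loss of microwave
absorption in desiccated tissue. Any smooth two-parameter family able to
match a prolate isotherm would serve; this one was chosen for its minimal
parameter count and is documented as replaceable.

### Calibration against manufacturer tables

Vendors tabulate expected ablation length/diameter per (power, time),
typically from ex vivo experiments. `calibrate` fits the two decay lengths
(L_ax, L_rad) so that full simulations — baseline perfusion on, no vessel
subdomain, matching in-vivo conditions away from large vessels — reproduce
the table. The fit is a bounded, derivative-free, damped multiplicative
fixed-point iteration on the reference (median) table row, exploiting the
near-diagonal sensitivity of ablation length to L_ax and diameter to L_rad;
it converges in ~4 iterations and is deterministic from its fixed starting
point. The fitted model is then re-simulated on every table row and per-row
residuals reported. The absorption-curve parameters are held at their
defaults during calibration (a config choice; they are weakly identified by
size data alone).

Because real vendor tables are proprietary, the bundled table
(`data/manufacturer_table_synthetic.csv`, 80/90/100 W × every whole minute
from 3 to 10) is
*synthetic*: it was generated by this package's own simulator at a fixed
reference source model (`scripts/make_synthetic_table.py`) whose parameters
differ from the calibration template's starting point. Calibrating against
it is therefore a genuine round trip — the optimizer must recover ablation
dimensions produced by parameters it does not start from — and the shipped
values are reproducible to the stated rounding. Its dimensions (41–49 mm
length, 24–33 mm diameter) sit in the range of published 2.45 GHz MWA
devices.

### Arrhenius damage and ablation extraction

Thermal injury is the first-order Arrhenius integral
Ω(x) = ∫ A·exp(−E_a/(R·T_K)) dt with liver coagulation kinetics
A = 5.51·10⁴¹ 1/s, E_a = 2.769·10⁵ J/mol. The predicted ablation is the
region Ω ≥ Ω* with Ω* = 1 (≈63 % cell death) — used consistently for
calibration and evaluation, and exposed as a config/CLI option. The solver
co-integrates Ω trapezoidally at every time step (so the perfusion sink can
react to coagulation); the standalone `damage.accumulate` operation applies
the same rule to saved temperature snapshots. Sequential ablations of a
plan are treated as independent — each starts from a uniform 37 °C field —
and their masks are united; a warm-start mode is deliberately absent from
the defaults.

## Numerics

* **Scheme.** Backward (implicit) Euler with a 7-point Laplacian;
  all nonlinear coefficients (Cp_eff, ω_eff, η) lagged one step. This is
  unconditionally stable against the strong vessel sink at dt = 1–10 s.
* **Linear solver.** The symmetric positive-definite step system is solved
  matrix-free with Jacobi-preconditioned conjugate gradients (relative
  tolerance 10⁻⁷) on the temperature deviation from T_b; a fused-stencil
  `numba` kernel is used when available, with a pure-numpy fallback that
  computes identical results. Typical step counts are 8–25 CG iterations.
* **Boundaries.** Dirichlet T_b on a ghost layer outside the domain faces
  (default), or zero-flux "insulated" faces for energy audits. A
  no-diffusion mode supports closed-form verification.
* **Subdomains.** Each ablation is simulated on a local box around its
  active zone (default margin 30 mm, clipped to the case grid, Dirichlet
  T_b on its faces): the Ω ≥ 1 region ends well inside the margin, so this
  changes predictions negligibly while making multi-ablation cohorts cheap.
  Calibration uses a 34 mm margin at 1 mm spacing.
* **Step sizes.** dt = 5 s for plan/calibration runs (volume metrics are
  insensitive below this); dt = 0.5 s for energy audits, which resolves the
  passage of voxels through the evaporation Cp bump — with η ≡ 1 and
  insulated faces, the continuous-enthalpy balance then closes to well
  under 1 % per simulated minute; dt = 0.1 s for the analytic verification
  cases. Verified accuracy: free-diffusion Gaussian L∞ error < 1 % at
  0.5 mm / 0.1 s, perfusion-only exponential decay < 0.5 %, uniform
  insulated heating exact to solver tolerance, peak temperature change
  < 2 % from 1 mm to 0.5 mm grids.
* **Determinism.** Fixed inputs give bit-identical outputs; there is no
  hidden randomness in the solver, and all phantom sampling flows from
  explicit seeds.

## Metrics

* **Dice** 2|A∩B|/(|A|+|B|); defined as 1 when both masks are empty.
* **Signed surface distances.** Surfaces are mask boundary voxels
  (6-connectivity); for each predicted-surface voxel the Euclidean
  distance transform gives the exact distance (mm) to the ground-truth
  surface, signed positive where the prediction locally encloses the ground
  truth and negative where the ground truth extends outside it. The
  reported Hausdorff distance is max |d|; the 95th percentile is also
  reported. Distances are computed prediction → ground truth (a symmetric
  variant is a trivial max of both directions). Voxel-center surfaces bias
  distances by up to half a voxel; sub-voxel meshing is deliberately not
  used so the metric stays exactly oracle-testable.
* **Vascular fraction.** |vessels ∩ E| / |E| where E is the manufacturer
  ellipsoid (tabulated length/diameter at the case's own setting, long axis
  along the applicator, centered at the active-zone midpoint). For
  multi-ablation plans the maximum over per-ablation ellipsoids is used —
  the most vessel-affected ablation governs the cooling risk — with a mean
  variant available.
* **Cohort statistics.** Identity-line relative distance (y−x)/x between
  model (y) and manufacturer (x) volumes; two-group Tukey (studentized
  range, Tukey–Kramer) 95 % CI between cases with vascular fraction > 5 %
  and the rest, applied to |identity distance| (the signed variant is also
  computed); a threshold scan returning the smallest candidate VF threshold
  with a significant split; box-and-whisker aggregates (Tukey 1.5·IQR
  whiskers) of |ΔV|/V_GT, Hausdorff and Dice for model vs manufacturer,
  with paired mean deltas oriented so positive favours the model; Pearson r
  on untransformed volumes. Expert-review exclusion flags (overestimated
  ground truth, misaligned applicator) are *inputs* carried per case, never
  auto-detected; the phantom plants them with known labels so the exclusion
  pathway is testable.

## Synthetic phantoms — what they emulate and what they don't

`phantom` generates desk-scale cases: an ellipsoidal liver with a smooth
seeded surface perturbation; a recursive branching tree of tapered vessel
tubes (default 2 roots, 3 levels, 4 mm root radius, taper 0.7 per level,
radius floor 1 mm — thinner branches contribute no relevant heat sink);
applicator plans drawn from the clinically observed ranges (80/90/100 W,
whole-minute durations of 3–10 min as clinically programmed, 1–6 sequential
ablations); and a synthetic ground truth.

The ground truth is produced **by the biophysical model itself** (vascular
cooling on), optionally degraded by two controlled artifacts seen in real
retrospective data: a rigid shift of the ground truth (registration error
between the planning and control scans) and a wedge-shaped inflation from
the ablation towards the liver capsule (vasculature "shortage": occlusion-
induced infarction that images like ablated tissue). This closed loop is a
deliberate design choice: it gives the validation pipeline known answers
(artifact-free cases must close at Dice = 1 exactly), makes artifact
effects strictly attributable, and keeps everything seeded and
reproducible. **It is not a clinical validation** — agreement of the model
with its own output says nothing about agreement with contrast-CT ground
truth in patients, real registration error is deformable rather than rigid,
real vessel trees and infarct geometry are far more complex, and CT
segmentation noise is absent entirely.

Cohort-level experiments use a "desk-scale" configuration chosen for
single-workstation runs: 20 cases on 96³ grids at 1 mm with 1–2 ablations
per case and half the cohort constructed with a root vessel adjacent to the
applicator (the rest with vessels ≥ 25 mm away) to plant a vascular-fraction
spread straddling the 5 % analysis threshold. Plan settings are drawn once
per case slot and shared between the high-VF case and its low-VF
counterpart, so the two groups see an identical power/duration mix: without
this pairing the vascular-fraction grouping is confounded with ablation
size (small ellipsoids inflate VF), and setting-dependent discretization
bias can masquerade as a group effect in the null (cooling-off) comparison.
Under these conditions the
cooling-off model correlates with the manufacturer baseline at r > 0.99
with a non-significant Tukey split, while the cooling-on model shows a
significant high-VF deviation below the identity line — the qualitative
signature reported for clinical cohorts — at effect sizes native to these
phantoms, not those of any clinical dataset.

## Degenerate inputs and tie-breaks

Empty masks: Dice of two empty masks is 1; surface distances require both
masks nonempty and raise otherwise. Table lookups never extrapolate.
The threshold scan skips candidates leaving fewer than two cases on either
side and breaks ties toward the smaller threshold. Pearson r on a
zero-variance cohort is reported as undefined (`None`) rather than NaN.
The shortage wedge picks, among a fixed set of candidate directions, the
one adding the most liver tissue beyond the existing ablation, so the
artifact reliably inflates the ground truth even when the ablation already
touches the nearest capsule point.

## Known limitations

No electromagnetic field solve (the deposition profile is phenomenological);
no tissue shrinkage, swelling or vascular-infarction dynamics; no flow-
resolved hemodynamics (the vessel sink is an effective exchange rate); λ is
constant by default (an optional linear slope is not enabled); CEM43 dose is
not the ablation criterion (Ω threshold only); registration artifacts are
rigid integer-voxel shifts; and the exact parameterizations of the
temperature-dependent perfusion and absorption curves are documented
stand-ins with the correct qualitative shape, re-fitted rather than
transcribed from any specific device.
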