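# Methods

## System and models

A VWF concatemer of N monomers (20–200) is tethered to the wall of a flow
chamber and exposed to wall shear stress σ (dyn cm⁻²; 1 dyn cm⁻² = 0.1 Pa).
Above an onset stress the molecule extends along the flow axis; drag on each
monomer is transmitted along the spine, so tension rises linearly from zero
at the free end to f_mono·N_down at the tether. Fluorescent GPIbα binds the
A1 domain of monomers whose local tension has switched A1 into its
high-affinity state.

### Per-monomer drag and tension

Each monomer is idealized as a chain of spheres translating with the local
flow, v = γh, where γ = σ/μ is the shear rate and h the sphere-center
height. Stokes' law per sphere gives f = 6π·μ·r·v = 6π·r·σ·h — viscosity
cancels, so drag depends only on σ and geometry. Two geometries bracket the
uncertainty: a *dumbbell* (one 13 nm-radius sphere per monomer at h = 20 nm)
giving 0.6 pN at 1280 dyn cm⁻², and a *five-sphere* chain (five 3 nm-radius
spheres at h = 10 nm) giving 0.4 pN; their mean, ≈0.5 pN per monomer at
1280 dyn cm⁻², is used throughout. Tension bookkeeping: the per-monomer
profile stores f_mono × (monomers strictly downstream), so the free-end
entry is exactly zero; the tension at the tether point itself, which also
carries the tethered monomer's drag, is exposed separately as
`tension_at_tether` = f_mono·N_down. For an interior tether only the longer
arm bears load; the short arm trails with zero tension.

### Two-state force activation

A1 occupies a low-affinity state 1 and a high-affinity state 2 separated by
ΔG (k_BT units) at zero force; tension f tilts the balance by −f·Δx, with
Δx the inter-state displacement projected on the force axis (Δx₀·cosθ is
never decomposed). The state-2 occupancy is logistic,

    P₂(f) = 1 / (1 + exp(ΔG − f·Δx/k_BT)),

with half-activation at f½ = ΔG·k_BT/Δx. Equilibrium bound density is
n(f) = n_max·P₂(f) with n_max = N_total·[C]/(K_D,2 + [C]); the apparent
on-rate is k_on(f) = k_on,2·P₂(f) while k_off is force-independent over the
observed range (the data show no catch-bond decrease, and none is modeled).
k_B = 0.0138 pN·nm/K; the default temperature is 295 K (22 °C assay
temperature) — the temperature enters only through k_BT and is configurable
on every parameter object.

### Association kinetics

With ligand in large excess, bound density in a tension bin follows
homogeneous 1:1 kinetics (pseudo-first-order): the observed rate
k_obs = k_on[C] + k_off is affine in concentration. `fit_association`
performs a global least-squares fit of (k_on, k_off, N_total) across the
concentration ladder of one bin, with rates fit in log-space for
conditioning; a per-trace exponential fit followed by linear regression of
k_obs on [C] is retained as an independent cross-check pathway. Confidence
intervals are residual-bootstrap percentiles. Single-concentration inputs
are fit but flagged under-identified; data whose rise completes before the
first frame are flagged `kobs_unidentifiable_plateau_only` (the criterion is
k_obs·t₁ > 3). Ligand depletion is ignored per the stated excess.

### Relaxation and extension laws

After flow stops, normalized length follows L/L0 = (1−a) + a·exp(−t/τ).
The amplitude a is fit globally across traces by default (a single a ≈ 0.96
describes the ensemble); per-trace a is available. τ scales with initial
length as τ = A·L0^ν, fit by log–log regression with a bootstrap CI on ν;
rescaling time by L0^−ν collapses the ensemble onto one master curve, and
the collapse dispersion (mean across rescaled-time bins of the inter-trace
SD) is minimized near the true ν — the Zimm range ν ≈ 1.5–1.8 is used only
as a comparison constant. Under flow, steady-state relative extension rises
linearly in ln σ between an onset stress (≈15 dyn cm⁻²) and saturation
(1280 dyn cm⁻²); the log-shear fit excludes saturated points (L/L0 > 0.95)
and reports the stress where the line extrapolates to zero extension.

### Trace analysis and calibration

Profiles are 1-D two-channel intensity traces along the flow axis (pixel
0.27 μm by default; the tether at the x-minimum for forward flow). Length is
the largest contiguous run above background-median + 3·(1.4826·MAD), with
the threshold crossing interpolated into the flanking pixel but clamped to
the boundary pixel's half-width, so a single bright pixel measures one pixel
width. Intensity converts to counts via the single-fluorophore intensity
(median downward step from binary-segmentation change-point detection of a
photobleaching staircase; segments must be flat at the noise scale, so
smooth ramps are rejected) divided by the degree of labeling (0.67
fluorophores/monomer for VWF, 1.01 per molecule for GPIbα). TIRF height
correction (penetration depth 150 nm, reference height 4.5 nm) is available
but off by default, matching the uncorrected calibration convention.

Cohort QC excludes concatemers whose repeat lengths at matched σ vary by
CV > 10% and, for binding analyses, those extended < 20 nm per monomer at
1280 dyn cm⁻². Bound-ligand density is accumulated in seven half-open 8 pN
tension bins, [0,8) … [48,56); sites above 56 pN fall outside the binned
analysis and are dropped; the per-bin force is the mean tension of member
monomers, not the bin midpoint. The lowest bin is fit-eligible for
equilibrium binding but excluded from kinetic fitting, where its signal is
too low to constrain rates.

Activation is called when ROI ligand density exceeds background mean + 3 SD
in ≥ 3 consecutive steady-flow frames (strict inequality; the exact
experimental criterion is not published, so this reconstruction was chosen
to pin the per-triplet false-positive rate near 0.1%, verified by Monte
Carlo). The threshold stress σ_T is the first positive call of an ascending
ramp; σ₅₀ per size bin is taken from the median-σ_T concatemer of the bin
(its (N, σ_T) pair is used jointly, which keeps σ₅₀·N exact on pure
hyperbolas); b of σ₅₀ = b/N_VWF comes from count-weighted least squares. A
logistic percent-activated fit is a possible alternative σ₅₀ definition; the
median was chosen for robustness at the per-bin counts involved.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
log-uniform sizes over 20–200 monomers; tether attachment within the
terminal 10% of either end (end-biased wall capture); Poisson labeling at
0.67/monomer; log-shear extension between onset 15 and saturation
1280 dyn cm⁻², with saturation extension per monomer drawn from
Normal(31, 12) nm truncated at 5 nm (reproducing the ~16% sub-20 nm QC
exclusion fraction); instantaneous extension (complete within one frame) and
exponential relaxation with τ = 0.2·L0^0.59 s and lognormal scatter
(σ_log = 0.15); one A1 site per monomer at 60 nm contour spacing —
sub-stoichiometric occupancy, not site spacing, then produces the ~126 nm
observed spacing between bound ligands; binding rates k_on,2 = 50×10⁶
M⁻¹s⁻¹, k_off = 3.9 s⁻¹, ΔG = 3.2 k_BT, Δx = 0.6 nm (150 mM preset; the
10 mM preset uses 538×10⁶, 0.3 s⁻¹, 2.8 k_BT, 0.8 nm); frame schedules of
10 ms exposures every 300 ms (equilibrium), 57 fps (kinetics) and 20 fps
(relaxation); Gaussian PSF (σ = 0.15 μm), TIRF attenuation by height,
Poisson photon noise and Gaussian read noise.

Two sampling conventions coexist deliberately. Flow-initiation *kinetics*
are simulated as an exact per-site telegraph (Gillespie) process with rates
k_on,2·P₂(f)·[C] and k_off — exactly the process the kinetic equations
describe, so rate recovery is unbiased. *Equilibrium snapshots* are drawn
from the equilibrium binding law P₂(f)·[C]/(K_D,2+[C]) itself. The telegraph
stationary law, P₂[C]/(P₂[C]+K_D,2), differs from the binding isotherm at
low force: fitting the isotherm to telegraph-stationary data would recover
ΔG shifted by exactly ln(1+[C]/K_D,2) (≈0.8 k_BT at 100 nM). The two-state
binding framework treats the conformational populations as set before
ligation; the equilibrium generator follows that hierarchy so that fits
recover the generating parameters, and the distinction is surfaced here
rather than hidden in a fudge factor.

Activation thresholds are generated as a *pure tension threshold*: a
concatemer activates at the first ramp stress where f_mono(σ)·N_down reaches
the tension implied by the configured b (27 pN at b = 6.9×10⁴ dyn cm⁻²
given 0.5 pN per monomer at 1280 dyn cm⁻²). The analysis bins by total
N_VWF (the tether position is unresolved experimentally), which biases
recovered b upward by the ~5–10% tether offset plus ramp discretization —
visible in the round-trip reports and well inside the 20% recovery check.

Not emulated: polymer hydrodynamics (no Zimm/Rouse dynamics — extension and
relaxation laws are phenomenological by design), 2-D imaging (profiles are
born 1-D; no registration or drift), partial compact-state shielding
(all-or-none per molecule), ligand depletion, and photophysics beyond
single-exponential bleaching. Passing round trips therefore validate the
estimators against the assumed data-generating laws, not against un-modeled
instrument systematics.

## Numerical choices

- Two-state fits: trust-region least squares with bounds ΔG ∈ [0, 20] k_BT,
  Δx ∈ (0, 5] nm, amplitude ≥ 0; five fixed multi-starts guard the
  logistic's flat directions; bin weights are √(concatemer counts).
  Bootstrap CIs resample bins (500 reps default, seeded; replicates restart
  from the point fit). n_max can be floated (default) or pinned to an
  independent N_total estimate — both modes are provided since either
  convention is defensible.
- Kinetic global fits: Levenberg–Marquardt on log-parameters; N_total
  shared across concentrations by default (the model has a single N_total),
  per-concentration plateaus as an opt-in diagnostic; 300 residual-bootstrap
  reps.
- Off-rate after flow stop: A·e^−kt + B fit; noise is estimated from the
  settled tail so fast decays do not inflate it; results with 1/k shorter
  than two frame intervals are flagged as lower bounds.
- Degenerate inputs raise or flag, never silently fall back: non-decaying
  traces, stepless staircases, all-saturated extension curves, degenerate
  L0 ranges, non-monotone stress schedules, empty backgrounds.
- Report-level rounding: one decimal for pN, one significant figure for
  collision rates; unrounded values are always retained on the objects.

## Problem sizes

The default study-scale datasets are: 240 concatemers for the activation
cohort, 103 long concatemers × 5 equilibrium frames for force-binned
binding, 94 flow-stop traces for relaxation scaling, and 5-concentration ×
34-frame ladders at 2000 sites per tension bin for kinetics; the stochastic
ensemble checks use 1000–10,000 independent sites. Simulation-study examples
quoted at 200 replicates in exploratory analyses are exercised in the suite
as single-seed recovery checks at the same tolerances plus 20-replicate
coverage checks, which keeps the full suite under a minute without changing
the conditions tested.

## Known limitations

- The σ₅₀ analysis uses total concatemer size for N, as the experiment does;
  recovered b inherits the corresponding upward bias.
- k_off is modeled force-independent within 0–56 pN; the post-flow-stop
  apparent off-rate (~23 s⁻¹) reflects relaxation-coupled state change and
  is reported only as a lower-bound-flagged exponential fit.
- The equilibrium-vs-telegraph ΔG convention above matters when comparing
  fitted ΔG across concentrations; fits at one concentration are internally
  consistent.
- Intensity calibration assumes a stationary single-fluorophore brightness;
  blinking and bleaching during acquisition are not modeled.
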