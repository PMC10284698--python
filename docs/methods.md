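# Methods

This note records the models implemented in `sterolfilm`, the default
parameters and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter.

## Adaptation kinetics

The interfacial polarity adaptation that builds adhesion force is modelled
as an order-*n* decay of the surface density σ of not-yet-adapted
cooperative sites, dσ/dt = −kσⁿ, with closed forms σ(t) = σ₀e^(−kt)
(n = 1) and σ(t) = σ₀[1 + (n−1)kσ₀ⁿ⁻¹t]^(−1/(n−1)) (n > 1). The measured
force is taken proportional to *adapted* sites, F(t) = F∞(1 − σ/σ₀), so
F(0) = 0 and F rises monotonically — the orientation that matches
force-vs-contact-time data. σ itself decays; only the complement is
observable as force.

Identifiability: force data constrain only κ = kσ₀ⁿ⁻¹, which is what
`fit_kinetics` reports. Order selection uses AICc (curves have ≤ 16
points). Two selection modes exist because raw single curves are
uninformative: at 5 % multiplicative noise, the best wrong-order fit
differs from the true order-3 curve by under 1 % of F∞, so single-curve
selection is near chance — an information limit, not a fitting defect.
The default mode therefore pools replicate curves into a mean ± s.e.m.
curve and fits with inverse-variance weights (AICc evaluated on the
weighted χ² actually minimized); per-curve majority voting remains
available.

Generator defaults (chosen once): 12 contact times geometrically spaced
over 0–60 s — the early-time curvature is where adjacent orders differ,
and multiplicative noise makes early points precise — with κ = 0.3 s⁻¹
(half-rise ≈ 5 s, an adaptation over "a few seconds"), F∞ = 1.5 nN,
noise CV 0.05. Under these conditions pooled selection recovers order 3
in ≈ 99 % of 20-curve batches.

Repeated-force variability uses the population coefficient of variation
of mean-normalized series; normalization is scale-invariant and
idempotent.

## Adsorption thermodynamics and the entropy barrier

Sauerbrey: Δm = −C·Δf/n with C = √(ρ_q μ_q)/(2f₀²); standard AT-cut
quartz constants (ρ_q = 2648 kg m⁻³, μ_q = 2.947 × 10¹⁰ Pa) give
C ≈ 17.7 ng cm⁻² Hz⁻¹ at 5 MHz. Rigid-film assumption only.

Coverage inversion assumes Langmuir equilibrium: θ/(1−θ) = Kx with a
mole-fraction standard state (x = c/55.5 M) so K is dimensionless and
ΔG = −RT ln K is well posed. The standard-state choice shifts ΔG by an
additive constant only; ΔS comes from the *slope* of ΔG(T) and is
convention-invariant, as is the barrier
ΔS_barrier = ΔS_multilayer − mean(ΔS_controls) (errors in quadrature over
the two fixed-monolayer controls).

Statistical care: the log transform of a noisy coverage is biased near
saturation. `dG_from_replicates` pools replicates at each temperature and
subtracts the second-order delta-method term ½g″(m̄)·Var(m̄), then the
ΔG(T) line is fitted with inverse-variance weights. Measured over 200
synthetic replicates per barrier value in {−100, −200, −300} J mol⁻¹ K⁻¹,
the chain's mean error is ≲ 1 J mol⁻¹ K⁻¹ and statistically
indistinguishable from zero.

Generator defaults: ΔH = −55 kJ mol⁻¹, intrinsic ΔS = −50 J mol⁻¹ K⁻¹,
barrier −200 J mol⁻¹ K⁻¹ on the multilayer class, 6 temperatures
288–313 K × 3 replicates, γ_max = 250 ng cm⁻² (a compact lysozyme
monolayer), x = 1.26 × 10⁻⁷ (100 µg ml⁻¹ lysozyme), mass noise 2 % of
γ_max. The multilayer class also receives a compensating enthalpy
T_comp·ΔS_barrier (T_comp = 300.5 K, mid-range): without
enthalpy–entropy compensation a 200 J mol⁻¹ K⁻¹ barrier separates the
surface classes by ~60 kJ mol⁻¹ in ΔG, pushing one class to vanishing or
saturated coverage where no slope is measurable. Compensation is a
physically standard feature of adsorption systems and leaves the slopes —
the only quantity the barrier chain uses — untouched. `gamma_max="auto"`
(5 % above the observed maximum) exists for capacity-free use but is
biased when the data approach saturation; supplying the known capacity is
preferred.

Geometric estimate: ΔS = R ln(A_constr/A_fluct) per interfacial molecule,
multiplied by the number of molecules constrained under one adsorbed
protein. Defaults: A_constr = 0.38 nm² (upright sterol ring
cross-section), A_fluct = 1.71 × 0.65 nm² ≈ 1.11 nm² (side-on molecular
dimension swept by a cooperatively pivoting molecule), and 18 molecules —
six cooperative trios — under a ~7 nm² lysozyme footprint. These are
literature-standard cholesterol/lysozyme dimensions; together they give
≈ −160 J mol⁻¹ K⁻¹ per protein, consistent with the measured barrier.
The hydrogen-bond equivalent T|ΔS|/E_HB uses E_HB = 20 kJ mol⁻¹ per bond
(configurable; a mid-range literature value).

## Rotor Monte Carlo model

Geometry: `n_layers` × `per_layer` molecules (default 4 × 128 = 512) on a
per-layer lattice in a 7.1554 × 7.1554 × 50 nm³ box, stacked as two
tail-to-tail double layers so hydroxyl heads meet at the inner interface
and face the water on top. 128 molecules factor as a 16 × 8 grid
(spacings 0.894/0.447 nm); layer counts with no factorization of aspect
ratio ≤ 4 are rejected. A configurable fraction of top-layer molecules
starts head-down ("reverted"); the count uses the ceiling of
fraction × per_layer, which reproduces the reference counts 13/39/64 at
10/30/50 % of 128.

Only the interfacial layer is mobile (lower layers emulate the
substrate-restrained bulk). Its reduced energy in kT units is

    E = −Σ⟨ij⟩ J_ij (u_i·u_j) − h Σ u_iz + ½k_z Σ δz_i²

with bond couplings J_ij = J(a/d_ij)² (a = shortest spacing) so the
anisotropic grid behaves laterally isotropically. Metropolis proposals
are small-angle axis perturbations (σ = 0.35) mixed with 10 % axis
inversions; any proposal whose head crosses the equator is accepted with
probability e^(−B)·min(1, e^(−ΔE)). The prefactor form matters: adding B
to ΔE inside the exponent would break detailed balance whenever
|ΔE| < B, whereas a symmetric kinetic prefactor cancels from the balance
condition — equilibrium is untouched and only flip *kinetics* slow by
e^(−B), which is exactly the physics being modelled (an activation
barrier for reorientation through the lying-down state). Head heights
take independent Gaussian-step Metropolis moves. Updates run on a
checkerboard so simultaneously updated sites never interact; sweeps are
recorded every `sample_stride` after `burn_in`, and acceptance statistics
(with an optional per-proposal log for balance verification) are kept.

Defaults J = 0.4 kT and h = 0.15 kT were set once from a mean-field
estimate targeting weak global polar order with nearest-neighbour
alignment — the regime in which the pair correlation C_r decays within
about one lattice neighbour distance (measured decay distance ≈ 0.78 nm)
while a head-down molecule still relaxes head-up. The presets then differ
only in kinetics and stiffness: cholesterol-like B = 1.5 kT,
k_z = 10 kT nm⁻² (head-height r.m.s. ≈ 0.32 nm); stigmasterol-like
B = 12 kT, k_z = 45 kT nm⁻². At 10 % reversion the cholesterol-like
preset recovers every reverted molecule within a few thousand sweeps
while the stigmasterol-like preset recovers none, and its interfacial
height RMSD is about half — the qualitative contrast between the two
analogues. Monte Carlo sweeps are not mapped to physical time; no
quantitative correspondence to atomistic dynamics or microsecond
timescales is claimed.

## Trajectory observables

The interface selection is frozen at the first frame (topmost layer
index, or a head-height cutoff for imported trajectories). Tilt is
arccos(u_z) ∈ [0°, 180°]; for GRO imports the axis is the normalized
tail-to-head (C17→C3) vector so an equilibrium head-up molecule sits near
0°. C_r(d) is the mean of u_i·u_j over pairs at minimum-image lateral
distance d (x, y only — the interface is quasi-2D); a second-Legendre
estimator is available but the first-rank form is the default and the one
used in headline runs. Empty bins are reported as NaN with zero counts,
never as zero correlation. Dispersion is the s.d. of per-time-window
means (5 contiguous windows). The decay distance is the first crossing
below 1/e of the first populated bin, linearly interpolated; curves that
never cross are reported censored at the maximum distance. Height RMSD is
referenced to the first analysed frame by default (time-mean reference
optional). Flip detection uses a 60°/120° hysteresis band so angular
noise around the equator cannot generate spurious events; a recovery is
the first crossing of an initially reverted molecule below the aligned
threshold within the frame budget.

## FRAP

The generator simulates explicit 2D Brownian particles in an 80 µm
periodic square: everything inside the 10 µm disc at t = 0 is bleached
dark, a `mobile_fraction` subset diffuses with per-frame steps of
variance 2DΔt per axis, and the recorded intensity is the bright count in
the disc normalized to the pre-bleach density, at 1 s per frame for
300 s. Bleaching is binary and there is no acquisition bleaching,
matching the fitted model's assumptions. Two finite-size effects are
inherent: the plateau is 1 − A_disc/A_field ≈ 0.988 rather than 1, and
long-wavelength density fluctuations relax on L²/4D (hundreds of
seconds), leaving a persistent random offset of order 1/√N_disc in the
tail. The default 2 × 10⁵ particles keep both below the fit's noise
floor.

Fitting uses the Soumpasis uniform-disc closed form, evaluated with
exponentially scaled Bessel functions (i0e/i1e) for stability at small t,
and nonlinear least squares in (τ_D, mobile fraction);
D = w²/(4τ_D). The closed form was chosen over Hankel-transform numerical
schemes because it is testable against an independent Bessel-series
oracle; self-consistency (fit of model-generated data) recovers
parameters to machine-level precision, and particle-simulated curves at
D = 0.35 µm² s⁻¹ fit back within the 0.3–0.4 µm² s⁻¹ band. Flat curves
are flagged immobile with D reported as not estimable.

## Bioadhesion index

Surface × assay means (medians optional for outlier-dominated counts) are
divided by the cholesterol-multilayer mean per assay; the index is the
arithmetic mean of the normalized components per surface (geometric mean
optional; the choice is recorded in every report). A composite reference
value is built from per-assay control surfaces (bare substrate for
bacterial counts, bare metal for adsorption) and aggregated the same way.
The index is invariant to per-assay rescaling and assay order, and the
reference surface scores exactly 1. Cell counts scale to cells mm⁻² as
count × 10⁶ / area(µm²).

## What the generators do not emulate

Synthetic force curves have i.i.d. multiplicative noise — no drift,
cantilever artefacts or retraction-shape effects. The adsorption
generator assumes ideal Langmuir equilibrium with Gaussian mass noise —
no kinetic endpoints, viscoelastic QCM response or protein conformational
entropy. The rotor model has no water, ions, electrostatics or atomistic
detail, and Monte Carlo time is not physical time. FRAP curves assume
pure diffusion with binary bleaching. Passing tests therefore demonstrate
the correctness and statistical calibration of the analysis chains under
their stated model assumptions, not instrument-level realism.

## Problem sizes

Default test and example runs use 20-curve kinetics batches, 6 × 3
adsorption tables, rotor runs of 5 × 10³–2 × 10⁴ sweeps (the headline
correlation run uses 5 × 10⁵ sweeps after burn-in, sampled every 500),
and 2 × 10⁵ FRAP particles × 300 frames — sizes at which every stage's
statistical targets are met on a single CPU in minutes.
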