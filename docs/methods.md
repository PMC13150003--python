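# Methods

## Scope and model

`r1rho` implements rotating-frame (R1ρ) relaxation-dispersion analysis for
protons in exchanging biomolecules, with two connected capabilities:

1. a Bloch–McConnell simulator that quantifies how dipolar cross-relaxation
   with a neighbouring proton distorts ¹H R1ρ dispersion profiles, and
2. a dispersion-fitting suite for two- and three-state chemical exchange
   (linear, star and triangular three-state topologies), with Monte-Carlo
   uncertainties and AICc/BIC/F-test model selection.

The motivating system is imino/aromatic protons in duplex DNA, where the
Watson–Crick-Franklin (WCF) ground state exchanges with a sparsely populated
Hoogsteen (HG) conformer and a second excited state (ES2), but nothing in
the code is DNA-specific.

### Evolution generator

The rotating-frame dynamics of an n-site exchange network are written as a
homogeneous linear system dM/dt = L·M over {I_x, I_y, I_z} per site,
extended to {S_x, S_y, S_z} per site when a dipolar-coupled neighbour
proton is present (dimension 3n or 6n).  Per-site blocks carry the offset
δ_i = 2π(Δω_i/2π − Ω_SL/2π) relative to the spinlock carrier, the RF
nutation ω_SL about +x, and the auto-relaxation rates −R2 (transverse) and
−R1 (longitudinal).  Exchange couples identical operators across sites with
directed rates obeying detailed balance, k_ij = k_ex·p_j/(p_i+p_j), so each
edge is parameterised by one total rate k_ex = k_ij + k_ji and cyclic
topologies are thermodynamically consistent by construction.  Relaxation is
toward zero (no thermal-recovery term): R1ρ is a decay-rate measurement,
and the cross-relaxation artifact mechanism — transfer from a z-polarised
neighbour — is captured by starting the partner at +z (see below).

### Dipolar rates

For a like-spin ¹H–¹H pair at distance r under isotropic tumbling with
correlation time τ_c, the package uses J(ω) = τ_c/(1+(ωτ_c)²) (so J(0) =
τ_c, all prefactors in the rates), d = (μ0/4π)γ_H²ħ/r³ and q = d²/10:

    σ        = q(6J(2ω0) − J(0))          longitudinal cross-relaxation
    μ        = q(2J(0) + 3J(ω0))          transverse cross-relaxation
    ρ1_dip   = q(J(0) + 3J(ω0) + 6J(2ω0))
    ρ2_dip   = q/2(5J(0) + 9J(ω0) + 6J(2ω0))

These reproduce the standard limits (NOE η → +1/2 in extreme narrowing,
σ → −qJ(0), μ → +2qJ(0) in the slow-tumbling limit, so |μ| > |σ| for
duplex-sized molecules).  σ couples I_z↔S_z and μ couples I_x↔S_x, I_y↔S_y
within each exchange site, with site-specific values because exchange can
modulate the distance.  ρ1/ρ2 are computed but *not* added to the
user-supplied R1/R2 by default: when a simulation fixes R1/R2 for every
species, those inputs are taken as already containing all auto-relaxation
pathways.  An `additive_auto` flag enables the additive convention.

### Spinlock element and R1ρ extraction

The simulated pulse element aligns the observed spin's equilibrium z
magnetisation (distributed across sites in proportion to population) along
the average effective field, evolves it under L for each duration τ_SL, and
projects it back — so far-off-resonance locks decay at R1 and on-resonance
locks at R2(+Rex) automatically.  The tilt angle uses the
population-averaged offset (θ = arctan(ω_SL/|Ω̄|)); a ground-state-only
convention is available.  The partner either stays at +z (selective
excitation, default) or is rotated along with the observed spin
(nonselective).  Both modes are provided because pulse-sequence details
vary; selective is the conservative default for imino-proton experiments
with selective excitation schemes.

R1ρ comes from two routes:

- **decay route** (simulation, supports the partner): mono-exponential fit
  of the propagated intensities over 8 durations spanning 0 to
  1.5/R1ρ_expected, auto-scaled from the exchange-only eigenvalue so the
  fit stays well conditioned in every regime;
- **eigenvalue route** (fitting, exchange-only): the eigenvalue of L whose
  eigenvector has maximal overlap weight |⟨m0|v_k⟩⟨w_k|m0⟩| with the
  tilted-frame initial magnetisation; if the top two weights agree within
  0.1% the least negative real part wins.  The overlap rule keeps the
  selection stable at extreme offsets where the "R1ρ-like" and "R1-like"
  modes cross and a bare least-negative-real-eigenvalue rule is ambiguous.

The two routes agree within 1% once τ_SL exceeds ~3 transient lifetimes
(tested).  R2eff = (R1ρ − R1cos²θ)/sin²θ removes the R1 projection.  Note
that the textbook identity R1ρ = R1cos²θ + R2sin²θ for exchange-free spins
is exact only to first order in (R2−R1)/ω_eff; the Bloch eigenvalue carries
a second-order correction (~10⁻⁵ relative at typical conditions), which is
why tests assert exactness only at θ = 90°.

### Cross-relaxation artifact study

The artifact study uses a two-state system with k_ex = 2000 s⁻¹, p_ES =
0.5%, Δω_ES/2π = +600 Hz, R1 = 2.5 s⁻¹, R2 = 22.5 s⁻¹ for all species, a
dipolar partner at Δω_dip/2π = −600 Hz, and τ_c = 5.1 ns at 600.16 MHz —
representative of an imino proton in a mid-sized DNA duplex.  Three
distance scenarios link the partner to the exchange: coupling in the ground
state only (excited-state distance 40 Å, effectively uncoupled), equal
coupling in both states, and stronger coupling in the excited state
(r_j = r_i − 0.2 Å).

The artifact metric at each spinlock grid point is
100·|R1ρ(full) − R1ρ(σ=μ=0)| / R2_ref with R2_ref the population-averaged
input R2 (22.5 s⁻¹ here), i.e. percent of a fixed R2 error band rather than
a point-wise normalisation.  Default grids: 25 log-spaced on-resonance
powers over 100–6000 Hz; off-resonance offsets −900…+900 Hz in 25 Hz steps
at ν_SL = 250 Hz.  These grids span the features that matter (both ±600 Hz
responses and the Rex quench); thresholds near a tolerance boundary can
shift by one grid step under different grids, which is why the distance
threshold is reported on an explicit grid.

With these conditions the maximal on-resonance contribution at r = 3.0 Å
(scenario 1) and r = 3.2 Å (scenario 3) stays below 5% of R2, while at
r = 2.5 Å it exceeds it and the off-resonance profile develops a response
near Δω_dip — the practical distance rules the simulator exists to
establish.

### Decay analysis

Measured (or synthetic) peak intensities are fitted to I0·exp(−Rτ) by
weighted Levenberg–Marquardt with per-point weights 1/rms², where
rms = I/(2·sino) is the per-spectrum baseline noise reconstructed from the
exported signal-to-noise values.  Uncertainties come from Monte-Carlo
resampling (500 replicas by default): parametric redraws around the fitted
curve with the per-point rms as scale.  A residual-resampling scheme is
also provided; parametric is the default because the weighting rule is
explicitly built on per-spectrum noise levels.  Replicas that fail to
converge are excluded; >10% exclusions raise.  Initial guesses (amplitude
from the earliest point, rate from a log-linear regression) remove
starting-point sensitivity.  Covariance-based errors are reported without
reduced-χ² rescaling since the weights are absolute uncertainties; the MC
sd agrees with them within ~20% on well-conditioned curves (tested).

### Exchange fitting

Dispersion datasets (R1ρ or R2eff vs spinlock power and offset, with
per-point sd) are fitted by weighted Levenberg–Marquardt (lmfit) over the
eigenvalue forward model.  Topologies: two-state (a–b), linear (a–b–c),
star (b–a–c), triangular (all three edges), with a = ground state (Δω ≡ 0).
One shared R1 and R2 across states per spin by default; populations are
parameterised by the minor-state fractions (ground state = 1 − Σp).  Global
fits share the kinetic parameters (edge k_ex and populations) across spins
while chemical shifts and relaxation rates stay spin-specific; the sharing
set is overridable.

Numerical choices that matter:

- **log-scale internal parameters.**  Exchange rates and populations are
  minimised as log10 values: their ranges span decades and the log
  parameterisation keeps Levenberg–Marquardt steps well scaled.
- **staged multi-start.**  Random multi-start alone (rates log-uniform over
  [50, 5·10⁴] s⁻¹, populations uniform (10⁻⁴, 0.3), offsets uniform
  ±3000 Hz) reliably stalls in collapsed-second-state minima for
  three-state models.  Three-state fits therefore first run a short
  two-state prefit whose minor state seeds one slot of every start
  (alternating between the two slots) while the second state and extra
  edges keep their random draws.  Every start is explored with a bounded
  iteration budget and the best three are polished to convergence; best-χ²
  wins.  On synthetic triangular data this reproduces the fit polished
  directly from the generating parameters in every tested realisation.
- **minor-state canonicalisation.**  Swapping the two minor states is an
  exact model symmetry for triangular and star topologies; results are
  reported with the minor states ordered by increasing Δω.  The linear
  chain has no such symmetry, but at some conditions a reversed chain fits
  comparably (see Limitations).
- **identifiability.**  Fits require at least n_free + 2 points per
  dataset.  When the observable is R2eff, R1 should be fixed (the transform
  removes the R1 projection, leaving it unidentifiable); the recovery
  harness fixes R1 at its generating value, standing in for the independent
  R1 measurement an experimentalist would use.

Monte-Carlo parameter errors redraw every observable from Normal(value, sd)
and refit from the point estimates (500 replicas by default; the recovery
harness uses 50 to keep ten-seed experiments affordable).

### Model selection

From the weighted-least-squares Gaussian likelihood: AIC = N·ln(χ²/N) + 2k,
AICc = AIC + 2k(k+1)/(N−k−1), BIC = N·ln(χ²/N) + k·ln N.  For nested pairs
(two-state ⊂ linear/star ⊂ triangular) the F-test uses
F = ((χ²₁−χ²₂)/(k₂−k₁))/(χ²₂/(N−k₂)).  A richer model is selected only when
all three rules agree: F-test p < 0.05, ΔBIC ≥ 10, and lower AICc; partial
agreement is recorded as an explicit disagreement without changing the
selection, non-nested pairs skip the F-test, and ties fall to the fewest
parameters.  The conjunction is deliberately conservative — on two-state
data the triangular model is rejected in ≥ 9/10 synthetic runs, while on
triangular data the χ² gap is large enough that all rules agree.

## Synthetic data: what it emulates and what it does not

Two generators exist:

- **intensity tables** (`generate_synthetic_dataset`): propagated spinlock
  decays scaled to an initial intensity, with additive Gaussian noise whose
  per-spectrum rms is a fixed percentage of the initial intensity (baseline
  noise does not scale with the signal), and a sino column satisfying
  rms = I/(2·sino) — the spectrometer-export dialect end to end;
- **dispersion datasets** (`simulate_dispersion_dataset`): eigenvalue-model
  R1ρ/R2eff values with per-point Gaussian noise at a stated percentage,
  used by the recovery experiments.

The recovery experiments use the published best-fit parameter sets as
generating conditions: the wild-type T9 triangular set (k_ex,WCF⇌HG =
2.7 kHz, p_HG = 0.6%, Δω_HG = −593 Hz, k_ex,WCF⇌ES2 = 0.5 kHz, p_ES2 =
0.9%, Δω_ES2 = +288 Hz, k_ex,HG⇌ES2 = 3.2 kHz) and the nebularine-modified
P16 linear set, for which only the fast edge (18 kHz) and its population
(19.3%) are published; the remaining P16 generator values are carried over
from the wild-type set (the WCF⇌HG rate is reported unchanged by the
modification) with the simulation R1/R2 of 2.5/22.5 s⁻¹.  Grids: 15
on-resonance powers 1–6 kHz plus 21-point offset scans (±1.5 kHz) at 250,
500 and 1000 Hz; 2% Gaussian noise; 10 independent realisations.

Synthetic data contain none of the following real-data features: peak
overlap and deconvolution error, B1 inhomogeneity and calibration error,
off-resonance effects of finite alignment pulses, temperature drift, water
exchange, or more than one dipolar neighbour.  Passing recovery tests
therefore demonstrates the *statistical* machinery (estimator correctness,
error calibration, selection behaviour) under the published exchange
regimes — not robustness to instrumental artifacts.

## Known limitations

- Isotropic tumbling only; anisotropic rotational diffusion and
  cross-correlated relaxation are out of scope.
- One dipolar partner; networks of coupled protons (spin diffusion chains)
  are not modelled.
- Exchange fitting uses exchange-only matrices; the simulator's role is to
  certify when neglecting the partner is safe (≥ ~3 Å with the neighbour's
  shift outside the scanned offset window, per the artifact study).
- At the synthetic P16 conditions the orientation of the linear chain is
  only weakly identified: about half of the noise realisations fit a
  reversed chain (ground state connected to the strongly populated end
  state) with indistinguishable χ².  The fast minor–minor edge rate is
  recovered regardless; chain-orientation claims need external information.
- Per-seed exchange-rate estimates at the 78-point grids with 2% noise
  carry ~25–30% Monte-Carlo uncertainty; medians over ten realisations are
  unbiased in our checks but still scatter by ~10%.
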