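# r1rho

¹H R1ρ relaxation-dispersion analysis for exchanging biomolecules:
a Bloch–McConnell simulator that quantifies cross-relaxation artifacts from
dipolar-coupled neighbour protons, and a dispersion-fitting suite for
multi-state chemical exchange with Monte-Carlo errors and statistical model
selection.

## The problem

Rotating-frame relaxation dispersion (R1ρ RD) measures how the decay rate of
spin-locked magnetisation depends on the spinlock amplitude ω_SL and offset
Ω_SL, and from that dispersion extracts the kinetics (k_ex), populations (p)
and chemical shifts (Δω) of sparsely populated excited conformational
states.  Applied to protons — e.g. imino ¹H in DNA at natural abundance —
the experiment has a well-known caveat: a nearby proton can exchange
magnetisation with the observed one through the dipolar interaction
(cross-relaxation rates σ for z–z and μ for transverse transfer, both
∝ r⁻⁶), which distorts the dispersion profile and can masquerade as extra
exchange.  This package answers both halves of the problem:

- **When is the artifact negligible?**  Full Bloch–McConnell propagation of
  the spinlock element for a two-state (GS/ES) spin with a dipolar partner
  at per-state distances, under three coupling scenarios, gives a
  quantitative percent-of-R2 contribution and distance thresholds
  (≈ 3 Å for ground-state-only coupling, ≈ 3.2 Å when the excited state is
  coupled more strongly).
- **Given clean data, what exchange model does it support?**  Dispersion
  datasets are fitted to two-state and three-state (linear GS–ES1–ES2, star
  ES1–GS–ES2, triangular) exchange models, with R1ρ computed as the
  relevant eigenvalue of the exchange-only Bloch–McConnell matrix,
  per-parameter Monte-Carlo uncertainties, and model ranking by AICc, BIC
  (difference ≥ 10) and F-test (95% confidence) in conjunction.

The shipped reference conditions reproduce the WCF ⇌ HG ⇌ ES2 equilibrium
of a DNA duplex, including a triangular three-state parameter set
(k_ex,WCF⇌HG = 2.7 kHz, p_HG = 0.6%, Δω_HG = −593 Hz, p_ES2 = 0.9%,
Δω_ES2 = +288 Hz, k_ex,HG⇌ES2 = 3.2 kHz) and a fast-edge linear set
(18 kHz).  See `docs/methods.md` for the model, conventions and numerical
choices.

## Worked example

Artifact bound for a neighbour proton at 3.0 Å (two-state system with
k_ex = 2 kHz, p_ES = 0.5%, Δω_ES = +600 Hz, Δω_dip = −600 Hz, τ_c = 5.1 ns
at 600.16 MHz):

```python
from r1rho import (ScenarioSpec, default_fig2_system,
                   cross_relaxation_contribution)

scenario = ScenarioSpec(1, 3.0)            # coupling in the ground state only
net, partner, tumbling = default_fig2_system(scenario=scenario)
contrib = cross_relaxation_contribution(net, partner, tumbling, scenario)
print(round(contrib.contribution_pct.max(), 3))   # -> 2.534  (% of R2)
```

2.5% of R2: at 3.0 Å the artifact stays inside a typical ±5% experimental
error band, so exchange-only models are safe.  At 2.5 Å the same call gives
7.6% — too large to ignore.

Fitting a triangular three-state model to synthetic dispersion data
generated at the WCF/HG/ES2 parameter set with 2% noise:

```python
from r1rho import (A2_WT_T9_TRIANGULAR, ExchangeModelSpec, compare_models,
                   fit_model, mc_parameter_errors, simulate_dispersion_dataset)

ds = simulate_dispersion_dataset("triangular", A2_WT_T9_TRIANGULAR,
                                 noise_pct=2.0, seed=7)
spec = ExchangeModelSpec("triangular", fixed={"r1": 2.5})
fit = fit_model(ds, spec, n_starts=20, seed=11)
fit = mc_parameter_errors(fit, ds, spec, n_replicas=50, seed=12)
print(f"kex(WCF-HG) = {fit.estimates['kex_ab']:.0f} +/- {fit.mc_sd['kex_ab']:.0f} s-1")
# -> kex(WCF-HG) = 3606 +/- 414 s-1      (truth 2700; within ~2.2 MC sd)
print(f"p_HG = {100*fit.estimates['p_b']:.2f}%  dw_HG = {fit.estimates['dw_b__sim']:.0f} Hz")
# -> p_HG = 0.66%  dw_HG = -572 Hz       (truth 0.60%, -593 Hz)

two_state = fit_model(ds, ExchangeModelSpec("two_state", fixed={"r1": 2.5}),
                      n_starts=8, seed=11)
print(compare_models([two_state, fit]).selected.topology)
# -> triangular   (F-test p = 8e-23, dBIC = 103, dAICc = 111)
```

The dispersion data demand the three-state model (χ² 244.6 → 52.0 for 4
extra parameters), and the recovered parameters bracket the generating
values within their Monte-Carlo uncertainties.

## Command line

```
r1rho simulate --scenario 1 --r 3.0 --out profile.csv   # artifact scan
r1rho make-fixtures --seed 7 --out-dir fx               # synthetic intensity tables
r1rho fit-decays --in fx/intensities.tsv --out rates.csv
r1rho fit-exchange --in rates.csv --topology two_state --out fit.json
r1rho select-model fit_a.json fit_b.json --out comparison.csv
```

Intensity tables are tab-separated text (power_hz, offset_hz, duration_s,
intensity, sino) with `#` comments; every artifact carries its seed and
configuration hash.

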