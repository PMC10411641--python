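# skinbis

**Which skin layer changed its conductivity?** Surface bioimpedance
spectroscopy (BIS) measures the complex impedance of skin over a frequency
sweep, but because the layers act as coupled parallel circuits, a bulk
impedance change does not reveal *where* the change happened. `skinbis`
implements a complete, simulation-driven classification pipeline that
answers that question for a four-layer skin model (stratum corneum S,
epidermis E, dermis D, fat F):

1. **Forward model** — a complete-electrode-model (CEM) finite-element
   solver on a layered domain: ∇·(σ\*∇φ) = 0 with Robin-coupled electrodes
   φ + z σ\*∂φ/∂n = U_l, per-electrode current constraints and contact
   impedance Z_c, for colinear bipolar and tetrapolar four-pad arrays.
   σ\* = σ + jωε₀εr is the per-layer complex admittivity.
2. **Frequency-pair selection** — the spectrum is deconvolved into a
   distribution of relaxation times, Z(f) = R∞ + ∫ γ(ln τ)/(1+j2πfτ) d ln τ,
   via Gaussian-RBF expansion and Tikhonov-regularized non-negative least
   squares; valleys of γ separate relaxation regions and rank the
   low/high measurement pairs (f_low, f_high).
3. **Ratiometric features** — Z′ = |Z_l|/|Z_h|, θ′ = arg Z_l − arg Z_h,
   R′ = Re Z_l/|Z_h|, X′ = Im Z_l/|Z_h|, each turned into a relative change
   α = (x_t − x_t0)/x_t0 against a standard-conductivity baseline. Common
   instrument gain and phase offsets cancel exactly.
4. **Classifier** — a one-hidden-layer ReLU network (100 neurons, 5
   outputs) trained per frequency pair, stratified 5-fold validated with
   Acc = 100·T_predict/T_samples, predicting the source indicator
   k ∈ {S, E, D, F, S+E} (combinations containing the dermis collapse onto
   the dermis class).

The training data are generated entirely in-package over a 10,200-case grid:
2 injection patterns × 3 electrode sizes (d_e = 1, 2, 3 mm, labelled by the
penetration-depth regime D/H) × 10 conductivity-changed layer combinations
ψ₁..ψ₁₀ × 17 change levels (−20 % .. +20 %) × 10 frequency pairs from
{2, 10, 35, 100, 225} kHz. It is intended for researchers prototyping
layer-resolved BIS analysis who need a transparent, testable reference
implementation rather than a black-box toolchain.

See [`docs/methods.md`](docs/methods.md) for the models, defaults and
limitations.

## Worked example

```python
import numpy as np
from skinbis import (default_skin_stack, apply_conductivity_change,
                     ElectrodeArray, InjectionPattern, sweep_spectrum,
                     fit_drt, find_relaxation_features, select_frequency_pairs)
from skinbis.features import derived_quantities, impedance_inputs

stack = default_skin_stack()                     # S/E/D/F, 8 mm total
array = ElectrodeArray(diameter=1e-3)            # d_e = 1 mm, d_g = 1 mm, Zc = 50 Ohm
pattern = InjectionPattern.bipolar()             # central pad pair, i = 1 mA

# 1. simulate a baseline spectrum and rank frequency pairs by DRT
freqs = np.logspace(3, np.log10(3e5), 25)
baseline = sweep_spectrum(stack, array, pattern, freqs)
drt = fit_drt(baseline)
pairs = select_frequency_pairs(find_relaxation_features(drt),
                               [2e3, 1e4, 3.5e4, 1e5, 2.25e5])
print(f"best pair: {pairs[0].f_low/1e3:g} & {pairs[0].f_high/1e3:g} kHz")

# 2. perturb the dermis conductivity by +20 % and extract the four inputs
perturbed = apply_conductivity_change(stack, "D", 20.0)
fl, fh = pairs[0].f_low, pairs[0].f_high
base = sweep_spectrum(stack, array, pattern, [fl, fh])
meas = sweep_spectrum(perturbed, array, pattern, [fl, fh])
fv = impedance_inputs(
    derived_quantities(meas.at(fl), meas.at(fh), (fl, fh)),
    derived_quantities(base.at(fl), base.at(fh), (fl, fh)))
print("alpha (|Z|, theta, R, X):", np.round(fv.as_array(), 4))
```

Output:

```
best pair: 2 & 225 kHz
alpha (|Z|, theta, R, X): [-0.0005  0.0033 -0.001   0.0019]
```

The best-ranked pair straddles the γ valleys separating the relaxation
processes of the layer stack, and the dermis perturbation leaves a distinct
four-component signature: the magnitude ratio drops (the tissue became more
conductive), while the phase-difference and reactance-ratio changes carry
the frequency-dependence that identifies *which* layer moved. Feeding such
vectors for all 10,200 grid cases to the per-pair classifier yields 5-fold
cross-validated accuracies of ≈ 93 % (bipolar) and ≈ 83 % (tetrapolar) at
the top-ranked pair (seed 1).

The same flow is available from the shell:

```bash
skinbis run-all --outdir out --seed 1        # full grid; ~3 min on one core
skinbis simulate-dataset --out dataset.csv
skinbis train --dataset dataset.csv --pair 2000,225000 --phi I \
              --kfold 5 --out model.json --report report.json
skinbis predict --model model.json --features dataset.csv --out pred.csv
```

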