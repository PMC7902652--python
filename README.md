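# sniffmodel

Fluid-mechanical models of sniffing — for biologists asking why mammals
sniff at the rates they do, and for designers of "electronic noses" choosing
how fast a bellows-driven sensor should sample.

Most mammals probe odors with a periodic inhale/exhale rather than a single
long inhale. This package implements, as a tested library plus a set of
analysis drivers, the quantitative models that rationalize that behavior:

- **Allometric scaling** (`sniffmodel.allometry`): the empirical law
  f = 8 M^−0.18 Hz relating maximum sniff frequency to body mass, log-log
  OLS fitting of new mass–frequency tables, and four mechanistic
  predictions — inertial f₁ = √(P r_t⁴/4ρV_sn V_tot), resonant
  f₂ = 1/2π√(CI), the laminar ceiling f₃ < νRe_max r_t/4V_sn, and the
  infinite-tube balance f₄ = √(P r_t/ρπV_tot) — plus transit and mucus
  limits.
- **Womersley flow** (`sniffmodel.womersley`): the closed-form oscillatory
  velocity field u(r,t) = Re{(G/iρω)[1 − J₀(i^{3/2}αr/R)/J₀(i^{3/2}α)]e^{iωt}}
  in a circular channel, with Wo = R√(πf/2ν) (α = 2Wo), validated against
  an independent Crank–Nicolson finite-difference solver.
- **Odor deposition** (`sniffmodel.deposition`): a quasi-steady model in
  which only the near-wall layer x_eff whose diffusion length √(2Dτ)
  exceeds its wall distance during the residence τ = d_s/|u| contributes to
  the signal; predicted sensor amplitude A = β·N_d; Henry's-law headspace
  concentrations; and the sniff-frequency trade-off (fast sniffs → more
  information per second, but per-cycle amplitude sinks into the noise
  floor).
- **Trace analysis** (`sniffmodel.trace`): baseline / response / per-cycle
  amplitude extraction from sensor-current time series and sniff-rate
  estimation from audio amplitude envelopes by windowed peak counting.
- **Synthetic data** (`sniffmodel.synthetic`): seeded generators with
  ground truth, so the entire pipeline is testable offline.
- **Pipeline & CLI** (`sniffmodel.pipeline`, `sniffmodel` command): YAML
  run configs, manifests, and end-to-end reproduction runs.

## Worked example

```python
from sniffmodel.allometry import LAWS, evaluate_law, f2_resonance
from sniffmodel.womersley import womersley_number
from sniffmodel.deposition import (DEVICE_CHANNEL, DEVICE_CALIBRATION,
                                   OdorSource, headspace_concentration,
                                   detected_layer)
from sniffmodel.womersley import AIR

# a 20-kg dog: sniff volume and the device operating point
print(evaluate_law(LAWS["sniff_volume"], 20.0))   # 41.73 (mL per sniff)
print(f2_resonance(1.0))                          # 14.25 (Hz at 1 kg)
print(womersley_number(0.01, 0.3, 1.48e-5))       # 1.784 (device at 0.3 Hz)

# ethanol headspace and the detected layer at the operating point
print(headspace_concentration(OdorSource()).parts_per_thousand)  # 88.96
layer = detected_layer(DEVICE_CHANNEL, AIR, DEVICE_CALIBRATION.protocol(0.3))
print(layer.x_eff)                                # 0.000856 (m)
```

The sniff volume (41.7 mL ≈ a shot glass) and resonance frequency (14 Hz at
1 kg, falling as M^−0.27) say a dog-sized animal should sniff at a few Hz —
matching observation. The device's Womersley number 1.8 at 0.3 Hz marks its
fastest feasible sniff for the weakest ethanol mixture: only the ~0.9 mm
near-wall air layer can diffuse onto the sensor within a transit, and
sniffing faster thins it until the per-cycle signal drops below the 0.03 mA
noise floor.

## Analysis drivers

Numbered scripts under `analysis/` regenerate the study's tables into
`results/` (each prints what it found):

```
python analysis/01_simulate_data.py       # synthetic animals, traces, envelopes
python analysis/02_fit_scaling.py         # empirical fit + f1..f4 + breathing curves
python analysis/03_flow_profiles.py       # closed form vs finite difference
python analysis/04_deposition_tradeoff.py # A vs Wo*C, N_d curves, optimal f
python analysis/05_trace_features.py      # closed-loop feature recovery
```

A `sniffmodel` CLI wraps the same library for one-off use, e.g.
`sniffmodel flow wo --radius 0.01 --freq 0.3` or
`sniffmodel trace analyze --input trace.csv --freq 0.3`.

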