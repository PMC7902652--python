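# Methods

`sniffmodel` implements a family of quantitative models of sniffing — the
periodic inhale/exhale mammals use to sample odors — and of a bellows-driven
"electronic nose" bench device that mimics it. This note records the models,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## 1. Allometric scaling of sniff frequency

Respiratory quantities follow power laws of body mass, q(M) = a·M^b. The
library ships the published laws used throughout (all masses in kg):

| quantity | law | units |
|---|---|---|
| max sniff frequency (empirical) | 8 M^−0.18 | Hz |
| sniff tidal volume V_sn | 2.15 M^0.99 | mL |
| lung volume | 53.5 M^1.06 | mL |
| vital capacity V_c | 56.7 M^1.03 | mL |
| functional residual capacity V_r | 24.1 M^1.13 | mL |
| trachea hydraulic radius r_t | 0.0023 M^0.4 | m |
| relaxed breathing | 0.89 M^−0.26 | Hz |
| respiratory compliance C | 1.59×10⁻⁵ M^1.04 | L/Pa |
| respiratory inertance I | 7.84 M^−1/2 | Pa L⁻¹ s⁻² |

The total respiratory volume V_tot = V_c + V_r is not itself a power law;
it is approximated by an OLS fit in log₁₀–log₁₀ space over 200 log-spaced
masses spanning 0.01–10 000 kg (the mammalian range). That fit gives
81.7 M^1.065 mL, which rounds to the conventional 83 M^1.06; the small
prefactor difference is inherent to fitting a two-term sum and the grid
choice, and the grid is configurable and recorded in output metadata.

Fitting (`fit_power_law`) is unweighted OLS on (log₁₀ M, log₁₀ q), the
standard allometry practice; R² is computed in log space and standard
errors are returned for inference. Weights are accepted but off by default.

Four mechanistic predictions of maximum sniff frequency:

- **f₁ (inertial)** — lung pressure P applied over the tracheal
  cross-section accelerates the whole respiratory air column sinusoidally:
  f₁ = √(P r_t⁴ / (4 ρ V_sn V_tot)). The driving-pressure convention is a
  parameter: `peak` uses P_max = 10 kPa (size-independent maximal lung
  pressure); the default `sinusoidal_mean` uses 2P_max/π, the mean magnitude
  of a sinusoidal waveform. The two conventions bracket 14.4–18.1 Hz at
  1 kg with slope −0.225; the conventional rounded statement of this model
  (17 M^−0.25) sits inside the bracket but cannot be reproduced exactly
  because the convention behind it is not recoverable, so tests assert the
  bracket and the exact slope rather than a single prefactor.
- **f₂ (resonance)** — natural frequency of the compliance–inertance
  oscillator, f₂ = 1/(2π√(C·I)) = 14.25 M^−0.27 Hz with the published C and
  I magnitudes (their product treated as s²).
- **f₃ (laminar ceiling)** — an upper bound, not a prediction: requiring
  the peak tracheal Reynolds number 2U_max r_t/ν to stay below the
  turbulence threshold 2000, with U_max ≈ 2f V_sn/r_t², gives
  f₃ < ν Re_max r_t/(4 V_sn) = 7.92 M^−0.59 Hz. The exact exponent is
  0.4 − 0.99 = −0.59 (often quoted rounded to −0.60).
- **f₄ (infinite-tube)** — balancing the high-Womersley oscillatory
  flow-rate amplitude Q ≈ 2P r³/(μ Wo²) against Q = f V_tot yields
  f₄ = √(P r_t/(ρ π V_tot)), slope −0.33. Direct substitution of the
  constituent laws gives ≈ 271 M^−0.33 at peak pressure; the literature
  value 470 M^−0.34 is not recoverable from the printed constituents, so
  tests assert only the closed form, the slope, and monotonicity.

Two side limits: the **transit limit** (a sniff must reach the sensory
region: inhale ≥ L/U, so f ≤ U/2L; 25 Hz for a dog with L = 0.1 m,
U = 5 m/s) and the **mucus limit** (diffusion through a 10 μm mucus layer
with D = 6.5–8.2×10⁻¹⁰ m²/s takes x²/2D = 0.06–0.08 s).

## 2. Oscillatory channel flow

Sinusoidally driven laminar flow in a rigid circular channel is governed by
the Womersley number. Two conventions coexist deliberately:

- `womersley_number(R, f, ν) = R √(πf/2ν)` with **R the channel radius
  (half the hydraulic diameter)** — the convention in which the device
  operating points are quoted (0.3 Hz in the 1 cm channel → Wo = 1.78 ≈ 1.8);
- the classical Bessel-solution parameter α = R√(ω/ν) = 2·Wo.

The closed form is u(r,t) = Re{(G/(iρω))[1 − J₀(i^{3/2}αr/R)/J₀(i^{3/2}α)]
e^{iωt}} for momentum forcing (G/ρ)cos ωt, G the axial pressure-gradient
amplitude (protocol pressure amplitude divided by channel length). A
velocity-driven protocol back-solves G so the cross-section-mean velocity
amplitude equals the requested U_max. i^{3/2} uses the principal branch;
for |i^{3/2}α| > 600 the solver switches to the Stokes boundary-layer
asymptote 1 − e^{−(1+i)α(1−r/R)/√2} (flagged in metadata) to avoid Bessel
overflow. Square device channels are mapped to the circle of equal
hydraulic diameter before solving.

An independent finite-difference oracle (`numeric_oscillatory_solver`)
integrates the same equation by Crank–Nicolson on a uniform radial grid
(symmetry at r = 0 via the regularized Laplacian, Dirichlet no-slip at R),
from rest until two successive periods agree to 10⁻⁸ relative L2 (max 50
periods, error on non-convergence). Closed form and oracle agree to
≲ 0.01% relative L2 at α ∈ {1, 3, 7.14, 15} (Wo 0.5–7.5) on a 201 × 256
grid — far inside the 1% the validation demands. The oracle also confirms
the wall phase lead: near the wall the flow reverses before the centerline
for α ≥ 2, the signature feature of Womersley flow.

The Eq.-style flow-rate scale Q ≈ 2P r³/(μ Wo²) used by f₄ is an
order-of-magnitude relation: it equals the exact plug-flow limit
πR²G/(ρω) only when P is interpreted as the pressure drop over an
effective length πR/8, so with the full channel-length drop the ratio to
the integrated closed-form flow rate is 8L/(πR) (≈ 76 for the device),
with a further ~√2/Wo Stokes-layer correction. This quality note is the
reason f₄ is treated as a scaling, not a quantitative prediction.

## 3. Quasi-steady diffusive deposition

Odor reaches the wall-mounted metal-oxide sensor only by diffusing across
streamlines while it is advected past the sensor; the concentration field
itself is steady (no Taylor–Aris dispersion, no mucus layer, sensor-level
concentration equal to the headspace value — a documented upper-bias).
The regime requires Schmidt number Sc = ν/D < 4; ethanol in air has
Sc = 1.35.

Headspace concentration follows Henry's law: the pure-liquid mole fraction
is C = ρ_e/(u H P_atm) (ethanol: 789/(0.04607·1.9·101325) = 0.089 → 89
parts per thousand), scaled by liquid volume fraction for dilutions; the
number density follows from the ideal gas law at 298.15 K.

The sniff cycle is discretized into n_time = 64 uniform phases (below 64
the cycle average acquires percent-level wiggles from sampling the
near-reversal phases, and monotonicity in f can break on fine grids). At
phase t, air at wall distance y moves at the local speed |u(y,t)| from the
closed-form field and spends τ = d_s/|u(y,t)| over the sensor of width
d_s, capped at half a period because flow reversal sweeps the layer away.
The capture depth is the largest y with y ≤ √(2D·min(τ, 1/2f)), found by
bisection (the bound is monotone near the wall); the detected-layer
thickness x_eff is the cycle average, capped at R. Degenerate inputs: D = 0
gives x_eff = 0; an unforced (stagnant) protocol gives the half-period
depth √(D/f) with a warning.

**Velocity calibration.** The device's stroke amplitude is a calibration,
not a prediction: u_max = 0.9 m/s at the 0.3 Hz reference point, the value
at which the first-order capture estimate √(2D d_s/U) reproduces the
measured 0.35 mm detected layer. The self-consistent local-speed model
gives a thicker layer (~0.87 mm) at the same point because the air actually
sampled sits inside the slow near-wall region — matching the measured
0.35 mm with the self-consistent model would demand U_max ≈ 13 m/s
(Re ≈ 1.8×10⁴, turbulent, ~14 L stroke), which is physically inconsistent
with the device, so the calibration anchors the simple estimate instead and
the self-consistent layer is reported as-is. Because the stepper holds the
stroke volume constant, U_max scales linearly with f across sweeps
(U(f) = 0.9·f/0.3 m/s).

Molecules available per sniff are N_d = n·x_eff·d_s² (number density times
the wall shell over the square sensor footprint; a full wall-annulus
geometry is available as an option), and per second N_d·f (the per-second
convention is recorded as a flag; published per-sniff and per-second counts
are not mutually consistent under any single convention, so neither is
asserted). The predicted current amplitude is A = β·N_d with a single
sensor gain β fitted by least squares through the origin jointly across all
concentrations, or calibrated so the lowest concentration (8.9 ppt) meets
the 0.03 mA noise floor at 0.3 Hz — which reproduces the device's measured
operating limit: fastest feasible sniff 0.3 Hz at Wo ≈ 1.8.

The trade-off: per-sniff N_d decreases with Wo (thinner layer), per-second
N_d increases (more sniffs); `optimal_frequency` classifies each grid
frequency as `slow-sniff` (Wo·C < 0.01, the signal returns to baseline each
cycle so sniffing adds nothing), `below-noise` (A < 0.03 mA) or
`operational`, and returns the largest operational frequency. An empty
operational set is reported, not raised.

## 4. Sensor traces and audio envelopes

`extract_features` reduces a current trace to baseline (median of the
pre-odor segment — median, not mean, because the device only measures
positive current so the noise is asymmetric), response magnitude (median of
the settled second half of the odor window minus baseline), and per-cycle
oscillation amplitude. Cycles are detrended with a running median of window
1/f; the amplitude within each complete cycle is measured by quadrature
projection onto the sniff frequency. For the sinusoidal ripple this equals
half the peak-to-trough excursion (the natural reading of an oscillation
amplitude "A") while remaining unbiased under noise, where a raw
peak-to-trough inflates by ~2 noise extremes per cycle. Cycles whose trend
moves more than the oscillation itself are excluded: a running median
reproduces monotone segments exactly, so the rise after odor onset and the
decay at window end would otherwise contribute near-zero amplitudes.
Multi-sniff averaging to beat noise is deliberately not performed (the
clipped, non-zero-mean noise makes it invalid) and exists only as the
per-cycle list the caller may aggregate.

Onset detection returns the first linear-interpolated crossing of
baseline + fraction × response; for a first-order sensor rise with time
constant τ_s and fraction ½ this is t_on + τ_s ln 2, which the tests verify
against the closed form.

Audio-envelope sniff rates are estimated exactly as a manual analysis
would: count prominent peaks per sliding 1-s window, report the maximum
count. The envelope is first smoothed with a 25 ms moving average (short
enough to preserve rates up to rate/10) and the prominence threshold is
5× the noise sd estimated from the raw median absolute first difference,
scaled by the smoothing gain √w. These two constants were set by a
simulation study against the generator: noiseless pulse trains are
recovered exactly at any rate ≤ rate/10, and at SNR 3 the estimate is
within ±1 Hz in ≥ 95/100 seeds at 8 Hz (rat-like) and ≥ 90/100 at 2 Hz
(elephant/giraffe-like).

## 5. Synthetic data

Generators are pure functions of their spec (seed included) and return
their ground truth, so every analysis stage is tested closed-loop. The
trace generator emulates the device recordings: 10 mA baseline, first-order
rise (default time constant 5 s — the sensor's gradual return to baseline
is real but its dynamics are not published, so first-order lag is the
minimal model) toward +10 mA inside odor windows, sinusoidal ripple of
half-range `cycle_amplitude` while odor is present, and zero-mean Gaussian
noise with the total clipped at zero (default; a shifted log-normal
alternative models heavier positive tails). The allometry generator draws
masses log-uniform over 0.02–3400 kg (shrew to elephant) and applies
log-normal scatter σ = 0.11 in log₁₀, calibrated once by simulation so
n = 16 fits give R² ≈ 0.85 on average — the structure of the observed
mammal table. The envelope generator emits raised-cosine pulse trains
(cos⁴ bumps) plus white noise at the stated peak/σ SNR.

What the generators do **not** emulate: real audio spectra, sensor drift,
humidity/temperature crosstalk, multi-odor mixtures, or the 16-element
sensor array. Passing closed-loop tests therefore demonstrates estimator
correctness under the stated statistical structure, not robustness to
every artifact of real recordings.

## 6. Numerical choices and problem sizes

- Flow oracle: 201 radial points, 256 steps/period, period-to-period
  tolerance 10⁻⁸, ≤ 50 periods (typically ≤ 10).
- Capture-depth bisection: 60 iterations on [0, R] (resolution ~R·2⁻⁶⁰).
- Deposition sweeps: n_time = 64 phases; 32 is used in coarse shape tests
  where only monotonicity across well-separated Wo values matters.
- Replicate counts in statistical tests (200 fits for estimator bias, 100
  seeds for amplitude/envelope recovery) were chosen to keep Monte-Carlo
  error well below the asserted margins while the full suite stays in a
  few seconds.
- All internal computation is SI; published-law units (mL, L/Pa) convert at
  the boundary.

## 7. Known limitations

- The deposition model is quasi-steady and single-chemical; mixtures, mucus
  sorption, odorant partitioning and entrance-length development are out of
  scope.
- The detected layer's absolute thickness depends on the velocity
  calibration (§3); shapes and orderings (vs Wo, vs C) are
  calibration-independent and are what the tests pin down.
- f₁ and f₄ prefactors are convention-dependent (§1); the package exposes
  the conventions as parameters instead of picking silently.
- Womersley numbers quoted for the device ladder (1.25/1.5/1.65/1.8) sit
  ~2% above the recomputation at ν = 1.48×10⁻⁵; the exact ν or D_h behind
  them is not stated, so tests allow 3%.
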