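# Methods

## The measurement model

Dynamic instrumented palpation applies a force-controlled sinusoid about a
mean contact force and records the indentation of a membrane into the
tissue as a negative-going strain. For a linear viscoelastic half-space
probed by a rigid sphere, the package models each actuation block as

* force: `F(t) = F̄ + F̂·sin(2πft)`;
* strain: `ε(t) = −k_f·[d₀ + d̂·sin(2πft − δ)]`, where `d₀` is the mean
  indentation depth, `d̂` the oscillation amplitude and `δ` the phase lag.

The mean depth solves the Hertz relation
`F̄ = (4/3)·[E_static/(1−ν²)]·√R·d₀^{3/2}`; the oscillation is governed by
the *tangent* contact stiffness evaluated at `d₀` with the complex modulus
magnitude `|E*(f)|` in place of `E_static`, and delayed by the constitutive
phase `δ = arctan(E″/E′)`. The constitutive law is Kelvin–Voigt
(`E′ = E_static`, `E″ = 2πf·η`) by default; a standard linear solid is
available for model-misspecification studies.

Feature extraction inverts exactly this model. One subtlety deserves note:
the mean ratio `MR = F̄/d₀` is a *secant* stiffness, while the modulus
inversion uses the tangent slope `dF/dd = 2·[E/(1−ν²)]·√(R·d)`. For a
Hertzian `F ∝ d^{3/2}` the two differ by exactly 3/2, so extraction
multiplies MR by `SECANT_TO_TANGENT = 1.5` before inverting; the amplitude
ratio is already a tangent-type slope and is inverted directly. With this
convention the noise-free round trip (simulate → extract) is exact to
round-off, which the tests exploit.

Time lags of a passive linear model satisfy `Δt < 1/(4f)` (phase below
π/2) and, for Kelvin–Voigt, decrease strictly with frequency — both are
enforced and property-tested. Published in vivo/ex vivo datasets of this
kind contain some lag values *above* the quarter-period bound (e.g. ex vivo
lags of ~0.42 s at 1 Hz); these cannot arise from any passive linear model
and are not reproduced here. The generator caps drawn lags at 95% of the
quarter period, which affects only the upper tail of the widest (1 Hz, NC)
lag distribution.

## Signal conditioning

Raw strain contains an application transient at each block start and a slow
global drift. Conditioning per block: discard the first period, subtract a
centred moving average whose window is 3 periods of the block frequency
(restarted at each block boundary, so it tracks both the per-block settle
and the global trend), trim half a window at each edge, truncate to an
integer number of periods, then estimate mean, amplitude and phase of the
fundamental by direct projection onto sin/cos at the actuation frequency
(lock-in). On integer periods this estimator coincides exactly with the
corresponding FFT bin. The moving-average subtraction attenuates the
fundamental by a known Dirichlet-kernel factor
`sin(πfW/fs)/(W·sin(πf/fs))`; the strain amplitude is divided by
`1 − gain`, making the noise-free estimate exact rather than ~0.2% biased.
The mean strain is taken from the raw (undetrended) signal, since the trend
*is* the operating mean; residual drift bias on the extracted static
modulus with default drift settings is below 1%.

The phase difference is wrapped to [0, 2π). Estimates within 0.01 rad
below 2π are clamped to zero (a near-zero lag perturbed by noise), while
anything else above π is flagged and the block excluded with a logged
reason — as are blocks with fewer than 3 whole periods or a non-negative
mean strain (loss of contact). This mirrors the practical situation in
which low-frequency dynamic measurements are sometimes unusable.

## The synthetic cohort and its calibration

The default cohort emulates a 12-patient in vivo study: 4 patients measured
at 1 Hz and 8 at 5 Hz, 12–16 points each over a 3×4 zone grid, every point
probed at light (0.5 N) and firm (1.5 N) mean force, 20 s per recording at
1000 Hz. Each zone independently contains a lesion with probability 0.6,
and a point is labelled C iff its zone is lesioned (points revisiting a
zone share its label); this yields ≈165 points with ≈3:2 C:NC balance.
The light/firm force magnitudes are not reported for hand-held examinations
and are configurable placeholders; what matters downstream is the
mild strain-hardening law `E_apparent = E_base·(1 + β·F̄)` with
`β = 0.0541 N⁻¹`, chosen so the firm/light apparent-modulus ratio is ≈1.053,
matching the observed ordering of pooled medians (≈25.2/26.8 light/firm).

Ground-truth parameters come from class-conditional lognormal distributions
(lognormal guarantees positivity; published tables give only medians and
IQRs, so the log-scale spread is set from
`σ = asinh(IQR/2·median)/z₀.₇₅`). The calibration targets of the default
`in_vivo` profile are:

| quantity | C | NC |
|---|---|---|
| `E_static` firm (kPa), all frequencies | 26.8 (13.3) | 24.8 (11.9) |
| `E_dynamic` firm, 5 Hz (kPa) | 5.15 (4.86) | 4.61 (3.08) |
| `E_dynamic` light, 5 Hz (kPa) | 3.12 (3.97) | 2.81 (3.42) |
| `Δt` firm, 5 Hz (s) | 0.0175 (0.0078) | 0.0186 (0.0397) |
| `Δt` light, 5 Hz (s) | 0.0178 (0.0048) | 0.0173 (0.0062) |
| `Δt` firm, 1 Hz (s) | 0.0281 (0.0500) | 0.0422 (0.4549) |
| `Δt` light, 1 Hz (s) | 0.0204 (0.0261) | 0.0261 (0.2514) |

(median (IQR); the static modulus targets are pooled across frequency
groups, so the per-frequency subgroup medians are not separately pinned.)

**Spread matching.** With `spread_matching=True` (default) each stratum —
class for the static modulus; (class, frequency group) for lag and dynamic
modulus — receives the *quantiles* of its target distribution at ranks
`(i+0.5)/m` in a seed-determined random permutation, rather than i.i.d.
draws. The cohort's empirical class medians and IQRs then match the
calibration targets for every seed, so the round-trip acceptance checks
measure pipeline fidelity, not sampling luck. Each point keeps one latent
rank per quantity shared across pressure levels, preserving light/firm
correlation. Requesting a zero-IQR target with spread matching on is
reported as an error (use `spread_matching=False` for degenerate classes).

**Operator accommodation.** Hand-held dynamic stiffness readings are far
below the constitutive `|E*|` implied by the static modulus and phase lag
(≈5 kPa observed vs ≈30 kPa implied), because the operator's hand complies
with the imposed vibration. A single global attenuation factor cannot
simultaneously reproduce the C and NC dynamic-modulus medians (the
Kelvin–Voigt-implied C/NC ratio is ≈1.02 but the observed ratio is ≈1.12),
so the profile carries an explicit class-conditional distribution of the
*effective* dynamic modulus; the per-point accommodation factor is the
ratio of effective to constitutive dynamic modulus, and varies across
points as real operator behaviour does. With `accommodation=False` the
simulator reverts to the pure constitutive response. The phase is left
untouched by accommodation — lag targets are matched through `η` directly,
`η = E_static·tan(2πf·Δt)/(2πf)` at the point's actuation frequency.

**Drift and noise defaults.** Per-block settle: amplitude 10% of the mean
strain, time constant 0.3 s — fast enough that the discarded first period
plus averaging leaves <0.1% mean bias. Global linear drift:
5×10⁻⁴ of the mean strain per second. White noise at 40 dB (force) and
30 dB (strain) SNR relative to the oscillation amplitude. The strain
oscillation is saturated at 90% of the mean strain so contact is never
spuriously lost; this touches only the most compliant light-pressure tail
points and leaves class medians unchanged. Real recordings additionally
contain harmonic distortion, operator repositioning, and spatially
correlated tissue structure, none of which are modelled — passing
round-trip tests therefore demonstrate correctness of the analysis chain
under the stated model, not robustness to every clinical artefact.

## Classification protocol

One vector per point: `E_static`, `E_dynamic`, `PD`, `Δt` at firm and light
pressure (8 features), each point at its own actuation frequency (the
frequency-agnostic union; patients measured at different frequencies are
thus pooled into one feature space). Points missing a pressure level are
excluded in strict mode (default) or median-imputed. Standardisation
statistics are computed on the training fold only.

The network is a single hidden layer of 10 logistic units with a softmax
output (for two classes, equivalent to a logistic output), trained by a
full-batch first-order method (Adam) one epoch at a time with early
stopping on validation cross-entropy (patience 25, max 400 epochs) and
restoration of the best weights. The historical reference for this protocol
used scaled conjugate gradients; the contract here is the architecture and
the split protocol, not the optimiser trajectory. Ten repeats of
stratified random 70/15/15 splits are run (stratification keeps both
classes in every fold at n≈165); the headline report is the pooled
test-fold confusion matrix, with per-repeat and pooled all-data matrices
retained because published indicator tables of this kind are ambiguous
about which matrix they summarise.

## Numerical and design notes

* Quartiles are inclusive linear-interpolation ("type 7", spreadsheet
  QUARTILE) — the convention behind the reference summary tables.
* Hertz geometry defaults: R = 5 mm, ν = 0.5 (incompressible), calibration
  factor `k_f = 0.1 mm⁻¹` (strain of −0.1 per mm of indentation). The
  mean-force/modulus combinations put operating depths at 2–7 mm,
  comparable to the 3–8 mm pre-strains of bench-top studies; the point-probe
  Hertz idealisation is used well outside its small-strain regime, as is
  conventional for calibrated palpation probes, and the calibration factor
  absorbs the difference in practice.
* Lock-in preconditions: ≥3 whole periods per analysed block, sampling rate
  >2× (extraction) and ≥20× (simulation protocol) the actuation frequency.
* Determinism: every random draw descends from the cohort seed
  (per-recording streams are derived from (seed, point index, pressure)),
  and the classifier seeds sklearn from its own config seed, so the full
  pipeline is bit-reproducible.
* Problem sizes in the test suite (cohort of ~165 points × 2 pressures,
  200-replicate noise studies, 10-repeat training) are chosen to exercise
  the full study conditions while keeping a complete run in the
  one-minute range.

## Known limitations

* The per-point accommodation factor is a calibration device, not a
  biomechanical model of the operator's hand; it is frequency-flat within
  a recording.
* No poroelastic/biphasic modelling of the long-time drift; the drift is
  treated purely as a nuisance to be removed, not as a feature.
* Lesions are reduced to a per-zone binary overlap — no 3-D geometry,
  severity grades, or spatial correlation between adjacent zones.
* The 1 Hz frequency group reuses the 5 Hz effective-dynamic-modulus
  targets (no low-frequency dynamic calibration data exist, as those
  measurements were largely unusable in practice).
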