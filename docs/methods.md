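# Methods

This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not establish.

## Trajectory metrics

Input is a long-format table of tracked positions (cell, frame, x, y) at a
fixed imaging interval (default 5 min/frame). All metrics treat the field
axis as a configurable unit vector, default (+1, 0); whether "+x" means
anode or cathode is metadata about the chamber wiring, not something the
mathematics can decide, so the sign convention is a configuration choice.

- **Migration speed** — total distance over steps between *consecutive
  observed frames*, divided by the elapsed minutes of those steps. Steps
  across gaps in a track contribute nothing. Tracks with fewer than two
  frames have undefined speed (NaN).
- **Instantaneous directedness** — cosine between the displacement over a
  forward lag (default 6 frames = 30 min) and the field axis. The value at
  frame i requires frame i+lag to exist exactly; no padding or partial
  lags. Zero displacement gives NaN, never 0 — coercing to 0 would
  inflate the recruitment index's neutral band.
- **Displacement directedness** — same cosine measured from the cell's
  first tracked position; the classical metric, useful when cells do not
  reverse polarity.
- **Recruitment index** — RI = (C_A − C_C)/C_T × 100 with a neutral band
  |d| ≤ 0.01; C_T counts every defined value including the band.
- **Immobile-cell filter** — removes cells whose speed is strictly below
  the 25th percentile (numpy linear-interpolation convention) of the
  per-cell speed distribution. Cells whose speed is undefined are
  retained: a strict comparison cannot classify them.

Undefined values propagate as NaN and are excluded from per-frame
aggregates; per-frame cell counts are reported so downstream statistics
can weight accordingly.

## The stochastic plant

Each simulated cell, at model step t under field EF (V/cm), draws

    d(t) = clamp( onset(t) · [ noise + (ν/s)·bias(EF) ] ),   clamp to [−1, 1]
    onset(t) = 1 / (1 + e^{−(t−τ)})
    noise    = 2u − 1,  u ~ Uniform(0, 1), fresh per cell per step
    bias(EF) = EF/s + sign(EF) · s · |EF|^p / (|EF|^p + 1),  p = 1/|EF| (1 at 0)

with s = 3, τ = 4, direction flag ν = +1 by default. The onset factor
models the delayed cellular response after field exposure; the bias term
grows linearly at small fields and saturates as |EF| grows; the clamp
keeps samples in the physical range. The population observable is the
mean directedness (or the RI) of n_cells = 100 fresh samples per step.

**Composition options.** The published equation's typesetting collapses
fractions, leaving the placement of s ambiguous. `PlantParams.composition`
selects among three defensible readings:

| name              | sample before clamping                          |
|-------------------|-------------------------------------------------|
| `prefactor_s`     | onset · ν·s · [noise + bias]                    |
| `prefactor_inv_s` | onset · (ν/s) · [noise + bias]                  |
| `bias_inv_s`      | onset · [noise + (ν/s)·bias]   (preset default) |

The shipped presets use `bias_inv_s` because it is the only reading that
reproduces both qualitative regimes the closed-loop experiments are built
on: a ±0.65 directedness target is attainable below the ±4 V/cm actuator
bound (steady-state mean ≈ 0.65 at ≈ 2.1 V/cm), while ±0.9 is unattainable
(mean ≈ 0.77 at the 4 V/cm bound), which is what drives the controller
into sustained saturation. Under `prefactor_s` the mean reaches 1.0 by
≈ 0.75 V/cm and no saturation can ever occur; under `prefactor_inv_s` the
±0.9 target is marginally attainable and saturation is transient. It is
also the composition in which the direction flag ν scales only the
field-induced bias — random motility has no preferred direction. The
`prefactor_s` reading remains the constructor default so the elementary
operations match the equation read literally.

**Time and randomness.** Model time is the dimensionless step index since
field onset; the closed loop maps one control sample to one plant step,
and the onset clock runs from the start of the run (it does not restart
when the field changes sign; configurable). Cells draw independent noise
with no within-cell autocorrelation. Per-cell streams are spawned from a
single seed sequence, so enlarging the population never reshuffles
existing cells' draws, and identical seeds give bit-identical ensembles.

**Calibration.** `calibrate` grid-searches (s, τ) by summed squared error
between simulated and observed mean-response series, with the simulation
seed matched across grid points (noise-paired comparison). A zero-field
series carries no information about s under `bias_inv_s`; ties break by
grid order.

## The controller

A Gaussian RBF network u(z) = Σᵢ WᵢΦᵢ, Φᵢ = exp(−‖z−cᵢ‖²/βᵢ²), with
centers cᵢ = lᵢ·(1,…,1) on an arithmetic grid (in-silico: l from 0 to 2
step 0.01, M = 201, N = 6; recruitment-index preset: −5 to 5 step 0.1,
M = 101), a single shared width β = 1, and weights initialised as
independent uniform draws on [0, 10⁻⁴] (10⁻⁵ in the RI preset).

**Update laws.** Standard: Wᵢ ← Wᵢ + γeΦᵢ (γ = 5·10⁻⁴, Ts = 1 s).
Projected, branching on the *unsaturated* command u_raw = WᵀΦ:

    u_raw > UL:  W ← W + γₐΦe − sign(e)·αₐ·W·(WᵀΦ)/‖W‖·e
    u_raw < LL:  W ← W + γᵦΦe + sign(e)·αᵦ·W·(WᵀΦ)/‖W‖·e
    otherwise:   the standard update

Branching on the clipped command would make the saturated branches
unreachable. The projection term is implemented in its literal vector
form; the "simplified" scalar form (γₐ − sign(e)·αₐ‖W‖ factor) holds only
when W is parallel to Φ and is not used. A per-coordinate variant
(Wᵢ²Φᵢ/|Wᵢ|) is available behind `UpdateConfig.projection="per_weight"`.
sign(0) = 0, so a zero error never applies a projection push. A saturated
branch with ‖W‖ = 0 is impossible (u_raw would be 0, inside any bound
pair straddling zero); non-finite weights raise immediately.

With αₐ = αᵦ = 0 and γₐ = γᵦ = γ the projected law is algebraically
identical to the standard law — this is property-tested to 10⁻¹².

**Regressor.** z(n) = [r(n), y(n−1), …, y(n−5)] (in-silico) or the
interleaved [r(n), y(n−1), r(n−1), y(n−2), r(n−2), y(n−3)] (RI preset),
with zero padding for lags that do not exist yet, then mapped affinely
onto the center span: scale·z + offset. The in-silico presets use offset
+1, because the center grid spans [0, 2] while directedness spans
[−1, 1]: without the shift every activation underflows (Φ ~ e⁻⁵) the
moment the reference or output goes negative, the printed learning rate
cannot move the output, and two-sided tracking is numerically impossible.
The RI preset divides its percent-scale signals by 150, placing them
inside its ±5 grid for the same reason. These affine maps are the
package's reconstruction of the input normalisation the published
architecture requires but does not state.

**PID baseline.** Positional form u = kp·e + ki·I + kd·Δe/Ts with the
integral accumulated as I ← I + e·Ts and no clamping by default — the
windup-prone baseline the adaptive law is compared against. The baseline's
gains for the RI-tracking preset are documented placeholders (kp = 8·10⁻⁶,
ki = 10⁻⁹, kd = 0 mapping percent-scale error to amperes): no gains were
published, so the preset aims only for the qualitative behavior (tracks
the first setpoint, winds up on the reversal) and all gains are
config-exposed.

## The closed loop

Per step: assemble z from the current reference and the output history →
u_raw → clip to [LL, UL] → apply as field (or convert a current command
via EF = I/(A·σ)) → one plant step over all cells → observable y → error
e = r − y → weight (or PID) update. The run log records r, y, u_raw,
u_sat, e, and ‖W‖ at every step; any NaN aborts with the step index.
A run is fully determined by its seed: the plant noise and the weight
initialisation use independent streams derived from it.

Defaults: horizon 3600 steps (Ts = 1 s) with the reference switching sign
at step 1800 — chosen so the observed multi-minute post-switch recovery
fits comfortably within each phase. The in-silico observable is the mean
directedness; RI mode exists for the in-vitro-shaped presets, whose
chamber constants (cross-section 0.025 cm², conductivity 0.0095 S/cm) are
synthetic stand-ins making the ±0.95 mA current bound correspond to the
±4 V/cm field bound.

### Evaluation metrics

- MSE = mean(e²), RMSE = √MSE, MAPE = 100·mean(|e/r|) over steps with
  |r| > 10⁻⁹.
- Normalized variants: nMSE = Σe²/Σr², nRMSE = √nMSE, and nMAPE =
  MAPE/100, i.e. each metric is 1 exactly for a controller that never
  moves the plant (y ≡ 0). No definition of the normalization was
  published; this family was chosen for that fixed-point property, and a
  published PID nMSE ≈ 1 on a reversal it failed to track is consistent
  with it. (The corresponding published nMAPE figures appear to be on the
  raw percent scale instead.)
- Fall time: after the reference's high→low switch, the minutes the
  output takes to descend between 90% and 10% of the span from its
  pre-switch plateau to its own post-switch floor (each plateau estimated
  as the mean over the trailing 10% of its phase). Measuring to the
  output's own floor rather than to the reference target keeps the metric
  defined precisely in the saturated experiments, where the target is
  unattainable by design. A one-sample drop reports one sampling period;
  an output that never reaches the 10% level reports NaN.
- Improvement% = (old − new)/old × 100 for every ordered run pair.

## Synthetic data

`generate_tracks` emulates tracked-cell tables: mobile cells take steps
whose headings are +x (or −x for negative bias) with probability |b| and
uniform on the circle otherwise, so the expected per-step directedness is
exactly b — fixtures are analytically checkable. Step lengths are
Gamma-distributed with chosen mean (3 px) and dispersion (1 px) per 5-min
frame, roughly the displacement scale of cultured macrophages at this
frame rate; immobile cells jitter within ±0.01 px. The generator does not
model persistence, cell–cell interaction, drift, or track fragmentation,
so a green metrics test establishes correctness of the computation, not
robustness to those artefacts. `generate_reference` produces the
piecewise-constant (square or hold) targets the presets use.

## What the in-silico experiments establish

With the preset plant, a seed battery (10 seeds) reproduces the published
in-silico comparison within its stochastic tolerance: the non-saturating
example yields bit-identical runs under both laws (improvement exactly 0);
under saturation the projected law beats the standard law's MSE and fall
time in every seed, with mean MSE ≈ 0.17 (standard) vs ≈ 0.08 (projected)
and fall times ≈ 6.1 vs ≈ 2.9 min. The exact published magnitudes depend
on the realized noise, the unpublished horizon, and the reference
waveform of the first example, none of which are recoverable; the
package's reconstruction (square wave, midpoint switch, 3600 steps) is
documented above. The projected law's faster-than-published recovery is
reported as measured.

## Known limitations

- No spatial positions, cell–cell interactions, polarization/phenotype
  dynamics, or multi-axis fields in the plant; noise is white per cell.
- The plant-equation composition and the regressor normalisation are
  reconstructions of ambiguous source material (see above); all alternates
  remain selectable in configuration.
- The in-vitro presets are exercised against the simulated plant only; no
  hardware interfaces are included.
- MAPE is undefined on references that are identically zero, and fall
  time assumes a single high→low reference transition.
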