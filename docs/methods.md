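# Methods

This note documents the models behind `reactoscope`, the parameter choices
that matter, what the synthetic data do and do not emulate, and the
numerical decisions made where the design was genuinely open.

## Gene expression model

Both estimation and control are built on a one-stage birth–death model of
light-driven expression with a deterministic input delay:

- production propensity `b0 + k·u(t − τ)`,
- degradation propensity `γ·n`,

with `u(t) ∈ {0, 1}` the binary light activation of the 6-min interval
containing `t`. A 1000 ms pulse within an interval is mapped to full
activation (`u = 1`) for that interval: the photo-switching kinetics of
EL222-class transcription factors are fast relative to the imaging cadence,
so sub-interval pulse timing is not resolved. The delay `τ` (default
36 min) lumps transcription, translation and — dominantly — fluorophore
maturation into a pure input delay.

The deterministic ("average cell") variant is the ODE
`dP/dt = b0 + k·u(t − τ) − γ·P`, integrated exactly per interval (the input
is piecewise constant, so each step uses the closed-form exponential
solution; there is no integration error beyond floating point). The
stochastic ("single cell") variant is simulated exactly by the Gillespie
algorithm within each constant-propensity segment. Under constant input the
chain's stationary law is Poisson with mean `(b0 + k·u)/γ`, which the test
suite uses as an analytic oracle.

Parameters and defaults:

| parameter | meaning | unit | default |
|---|---|---|---|
| `k` | maximal light-induced production | molecules/min | scenario-specific |
| `b0` | basal (dark) production | molecules/min | scenario-specific |
| `γ` | degradation + dilution | 1/min | ln 2 / 90 |
| `τ` | maturation delay | min | 36 |
| `α` | fluorescence per molecule | a.u./molecule | 1–40 |
| `σ_meas` | measurement noise SD | a.u. | scenario-specific |

`γ` is interpreted as degradation **plus dilution**, with its default tied
to a 90-min generation time; with a stable fluorescent protein, dilution by
growth dominates turnover. The model deliberately has no explicit mRNA
stage; a single stage with a delay reproduces every input–output behavior
the filters and controllers rely on (step responses, delayed
cross-correlation, Poisson stationarity).

## Virtual microscope

Cells are filled ellipses. The camera model is linear: the expected pixel
value inside a cell is `background + gain · exposure_ms · signal`, where the
signal is the channel-relevant molecular state (expression reporter on
"GFP", membrane dye on "RFP", recombination reporter on "CFP"). Optional
Poisson shot noise (mean = expected intensity) and additive Gaussian read
noise complete a standard camera model. Brightfield renders dark cell
interiors (35 % of background at the center, rising to 70 % at the rim) on a
bright background, so threshold segmentation is well posed by construction.

DMD stimulation: the boolean mask is blurred with a Gaussian of `σ = 2 px`
to model illumination bleed-through, and a cell's dose is
`duration_ms · intensity · ⟨field⟩` over its **ground-truth** footprint
(physics acts on the true cell, not on the segmented mask). The Gaussian
form is a generic stand-in for bleed-through, not a claim about any
particular optical train; its single parameter is configurable.

The membrane-dye scenario uses a global exponential dye decay with a
half-life of 180 min, the timescale on which lipophilic stains visibly fade
over multi-hour acquisitions.

## Image analysis

Segmentation: Gaussian pre-smoothing (σ = 1.5 px) to suppress shot-noise
speckle, Otsu threshold on the inverted brightfield, hole filling, and a
minimum-area filter. This is adequate for the synthetic scenes at the
densities the scenarios use; it is not a general cell segmenter. Per-cell
fluorescence is the mean pixel intensity over the cell mask. SNR is the
mean intracellular intensity divided by the mean background intensity,
background being the complement of the 3-px-dilated union of cell masks.

Tracking solves a rectangular assignment problem on squared centroid
displacements with a hard gate (`max_disp`, default 10 px); unmatched
detections found new tracks. Ties resolve to lowest total squared
displacement, then lowest track id, making links deterministic. On division
the daughter closest to the parent centroid inherits the track id.

Mask erosion uses a disk structuring element; if erosion empties the mask
the single pixel nearest the centroid is kept, so a targeted cell always
receives light.

## Filters

**Kalman (population).** State = protein level in molecule units;
measurement `y = α·n + N(0, σ_meas²)`. The predict step is the exact
discretization of the ODE; the process-noise increment defaults to the
linear-noise-approximation variance of the birth–death process over one
step, `q = (b0 + k·u + γ·m)(1 − e^{−2γΔ})/(2γ)`, divided by the number of
cells when the filter runs on an ensemble mean. The maturation delay is
handled by buffering the last `⌈τ/Δ⌉` applied inputs and reading the
effective input from the head of the buffer, which keeps the filter
recursion standard.

**FSP (single cell).** The chemical master equation truncated to
`{0..N}`; one-step propagation uses the matrix exponential of the truncated
generator, cached per (N, birth rate, γ, Δ) — with binary inputs only two
matrices exist per model. Probability flowing past `N` accumulates in a
`leaked` scalar, so `Σp + leaked = 1` to 1e−9 between measurement updates
(a tested invariant); the measurement update multiplies by the Gaussian
likelihood and renormalizes, resetting `leaked`. A measurement incompatible
with the entire support falls back to the prior with a logged warning. The
generic truncation default is 8× the maximal stationary mean; scenarios
with known operating ranges may set `N` explicitly (the MPC study uses
`N = 256` for a maximal stationary mean of ~123, i.e. > 10 SD of headroom).

**Fitting.** The deterministic model is fitted to group-mean trajectories
by bounded least squares over `(k, b0, γ)` in lumped fluorescence units,
with `τ` profiled over a 0–60 min grid in 3-min steps. With 6-min sampling
and 6-min input intervals, delays within the same interval produce
*identical* predictions on the sampling grid, so `τ` is identifiable only up
to the measurement interval; the profile argmin returns the smallest tied
value. The characterization design uses three profiles — always-on,
step-down (on for the first half), and 3-on/3-off — because the step-down
group's free-decay phase pins down `γ` and breaks the `k`–`γ` confounding
that purely rising designs suffer from.

## Controllers

**Adaptive exposure.** If the measured mean is below `target − deadband`
the exposure increases by a constant step; above `target + deadband` it
decreases; always clamped to `[e_min, e_max]`. Sizing rule: against a dye
of half-life `T½`, holding the setpoint requires the exposure to grow at
`e·ln2·Δt/T½` per frame, so the step must exceed that at the largest
exposure the run will reach — the preset uses a 30 ms step, 50 a.u.
deadband, and `e_max = 2000 ms` for a 360-min run at `T½ = 180 min`.

**MPC.** Candidates are all `2^H` binary profiles (`H = 4`). Because
`τ = 36 min` exceeds the 24-min horizon, an input chosen now first affects
the output `τ` minutes later; the controller therefore propagates the model
through the committed delay-buffer steps (identical across candidates) and
scores each candidate on the `H` outputs it actually influences. Ties break
toward less total light (photo-toxicity minimizing), then
lexicographically off-first. Unreachable targets saturate without error.
The open-loop planner runs the same receding-horizon optimization against
the model alone and concatenates first-step decisions.

## Scenario designs (study conditions)

*Adaptive exposure*: 2 fields of view, 50 cells each, 360 min (60
fluorescence frames at 6 min), dye half-life 180 min, setpoint 3000 a.u.
The companion constant-exposure run shares all seeds.

*Characterization*: 3 groups, 60 steps of 6 min, 5 % (of dynamic range)
Gaussian noise on the group means, `k = 20`, `b0 = 0.5`, `γ = ln2/90`,
`τ = 36 min`.

*MPC comparison*: 100 SSA cells, 30 steps. True plant: `k = 0.9`,
`b0 = 0.05`, `γ = ln2/90`, `α = 40`, `σ_meas = 100` (~2 % of the dynamic
range), constant target 2000 a.u. (50 molecules). Cells carry lognormal
extrinsic variability of the induced rate (`CV = 0.25`, unit mean) — the
dominant noise source in real single-cell expression data and the feature
that population-level control cannot correct. The run starts from the
maintenance regime: each cell at its own conditional steady state under the
common duty cycle that holds the target, with that duty cycle as the shared
input history. Controllers never see the true rates; they use a model
calibrated from an in-silico characterization run (so population feedback
and open-loop control face realistic model mismatch). The ensemble
(per-cell rates and initial counts) is drawn once and shared across the
three strategies, making per-cell comparisons paired. Performance is the
time-averaged absolute deviation of the true fluorescence `α·n` from the
target. Expected outcome, and what the tests assert: single-cell feedback
is strictly better than both alternatives (paired sign tests), while
population feedback and open-loop control are statistically comparable —
with a correct-enough model both hold the mean, and neither can correct
individual cells.

*Recombination*: 40 cells, 180 min, brightfield every 3 min, stimulation
ticks every 6 min (1 s pulses, eroded masks, erosion radius 2 px). A dose
at least `dose_threshold` (100 ms-equivalent; an eroded-mask hit delivers
~400, bleed-through onto neighbors < 50) recombines a cell with
`p_rec = 0.9` per tick. The recombined phenotype: after a 24-min reporter
delay the reporter ramps linearly to plateau over 30 min, and the growth
rate is multiplied by 0.3. Growth/division are disabled in these presets so
that track↔ground-truth correspondence stays exact at low density; the
growth-arrest phenotype itself is exercised in dedicated population-dynamics
tests. The endpoint classifier thresholds the final reporter fluorescence
at the midpoint between basal and plateau levels, which separates the two
populations by ~3.5 shot-noise SDs.

## What the synthetic data do not emulate

Real optics (PSF, defocus, stage drift), realistic bright-field texture,
touching/overlapping cells that require learned segmentation, mRNA dynamics
and cell-cycle-dependent expression, mechanistic photocycle kinetics, and
lineage-resolved recombination reporters. Tests passing on these scenes
validate the *control and estimation stack* and the renderer's contracts;
they do not certify segmentation or tracking performance on real imagery.

## Numerical choices and degenerate inputs

- All randomness derives from one master seed via labeled `SeedSequence`
  streams; identical configuration + seed reproduce byte-identical outputs.
- The dense-grid Bayes filter used as the Kalman oracle uses a 4096-point
  grid over a range chosen to hold the posterior mass; grid spacing is far
  below the posterior SD, making discretization error negligible at the 1 %
  comparison tolerance.
- Empty masks, zero-frame runs, empty label sets and zero-duration
  propagation are all defined no-ops (documented per function) rather than
  errors; invalid configurations fail with a diagnostic naming the key
  before any acquisition.
- Exposure requests outside `[e_min, e_max]` clamp with a logged warning
  rather than erroring, matching how a hardware driver behaves.

## Known limitations

- The delay is identifiable only to the measurement interval (see Fitting);
  reported delays are grid values.
- The FSP truncation is static; a cell driven far above the anticipated
  operating range leaks mass (monitored and warned, not auto-extended).
- The event engine is sequential-equivalent: effects never interleave
  within a frame, which is a semantic guarantee, not a performance model of
  a threaded implementation.
- Population-level MPC with a binary actuator exhibits a small limit cycle
  around the target (one production quantum per interval); this is inherent
  to the actuation, not an estimator artifact.
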