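# Methods

## Model

Each network node is a cortico-thalamic motif of four neural
populations: cortical excitatory (e) and inhibitory (i), thalamic relay
(s, excitatory) and thalamic reticular (r, inhibitory).  Population
activity u_p (mV) follows first-order rate dynamics,

    du_p/dt = α_p,eff · ( −u_p + G_p + i_p + stimulation ) + noise,

where G_p collects sigmoid-transformed input from the partner
populations (F(u) = 1/(1+exp(−β(u−σ))), β = 20, σ = 0).  Cortex and
thalamus exchange activity with a conduction delay τ_ct = 20 ms in each
direction; the intrathalamic r↔s projections carry τ_tt = 5 ms.  The
rhythm-generating structure is a fast cortical e–i pair (gamma) nested
inside a slow delayed inhibitory loop e→r→s→e (total lag 45 ms, alpha).
Long-range coupling enters the excitatory population only, as a
tract-delayed afferent sum over the connectome scaled by the global
gain g.

Two exogenous inputs implement the experimental manipulanda: a static
drive I_o to the thalamic relay population (the idling/active control
parameter) and a sinusoid M·sin(2πωt) to the cortical excitatory
population (periodic stimulation).

## Parameter conventions

Nominal values follow the standard tabulation for this model family
(`CTWCParameters` defaults).  Three conventions deserve explicit
statement:

**Rate-constant units.**  The tabulated α_p values (0.3, 0.5, 0.2, 0.2
for e, i, s, r) are dimensionless in our implementation and converted
to effective rates by `rate_scale = 0.1 ms⁻¹`, i.e. population time
constants of 33, 20, 50 and 50 ms.  We verified by direct simulation
that this is the only unit reading of the tabulated values under which
the model expresses all three of its defining behaviours at once: an
idling-state spectral peak near 10 Hz, an active-state peak near 30 Hz,
and the idling→active transition near I_o = 1.3.  Reading the values as
rates in ms⁻¹ (time constants 2–5 ms) puts the idling cycle at 27.5 Hz
and the cortical resonance near 100 Hz or above; reading them as time
constants of 20–50 ms with the printed pairing inverted (e slow, i
slower) yields a 17.5 Hz rhythm and no state switch.  Physiologically,
20–50 ms is the accepted neural-mass range for population/synaptic
integration times.  `rate_scale` is an ordinary config key and can be
set to 1.0 to recover the literal-rate reading.

**Weight normalization.**  Before the global gain g = 5 is applied, the
connectome weight matrix is scaled to a unit maximum and divided by the
node count ("mean" scheme), so g·Q is a g-scaled weighted mean field of
afferent activity.  With β = 20 the cortical populations operate within
roughly |u| ≲ 0.3 mV of threshold; a weighted *sum* (row sums of order
2–10 after max-normalization) delivers a tonic afferent drive of
several mV, pinning u_e deep in sigmoid saturation where F′ ≈ 0 — the
network then shows no active-state gamma, no focal-drive propagation
and no connectivity structure at all.  Under the mean-field convention
all of these phenomena survive and the total long-range drive is
independent of parcellation granularity.  "max", "row" (per-row sums)
and "none" schemes are selectable for sensitivity analysis.

**Noise placement.**  The Euler–Maruyama update adds
α_p·√(2·D·dt)·η per step (η ~ N(0,1) i.i.d. per population, node and
step), i.e. the white-noise term shares the population rate
pre-multiplier with the deterministic drift.  With all gains zeroed
each population is then an Ornstein-Uhlenbeck process with stationary
variance α_p,eff·D — the closed form used in the test suite.  The
alternative placement (no α pre-multiplier) is available as
`noise_scaling="unit"`; it leaves all regime structure intact (peaks
shift by ~1–5 Hz) while raising the noise floor.

## Integration

Explicit Euler–Maruyama at dt = 0.1 ms (α_eff·dt ≤ 0.005, far inside
the stability region; halving dt moves the dominant spectral peak by
< 0.05 Hz).  Delays are rounded to integer step counts (half away from
zero) with a floor of one step, and served from a ring buffer whose
depth exceeds the maximum delay by one slot so a step's writes can
never alias a live delayed read.  History before t = 0 is the constant
vector (i_e, i_i, i_r, i_s), so gain-free systems start at their rest
point; the first `burn_in_ms` (default 1000 ms, ≥ the maximum delay by
construction) is discarded.  The stimulation sinusoid has zero phase at
the end of burn-in.  Given a seed, trajectories are bitwise
reproducible; the compiled kernel is cross-checked in the test suite
against a pure-NumPy stepper composed from the reference sigmoid,
coupling and afferent operations.

Long network runs may be recorded with an integer stride
(`record_every`); the stride is plain subsampling, appropriate because
the state variables are smooth on the 0.1 ms scale (the OU roll-off at
α_eff ≈ 0.02–0.05 ms⁻¹ leaves negligible power near the native
Nyquist).  Analyses that push near the recorded Nyquist should instead
use `downsample`, which applies a zero-phase FIR anti-alias filter
(passband flat to < 1%) and guards the requested rate against the
highest analysis band.

## Analysis chain

*Spectra* are Welch averaged periodograms (Hann taper) in two presets:
"peak" (2-s segments, 0.5 Hz bins, used for all peak-frequency
statements) and "meg" (256-sample windows, 128 overlap — the M/EEG
comparison convention, applied after downsampling to 500 Hz).  Peak
location refines the maximum bin by parabolic interpolation; a maximum
below twice the in-range median power is flagged as no-peak and ties go
to the lowest frequency.  Band powers integrate the density with the
trapezoid rule over delta (0.5–4), theta (4–8), alpha (8–12), beta
(12–30) and low gamma (30–45 Hz).

*Focal-drive maps* report per-node changes in **relative** band power
(band / total 1–45 Hz power) between a baseline and a perturbed run
with matched noise realizations.  Relative power is the meaningful
quantity here: switching a node to the active state reduces its total
variance by orders of magnitude, so absolute gamma power falls even as
the spectrum becomes gamma-dominated.  Absolute differences are
available via `relative=False`.

*AEC functional connectivity* follows the band-limited amplitude
envelope correlation recipe: per 30-s window (five windows by default)
each regional series is band-passed (4th-order Butterworth,
second-order sections, forward-backward), the Hilbert envelope taken as
the modulus of the analytic signal, 1 s trimmed from each window edge,
and Pearson correlations averaged across windows.  The phrase "real
part of the analytic signal" sometimes used for this step would return
the filtered signal itself; that variant is kept only as an audit mode
(`envelope_mode="real"`).  No leakage correction is applied — simulated
regional series have no source-mixing artifact.

*Thalamic-parameter fitting* scans a grid of (α_s, α_r), simulates one
idling node per cell, and scores each cell by the squared Pearson
correlation between its spectrum and a target spectrum on a shared
1–45 Hz grid.  Default scoring correlates log power of MEG-preset
spectra.  The two scoring modes answer different questions: log power
weights the overall spectral shape (background slope, relative peak
prominence) and is the mode under which a smooth alpha-peaked synthetic
target is matched at R² ≥ 0.6; linear power is dominated by the highest
peak and therefore selects the cell whose rhythm aligns with the
target's peak frequency (within 2 Hz in the shipped tests) at lower
overall R².  Users fitting for peak location should pass
`log_power=False`.  Grid cells whose simulation diverges are recorded
as NaN, not fatal.

*Arnold-tongue maps* simulate 20 s per (M, ω) cell, mark a cell
entrained when the dominant spectral peak lies within 0.5 Hz of ω
(2:1 and 3:1 harmonic locking is recorded separately), and store two
response measures: half the peak-to-trough range of u_e and the locked
spectral peak power.  The tongue apex is read from the lowest nonzero
amplitude row containing entrained cells, taking the contiguous run
nearest the natural frequency and, within it, the cell with maximal
peak-power response.  The peak-power tie-break matters in the active
state, where entrainment at M = 0.05 already succeeds across the whole
2–50 Hz range: the peak-to-trough range is an extreme statistic whose
argmax wanders by ±2 Hz between seeds, whereas the time-averaged locked
power identifies the same resonance cell across seeds.  Zero-amplitude
rows are excluded from apex determination (an unstimulated cell
trivially "entrains" at its own natural frequency).  Tongue width at an
amplitude row is the frequency measure of the contiguous entrained run
containing the apex column.

## Synthetic study materials

The connectome generator emulates only the statistics the model
consumes from a group-averaged tractography matrix: 68 regions in two
lateralized hemispheric clusters, symmetric non-negative weights with
zero diagonal, log-normal weight magnitudes attenuated with distance
(80 mm scale) and by a factor 3 across hemispheres, thresholded to 40%
density and max-normalized; tract lengths are Euclidean distances
mapped affinely into 15–245 mm, consistent with standard streamline
length filtering (10–250 mm).  It makes no attempt to match edge-level
values of any empirical dataset, so tests passing on these fixtures
demonstrate pipeline correctness and qualitative regime behaviour, not
empirical fidelity of any particular human connectome.

The target-spectrum generator produces a 1/f^χ background plus a
Gaussian alpha bump (default 10 ± 2 Hz, four times the background at
the peak) under multiplicative log-normal noise — a stand-in with the
gross shape of a resting sensor-averaged M/EEG spectrum.  It shares no
machinery with the model, so fitting it is a genuine cross-model test.

## Measured behaviour at nominal parameters

All numbers below are computed by the shipped tests and
`scripts/acceptance.py`, not asserted from memory: idling-state peak
8.3 Hz; active-state (I_o = 1.5) peak 31–33 Hz depending on seed and
record length (the active rhythm is a noise-sustained resonance with a
broad spectral peak, not a deterministic limit cycle — at D = 0 the
driven fixed point is stable); regime switch between I_o = 1.25 and
1.30 at 0.05 grid resolution; idling tongue apex 8 Hz with width
growing from 1 Hz (M = 0.05) to ~20 Hz (M = 1); active tongue apex
33 Hz, entrained across the full 2–50 Hz range already at M = 0.05.
The idling rhythm sits ~1.5 Hz below, and the active rhythm ~2 Hz
above, the round 10/30 Hz figures usually quoted for this circuit;
both lie within the alpha and low-gamma bands respectively, and we
chose not to re-tune the rate scaling per state, which would amount to
fitting the summary statistics rather than reading the parameter table.

## Problem sizes

Default experiment scales were chosen to keep every analysis
statistically stable at interactive runtimes: 20 s simulated time per
spectral estimate and sweep cell (0.5 Hz Welch resolution, ~10
averaged segments), 60 s for the 68-node focal-drive experiment (five
orders of magnitude of alpha-power change at the driven node dwarf the
estimator noise), and 64 s / three 20-s windows for network AEC
checks.  The grid fit uses 5×5 cells over α_s, α_r ∈ [0.1, 0.3].

## Known limitations

- The model reproduces regime structure, not biophysical calibration:
  absolute u_p scales and band powers are arbitrary model units.
- First-order population dynamics cannot capture damped evoked-response
  waveforms that second-order (synaptic-kernel) models produce.
- The active-state "gamma oscillation" is a stochastic resonance around
  a stable focus; analyses that require a deterministic limit cycle
  (e.g. phase-response curves) do not apply.
- The mean-field weight normalization makes inter-node influence weak
  by construction; network FC structure is correspondingly subtle
  (correlation with the structural template ~0.1–0.5 in the active
  state, near zero when idling), and single-seed FC contrasts at small
  network sizes can invert in the alpha band.
- Delays below dt collapse to a single integration step.
- No tractography, parcellation handling, or subject-level variability:
  synthetic connectomes are statistical stand-ins only.
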