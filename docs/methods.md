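# Methods

## Model

Each cell carries a repressilator: a ring of three genes (*lacI*, *tetR*,
*cI*) whose proteins (LacI = `lp`, TetR = `tp`, cI = `cp`) cyclically
repress the transcription of the next gene in the ring (cI ⊣ *lacI*,
LacI ⊣ *tetR*, TetR ⊣ *cI*).  Per gene the model tracks one mRNA and one
protein, giving six ODEs per cell:

    d(lp)/dt = k_lr·lr − k_lp·lp
    d(tp)/dt = k_tr·tr − k_tp·tp − diff·tp + diff·tp_external
    d(cp)/dt = k_cr·cr − k_cp·cp
    d(lr)/dt = α₀ + α·km^n / (km^n + cp^n) − k_lr·lr − k_lr2·lr
    d(tr)/dt = α₀ + α·km^n / (km^n + lp^n) − k_tr·tr − k_tr2·tr
    d(cr)/dt = α₀ + α·km^n / (km^n + tp^n) − k_cr·cr − k_cr2·cr

Two cells are coupled only through TetR, which exchanges between the
cells by first-order bidirectional diffusion at rate `diff` (each cell's
`tp_external` is the partner's `tp`).  The exchange is antisymmetric:
total TetR is unaffected by the coupling.

Default constants: α₀ = 0.03, α = 29.97, km = 40, n = 3,
protein degradation k_{lp,tp,cp} = 0.069, mRNA-to-protein coupling
k_{lr,tr,cr} = 6.93, second mRNA removal k_{lr2,tr2,cr2} = 0.347.
Time is dimensionless ("model time units"); frequencies are cycles per
model time unit.  Concentrations are nonnegative; the integrator clips
sub-roundoff negative excursions to zero inside the right-hand side.

Two deliberate literalisms are worth flagging:

* the mRNA equations carry **both** removal terms (−k_?r and −k_?r2), so
  the effective mRNA turnover is 6.93 + 0.347.  Whether the first term
  models translation-coupled mRNA consumption or is an artefact of the
  source model is undecidable from the constants alone; the form is kept
  as stated.  Variants without the double term were checked and behave
  strictly worse against every reference value available.
* the repression term uses the standard Hill form km^n/(km^n + x^n).
  With a *linear* repressor in the denominator (km^n + x) the system has
  a globally attracting fixed point at these constants and never
  oscillates, so the Hill reading is forced.  The exponent placement is
  still switchable (`hill_exponent_on_repressor`) for sensitivity work.

With the default constants the free-running cell settles onto a limit
cycle of period ≈ 74.88 time units (frequency ≈ 0.01335 cycles per time
unit), with TetR swinging between ≈ 25 and ≈ 236 concentration units.

## Numerics

All simulations use `scipy.integrate.solve_ivp` with LSODA,
rtol = 1e-8, atol = 1e-10 (exposed in `IntegratorSettings`), and dense
output sampled on uniform grids (default 200 samples per period for
single cells, 60–100 for long coupled runs).  LSODA was the fastest of
the stiff-capable options on this vector field by a factor ≈ 2–4.
Halving the tolerances moves terminal states by < 0.1% over hundreds of
periods; classifications of every fixture scenario are unchanged.

**Limit cycle.**  A transient of 30 estimated periods is discarded; the
period is the mean spacing of the last 20 TetR maxima, each maximum
refined by a quadratic fit through three samples.  One period of the
dense solution starting at a TetR maximum is stored as the orbit; the
endpoint must return to the start within 1e-3 (relative, per species
scale), otherwise the extraction errors out.  Phase 0 is defined as the
TetR maximum — the model never singles out a phase origin, any
consistent convention reproduces the scan topology, and TetR is the
coupling species, so its peak is the natural marker.

**Frequency estimation.**  Two independent estimators: (1) FFT of the
mean-removed signal with parabolic interpolation of the dominant bin on
log-amplitude; (2) mean spacing of refined peak times.  They agree to
well under 1% on ≥ 50-cycle windows and are cross-checked routinely.

**Frequency calibration.**  The free-running frequency is tuned by
scaling the three protein degradation rates by one common factor `s`
(degradation speed is the canonical frequency handle for ring
oscillators of this type, and one parameter suffices for the needed
range).  Empirically f(s) ≈ f(1)·s^1.25 near the base set; a secant
iteration with a bisection fallback on a maintained bracket converges in
3–6 frequency measurements to 0.1%.

## Synchronisation criteria

A coupled run is *synchronized* when three conditions hold: the
oscillation is undamped, the two signals harmonise within an
ε-neighbourhood after a finite `t_sync`, and the locked signal is
monofrequential.  ε is "one minute per day": 1/1440 of the oscillation
period, applied to the offset between matched TetR peak times of the two
cells.

* **Identical cells** (phase-shift study): the locked state has zero
  lag, so `t_sync` is the first peak time after which |Δt| < T/1440
  holds for ≥ 10 consecutive cycles and through the end of the
  trajectory.
* **Detuned cells** (frequency-ratio study): a phase-locked pair keeps a
  constant *nonzero* lag, so the same ε is applied to the drift of the
  offset instead: the unwrapped offset series must settle into a band of
  total width T/1440 and stay there.  Two clocks whose mutual drift is
  below one minute per day-analogue period are operationally
  synchronized; slow beats and phase slips both wander by more and are
  rejected.  (Applying the raw |Δt| < T/1440 test to detuned cells would
  declare every detuned pair unsynchronized, contradicting the study
  design.)
* **Monofrequential**: over the terminal 80 base periods, the
  Hann-windowed TetR spectrum of each cell must contain no component
  above 10% of the dominant peak away from its integer harmonics
  (quasiperiodic regimes show sideband families near the fundamental —
  windowing matters, since rectangular-window leakage alone reaches 22%
  and fakes sidebands), and the two fundamentals must agree within 1%.
  The sideband resolution is set by the window length; 80 periods
  resolves the beat structures that occur at the default grids.
* **Damped**: the coupled steady state (damped-Newton root of the
  12-dimensional vector field, residual < 1e-10, analytic Jacobian) has
  only eigenvalues with negative real part *and* the trajectory's
  terminal amplitude has collapsed.  If the two lines of evidence
  disagree — which genuinely happens in a bistable regime at strong
  coupling and large detuning, where a stable steady state coexists with
  a persisting oscillation — classification raises a diagnostic error
  rather than guessing; the window bisection counts such cells as
  outside the window because the undamped condition fails linearly.
  Eigenvalues within 1e-8 of the imaginary axis are reported as marginal
  rather than silently rounded.

Defaults: hold = 10 cycles, horizon = 200 base periods (scans report
"not synchronized" beyond it), polyfrequential sideband threshold = 10%.
All are configurable; none is stated in the source material.

## Scans and window bisection

The phase scan seeds both (identical) cells on the shared limit cycle at
phases 0° and φ and classifies each (φ, diff) cell of the grid; default
grids are 36 phases × the seven couplings {0.01 … 0.13}.  The frequency
scan keeps cell B at the base set, calibrates cell A to ratio × base
frequency, and seeds each cell at phase 0 of its own cycle.  The window
bisection brackets the synchronized/not-synchronized transition on each
side of ratio 1 and halves to a ratio tolerance (default 0.01).  Scan
cells are independent and re-runnable bit-identically from the stored
provenance (the pipeline contains no randomness).

## PLL building blocks

The multiplier is the two-reaction network X₁ + X₂ → Y, Y → ∅ under
mass action with *clamped* inputs; its steady state is
Y* = (k_form/k_deg)·X₁(0)·X₂(0), the product itself when the two rate
constants match.  Clamping is essential — with consumed substrates the
steady state is zero — and the consuming variant is provided only for
contrast.  The low-pass filter is a linear m-stage cascade
dYᵢ/dt = kᵢ(Yᵢ₋₁ − Yᵢ) (three to eight stages typically); its gain is
the product of one-pole factors kᵢ/√(kᵢ² + ω²) and its lag the sum of
arctan(ω/kᵢ).  Driven-cascade simulations reproduce the closed forms to
< 1% after the startup transient has decayed below the resolvable gain
(the settle window scales with the slowest stage, ≥ 40/k_min).  Passing
the spiky repressilator TetR waveform through a 5-stage cascade with
corner rates at half the fundamental yields a near-sinusoid (residual
harmonic content < 10%), which is the property the comparator needs.
The closed feedback loop (oscillator ← filtered error signal) is out of
scope: no kinetics are specified for the comparator-to-protease link.

## Reference-value discrepancies

Three published reference values could not be reproduced from the
printed equations and constants, after systematic variation of every
ambiguous reading (Hill form, mRNA-removal terms, Hill exponent,
rate-scale factors):

1. **Free-running frequency.**  The printed constants yield 0.013354
   cycles per model time unit (period 74.88), not the published 0.001578
   (factor ≈ 8.46).  No single-parameter reading closes the gap; scaling
   the protein degradations to ≈ 0.2× reproduces 0.001578 but then
   contradicts the published limit-cycle point and window (below).  The
   published frequency axis appears to live on a different time scale
   than the printed rate constants.
2. **Limit-cycle point.**  The published 6-D state (lr = 0.819,
   tr = 2.388, cr = 0.068, lp = 36.263, tp = 166.685, cp = 64.26) is not
   on the limit cycle of the printed constants (closest approach ≈ 77%
   relative).  A single cell with an extra TetR outflux −d·tp, d ≈ 0.04,
   passes within ≈ 29%, suggesting the point was sampled from a
   coupled or dissipative run rather than the free-running cell.
3. **Window width.**  At diff = 0.07 the implemented pair phase-locks
   monofrequentially over a far wider ratio range than the published
   window (0.697–1.294); the same holds with the base cell recalibrated
   to 0.001578.  In ratio terms the published window is instead similar
   to this model's behaviour at diff ≈ 0.01–0.03, where the upper edge
   (≈ 1.09 at diff = 0.01) and the near-edge pull of the locked
   frequency toward the *faster* cell both appear — the same qualitative
   structure at a shifted coupling scale.

The calibrated-pair experiments are therefore specified in absolute
terms (both cells explicitly calibrated to the published frequencies),
which reproduces the mid-window common frequency to ≈ 0.3%; the other
published values are recomputed faithfully and reported as measured.
The acceptance script states what the pipeline actually produces; no
constant is adjusted to match a published number.

## Problem sizes

Acceptance-scale runs use: 100 cycles for the free-running frequency,
150–300 base periods of coupled integration for the calibrated pairs,
and a 150–200-period horizon per cell of the window bisection at ratio
tolerance 0.015.  These sizes hold every estimate's discretisation error
at least an order of magnitude below the tightest comparison tolerance
while keeping a full reproduction on one core in the tens of minutes.

## Limitations

* Deterministic ODEs only; no intrinsic molecular noise (no Gillespie
  branch), so the synthetic trajectories lack the cycle-to-cycle jitter
  of real single-cell data, and the sharp window boundaries measured
  here would smear under noise.
* Two cells only (the vector-field layer accepts per-cell parameter
  sets, but nothing above it handles N > 2).
* The quorum-sensing biochemistry that would mediate real intercellular
  coupling is abstracted into a single diffusion constant on TetR.
* Window boundaries are operational: they depend (weakly) on the
  simulation horizon and the sideband threshold, both of which are
  reported alongside results.
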