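# Methods

## Model

Three species, A, B and C, live on a periodic square of side `box_length`
(the unit of length; the reference arena is L = 1) with continuous
coordinates.  Dominance is cyclic: A preys on B, B on C, C on A.  The
population evolves by a random sequential (Monte Carlo) scheme:

* **Elementary step.**  One living individual is drawn uniformly; one
  action is drawn from {move, predate, reproduce} with probabilities
  (m, p, r), m + p + r = 1.
  - *Move* displaces the individual by exactly `move_length` in a uniform
    random direction (always succeeds; positions wrap).
  - *Predate* kills the closest individual of the actor's prey species
    within `pred_radius`; if none is in range, nothing happens.
  - *Reproduce* counts every individual — any species, the actor included —
    within `repro_radius` of the actor.  If the count is strictly below the
    local carrying capacity M, a newborn of the actor's species is placed
    uniformly in the disk of `offspring_radius` around the actor.
* **Full MC step.**  N₀ elementary steps, where N₀ is the population size
  frozen at the start of the step.  N₀ is the model's unit of time.

This is a May–Leonard scheme: predation and reproduction are separate
events, so the total population N = n_A + n_B + n_C fluctuates.  M is the
single environmental parameter: small M models a harsh environment that
supports only a sparse population, large M a benign one.

Reference parameter values: m = 0.5, p = r = 0.25;
`pred_radius` = `repro_radius` = 0.02, `move_length` = 0.01; initial
population 10⁴ per species, uniformly placed, in the unit box.

### Conventions on points the verbal model leaves open

* **The reproduction count includes the actor** ("all individuals within
  the reproduction range" — the actor is within its own range at distance
  zero).  Consequence: M = 1 forbids reproduction entirely.
* **The capacity check is evaluated around the parent**, not the proposed
  offspring site.
* **`offspring_radius` is an independent parameter** defaulting to
  `move_length` (0.01).  The model statement places the newborn "within a
  radius" that is plausibly either the movement or the reproduction range;
  keeping it configurable makes the choice explicit instead of silent.
  Offspring positions are area-uniform over the closed disk (radius drawn
  as R·√u).
* **N₀ is frozen per MC step** even as births and deaths change N
  mid-step; this gives a well-defined unit of time.
* **Closed disks everywhere**: an individual exactly at distance = radius
  is inside the neighbourhood (exact ties are measure-zero in continuous
  space).  The nearest-prey search breaks exact distance ties toward the
  smallest id, again only to make tests reproducible.
* **Interaction radii must be smaller than the box** (minimum-image
  distances are used throughout), but `move_length` may be arbitrarily
  large: a long step wraps around the torus, which is exactly the
  well-mixed limit worth studying.  Validation therefore bounds
  `pred_radius`, `repro_radius` and `offspring_radius` by `box_length`
  but only requires `move_length` > 0.

## Implementation

The production engine is a numba-compiled kernel over flat arrays.
Living individuals occupy slots 0..n−1; a death moves the last slot into
the vacated one, so uniform selection is O(1).  Neighbourhood queries use
a uniform periodic cell list with cell size ≥ max(`pred_radius`,
`repro_radius`), so every query touches at most a 3×3 block of cells; when
the box is narrower than three cells the engine falls back to brute-force
scans (the 3×3 block would self-overlap).  Buffers are sized from the
packing bound M/(π·`repro_radius`²); in the (never observed) event of
overflow the run is repeated from its seed with larger buffers, so results
are unaffected.

A pure-Python reference layer implements the identical processes on an
object-level `PopulationState`.  Both layers draw from one
`numpy.random.Generator` in the same documented order (actor, action, then
action-specific draws: angle for moves; radius then angle for a successful
birth; nothing for predation), so the compiled kernel, the brute-force
kernel backend and the Python layer produce bit-identical trajectories
from the same seed — this exact equivalence is asserted in the tests.

## Observables

* `summarize` reports the stationary mean of N with a block-averaged
  standard error (default block 100 MC steps).  Successive MC steps are
  strongly autocorrelated — the oscillation period is O(100) steps — so
  naive iid errors would be anticonservative.  The histogram of N uses
  unit bins (N is integer) unless the range exceeds 10³ values.
* `sweep_capacity` pools replicate means per M; `linear_fit` is weighted
  least squares (weights 1/SE²) via statsmodels, and slope comparisons use
  the joint standard error √(SE₁² + SE₂²).

## Spectral analysis

The species fraction ρ(t) = n_s(t)/N(t) — the fraction, not the raw
count — is transformed with the normalised DFT

    ρ(f) = (1/N_G) Σ_{t=0}^{N_G−1} ρ(t) e^{−2πift},

so ρ(0) is the time mean.  The power |ρ(f)|² is averaged across
independent runs ("ensemble" spectrum), folded to one side, and the peak
is the argmax over f > 0, reported as the integer cycle count k per
N_G-step window.  The DC bin is retained but never searched; no mean
subtraction, windowing or Welch segmenting is applied (a plain DFT over
one window per run).  An optional odd-width moving average is available
for noisy spectra but is off by default and never changes a clean peak.
Peak location is invariant to any overall power rescaling.

## Desk-scale protocol

The reference experiments relax for up to 10⁸ MC steps in the unit box;
that is far beyond a workstation check.  The scenarios shrink the box
(0.5 for spectra, 0.25 for capacity sweeps) with radii unchanged, and
scale the initial population by the area ratio, preserving local density
and rates.  The per-step oscillation frequency is set by the local
dynamics, so it survives the shrinking and needs no rescaling; the
large-scale spiral imagery does not survive and is only exported
qualitatively (snapshots).  Spectral runs use 1000 relaxation steps and
N_G = 10⁴ recorded steps; capacity sweeps use 2000 + 4000 steps.

Two finite-size effects of the reduced box matter and are handled
explicitly:

* **Fragile coexistence at small M.**  With ~4× (box 0.5) to ~16×
  (box 0.25) fewer individuals, the collective oscillation is nearly
  box-coherent and demographic fluctuations can drive a species extinct
  within 10⁴ steps at small M — something the full-scale system does not
  do on this horizon (verified directly: unit box, M = 10, 2000 steps,
  0/5 runs lose a species at `move_length` = 0.01, 5/5 at 0.8).  The
  ensemble spectrum characterises the oscillation of the *coexisting*
  state, so `spectrum_sweep` discards symmetry-broken replicates and
  draws replacements from the same deterministic seed sequence, recording
  how many were discarded.
* **Synchronised transient phase.**  Every run starts from exactly equal
  counts, so the composition oscillation initially has a common phase
  across seeds; over a short early window the three ensemble means differ
  systematically.  The phases decohere after O(10) oscillation periods,
  so label-symmetry checks use late windows.

Replicate counts: the reference spectra average 250 runs; desk-scale
checks use 8 coexisting replicates per M across the capacity sweep (16
for the single-M headline measurement in `scripts/acceptance.py`), the
most their intended runtime envelopes support.  Per-run peak locations at
M = 30 are tightly clustered (103–106 across independent seeds), while
the low-frequency drift power is heavy-tailed across runs; ensemble
averaging exists precisely to keep that drift from masking the peak.

One full-scale feature does *not* survive the reduction: at full scale
the spectral peak grows monotonically higher with M, but in the reduced
box the same near-extinction drift that forces the replicate filter also
inflates the measured peak power at small M (the M = 10 ensemble peak
height exceeds the M = 15 one in independent seed batches), so peak
*heights* are not monotone in M at desk scale even though peak
*locations* are.  The package reports heights as measured.

## What the synthetic fixtures do and do not show

`make_sinusoid_fixture` plants a known tone (default k = 107 cycles per
10⁴ samples) in Gaussian noise clipped to [0, 1]; it validates the
transform, folding, and peak extraction with a known ground truth.  It is
stationary, phase-locked and spectrally pure — unlike simulator output,
whose oscillation drifts in frequency and amplitude.  Passing the planted
tests validates the analysis pipeline, not the simulator; the simulator
is validated by the dynamical invariants (conservation, label symmetry,
backend equivalence) and the desk-scale phenomenology checks.

## Known limitations

* Quantitative spiral geometry (wavelength, defect tracking) is out of
  scope; snapshots are exported for qualitative inspection only.
* The empty-space fraction for the large-range scenario (share of a
  200×200 probe grid farther than `repro_radius` from every individual)
  is this package's own operationalisation of "deserted areas"; the
  reference description has no quantitative definition.
* Absolute spectral power values are not comparable to published curves,
  which are display-rescaled; only peak locations and relative heights
  are meaningful.
* At box sizes ≤ 0.25 and small M the coexisting state is metastable
  with a short lifetime; quantities conditioned on coexistence are then
  estimates over the surviving ensemble.
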