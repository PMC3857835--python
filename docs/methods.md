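# Methods

`gainfieldnet` simulates the self-organization of head-centered visual
responses in a two-layer rate model and quantifies the outcome with a
reference-frame receptive-field analysis.  This note documents the model,
the numerical choices, the defaults, and what the tests do and do not show.

## Model

**Input layer.** Input neurons are retinotopic visual neurons with peaked
eye-position gain fields.  Neuron *i* has a preferred retinal location
*x_i* and preferred eye position *e_i* on the cross product of two
1°-spaced grids, and fires at

    r'_i(x, e) = exp(-(e - e_i)² / 2σ_e²) · exp(-(x - x_i)² / 2σ_x²)

for a target at retinal location *x* while the eyes are at *e*.  The rate
is 1 exactly at the joint preference.  In the *decoupled* control the same
population keeps its size and grid but half of the neurons (alternating
along the grid) respond only to *x* and the other half only to *e* —
removing the single-neuron coupling of the two signals while preserving the
information content.

**Output layer.** Each of the *N* output neurons carries an activation
*h_j*, a firing rate *r_j* and a memory trace *q_j*:

    τ   dh_j/dt = -h_j + Σ_i w_ji r'_i
        r_j     = 1 / (1 + exp(-β (h_j - θ)))
    τ_q dq_j/dt = -q_j + r_j

Competition is implemented as a dynamic threshold: θ is recomputed at every
integration step as the π-th percentile of the instantaneous activation
distribution (linear interpolation between order statistics), so roughly
the top (100 − π)% of the layer fires strongly.  "Turning competition off"
pins θ at a fixed constant (0 by default) so all neurons may stay active.

**Plasticity.** Each output neuron receives afferents from its own random
subset of round(f·n_in) input neurons (fan-in identical across neurons,
connectivity fixed after initialization).  Weights start i.i.d. uniform and
each row is renormalized to unit Euclidean norm over its connected
synapses; renormalization runs after every weight update, which bounds
growth and makes learning competitive.  Two rules are implemented:

    trace    dw_ji/dt = ρ q_j r'_i
    hebbian  dw_ji/dt = ρ r_j r'_i

The trace rule's postsynaptic factor is the exponentially decaying memory
of recent firing, which binds input patterns occurring close together in
time onto the same output neuron.  The Hebbian rule has no explicit trace,
but a slow activation time constant gives it an implicit one.

**Protocol.** During training a visual target is fixed at one of T evenly
spaced head-centered locations while the eyes saccade through N_f fixation
positions drawn i.i.d. uniform from the permissible eye range; eye position
is piecewise linear in time (constant during fixations, constant-velocity
ramps during saccades) and the target's retinal location obeys x = h − e at
every sample.  Because the head-centered location is constant within a
period while the retinal location sweeps, the trace rule binds the
different retinal views of one head-centered location onto the same output
neurons.  Network state evolves continuously through an epoch — the trace
carrying across saccades and target periods is the learning mechanism —
and is reset at epoch boundaries.  Testing presents every combination of
E static eye positions and T_test head locations for a settle duration,
reads the final rates, and resets all state between conditions, so testing
has no order effects and never modifies weights.

## Numerics

* Forward Euler with dt = min(τ, τ_q)/10 (the faster of the two constants
  must be resolved during time-constant sweeps); dt is overridable.
* Stimuli are sampled at 1 kHz and linearly interpolated onto the
  integration grid.
* During testing the layer has no recurrent synapses, so the rates do not
  feed back into the activations; `settle_and_read` therefore integrates
  only *h* and evaluates the sigmoid at readout, which is identical to
  integrating all three variables and much cheaper.
* The percentile threshold uses numpy's linear interpolation between order
  statistics.
* Degenerate inputs are hard errors rather than silent fixes: grid steps
  that do not tile a range, eye positions not commensurate with the test
  head grid (the subvector alignment arithmetic would silently misalign),
  zero-norm weight rows, settle durations shorter than one step.

## Analysis

Testing produces a response tensor R[j, i, k] (neuron, eye position, head
location).  Per neuron:

* **Head-centeredness λ_h** — mean Pearson correlation over all unordered
  pairs of eye positions of the full head-centered response vectors.
* **Eye-centeredness λ_e** — the same after cropping each response vector
  to the window covering the intersection of the retinal ranges tested at
  the different eye positions: at eye e_i the window starts at index
  b_i = (e_i − e_min)/Δh and has length L = T − (e_max − e_min)/Δh.
* **RFI** = λ_h − λ_e; positive classifies the neuron head-centered,
  negative eye-centered, zero undetermined.
* **RF location** — centre of mass of the response over head space per eye
  position, averaged over eye positions with a response.
* **RF size** — ψ = φ · (global maximum rate); per eye position the
  response vector is linearly interpolated over head space and the total
  length of the above-ψ region (clipped to the tested interval) is
  computed from the threshold crossings; sizes are averaged over eye
  positions whose maximum reaches ψ.  Default φ = 0.5.
* **Coverage** — head-centered neurons (RFI > 0, RF location defined) are
  assigned to the nearest training location (ties to the more negative
  one); coverage is the normalized entropy −Σ p_t ln p_t / ln T of the
  assignment fractions, 1 for a perfectly even representation, and
  undefined ("no coverage") when any training location is unrepresented.

Population summaries report mean and population SD (divide by n) of each
metric over all analyzable neurons and over the RFI > 0 subset, the
head-centered rate (head-centered neurons over all output neurons), and
coverage.

**Exclusion rules and the response floor.** The logistic rate function
never reaches exactly zero, so "no response" must be operationalized: a
(sub)vector whose maximum rate stays below a floor of 0.01 — 1% of the
maximal possible rate — carries no response.  A neuron with no response in
the aligned retinal window at any eye position is excluded from analysis;
non-responsive subvectors are excluded pairwise from λ_e.  For the same
reason, vectors whose *dynamic range* is below the same floor (for
example, the residual ripple of a sigmoid saturated near 1, where the
threshold modulation is compressed to a few parts per thousand) are
treated as constant and dropped from the pairwise correlations: Pearson
correlation is scale-invariant, so without this rule such vectors inject
pure threshold noise into λ_h and λ_e.  A neuron whose reference-frame
metrics remain undefined after these rules is excluded.

## Defaults

| Parameter | Symbol | Full scale | Reduced scale |
|---|---|---|---|
| Retinal preference range | — | [−100, 100]° | [−40, 40]° |
| Eye preference range | — | [−30, 30]° | [−10, 10]° |
| Grid step | — | 1° | 1° |
| Tuning widths | σ_x, σ_e | 6° | 4° |
| Output neurons | N | 900 | 150 |
| Connectivity fraction | f | 0.10 | 0.10 |
| Init weight interval | — | [0, 1] | [0, 1] |
| Training locations | T | 8 at ±8, ±24, ±40, ±56° | 4 at ±7, ±21° |
| Fixations per period | N_f | 15 | 8 |
| Fixation duration | — | 300 ms | 300 ms |
| Saccade speed | v | 400°/s | 400°/s |
| Eye sample range | — | [−27, 27]° | [−9, 9]° |
| Epochs | — | 20 | 10 |
| Test eye positions | E | ±6, ±18° | ±2, ±6° |
| Test head grid | Δh | [−60, 60]° at 2° | [−30, 30]° at 2° |
| Settle duration | — | 300 ms | 300 ms |
| Activation time constant | τ | 10 ms | 10 ms |
| Trace time constant | τ_q | 100 ms | 100 ms |
| Sigmoid slope | β | 10 | 10 |
| Sparseness percentile | π | 95 | 95 |
| Learning rate | ρ | 0.05 s⁻¹ | 0.05 s⁻¹ |
| RF size threshold | φ | 0.5 | 0.5 |

The full-scale profile is the model at its intended size (201 × 61 =
12261 input neurons, 900 outputs, eight training locations).  The
reduced-scale profile is the package's routine-testing configuration: it
preserves every structural constraint — 1° grids, even target spacing,
visibility of every target at every permissible eye position, test eye
positions commensurate with the head grid — at roughly 1/50 of the state
size, so a full train-test-analyze cycle takes tens of seconds rather than
hours.  All simulation sizes quoted in the tests and the acceptance script
use this profile; that choice is the package's own trade-off between
statistical power and turnaround.

Dynamics and plasticity constants (τ, τ_q, β, π, ρ, f, the init interval
and the spatial defaults above) are package choices on the order of
magnitude a rate model of parietal cortex would use; all are
config-overridable, and the qualitative self-organization results do not
hinge on their exact values.

## Interpretation choices

* The sigmoid is the standard logistic r = 1/(1 + exp(−β(h − θ))), the
  simplest form with a named slope and threshold.
* The RFI is the difference λ_h − λ_e: continuous, bounded in [−2, 2],
  sign-classifiable, larger positive = more head-centered.
* Each training period starts at its first drawn fixation; eye position is
  not carried across target changes, since the (unmodelled) head movement
  between periods breaks eye-trajectory continuity anyway.
* The trace-vs-Hebbian comparison in the tests swaps only the learning
  rule at the default time constants.  A Hebbian rule with a slowed
  activation constant (e.g. τ = 100 ms) acquires an implicit memory trace
  and self-organizes nearly as well as the trace rule — that regime is
  exercised by the `tau_sweep_hebbian` experiment rather than by the
  default comparison.

## What the synthetic protocol does and does not show

All inputs are generated internally; there is no recorded neural data.
The stimulus generator emulates an idealized saccade-and-fixation regime:
a single point target, stationary head, instantaneous-onset
constant-velocity saccades, uniform fixation sampling, and noiseless
Gaussian input tuning.  Real gaze statistics (main-sequence saccade
kinematics, fixational drift, microsaccades, multiple objects, neural
noise) are absent, so passing tests demonstrate the *mechanism* — trace
learning over gain-field inputs suffices to build head-centered receptive
fields, and each component is necessary — not a quantitative fit to
primate physiology.

## Known limitations

* One-dimensional retinal and eye spaces; no torsion, no 2-D gaze.
* Competition is the percentile-threshold abstraction; no explicit
  inhibitory interneurons or recurrent dynamics.
* At reduced scale the reference-frame metrics of weakly selective
  neurons are noisy: a neuron responsive at only two eye positions gets
  λ_h and λ_e from a single correlation pair, and the dynamic competition
  threshold imposes weak common modulation on all co-active neurons, so
  individual RFI values can stray ~0.1 from zero in models (such as the
  decoupled control) whose population-level outcome is clearly not
  head-centered.  Population statistics are the reliable readout at this
  scale; single-neuron RFI margins tighter than ~0.1 are not.
* The delayed-trace variant of the learning rule and recurrent/feedback
  architectures between parietal areas are out of scope.
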