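# Methods

## Model

Each brain region *i* is a phase oscillator coupled through the weighted
structural connectome with transmission delays:

    dθi/dt = ωi + ξi(t) + (K/N) Σj aij sin(θj(t − τij) − θi(t))

* `ωi = 2π νi` with `νi ~ Normal(ν0, 0.1 Hz)`: a narrow spread of natural
  frequencies around the band of interest. Sweeping `ν0` (3, 11, 23, 35,
  51 Hz by default) probes the theta–high-gamma bands.
* `aij ∈ (0, 1]` are normalized structural weights (`aij = 0` means no edge;
  values below 1e-5 are treated as background and removed on load).
* `τij = dij / v` with Euclidean distance `dij` (mm) and conduction speed
  `v` (m/s, default 5); since 1 m/s = 1 mm/ms the quotient is already in ms.
  Control experiments replace this rule with a uniform delay (`τij = τ0`) or
  binarize the weights.
* `ξi` is Gaussian white noise of intensity 0.05 rad·ms^(−1/2). The source
  material states SD = 0.05 without units; we read it as white-noise
  intensity on the millisecond time base, so each 1 ms step receives an
  increment of standard deviation `0.05·√(Δt/ms)` rad.
* `K/N = 0.25` by default, with `N` the total node count for every network,
  including the two-node verification systems.

Functional connectivity is the correlation index
`σij = ⟨cos(θi(t) − θj(t))⟩`, +1 for in-phase, −1 for anti-phase, 0 for
uncorrelated phases. The angle brackets average first over the recording
window within a realization, then over realizations with fresh initial
phases, natural-frequency draws and noise paths (200 realizations of 12 s at
full scale; desk-scale runs shrink both proportionally via a scale factor).
A 95% t-interval across realizations accompanies every ensemble mean.

## Numerical integration

The delay differential equation is advanced with an embedded adaptive
Bogacki–Shampine 3(2) pair inside fixed macro-steps of one recording
interval (1 ms); after each macro-step one Euler–Maruyama noise increment is
added and the state and its derivative are appended to the history grid.
Specifics:

* **Delayed states** are evaluated by cubic Hermite interpolation on the
  macro-step history grid (phase and derivative stored per node per grid
  point), order-matched to the integrator. Delayed times inside the current,
  still-incomplete macro-step extrapolate the last completed segment; the
  derivative stored at a fresh grid point uses the same rule so it never
  reads the segment it terminates. Zero-delay edges use the current stage
  state exactly, so `τ = 0` reduces to the classic Kuramoto model with no
  interpolation error.
* **Pre-history**: each oscillator is held at its initial phase for t < 0.
  The transient discarded before recording (7 s by default) exceeds the
  largest delay by two orders of magnitude, erasing any influence of this
  choice.
* **Error control**: per-substep tolerances `atol = 1e-8`,
  `rtol = 1e-5` on the unwrapped phases (the standard
  `atol + rtol·|y|` scale), step-size exponent 1/3, growth
  capped at 2, minimum substep 0.001 ms. Phases are integrated unwrapped so
  the interpolant never crosses a branch cut, and returned wrapped to
  (−π, π]; σ only ever uses phase differences, so wrapping is safe.
  Delay-free integration agrees with an independent fixed-step RK4
  (dt = 0.01 ms) to better than 1e-10 rad over 1 s on a 5-node network,
  four orders of magnitude inside the 1e-4 rad acceptance bound.
* **Seeding**: realization *r* of an ensemble uses
  `SeedSequence(master).generate_state(r + 1)[-1] mod 2^31`, making
  ensembles reproducible bitwise and independent of execution order.
* Noise placement (inside the adaptive stepper vs at a fixed outer step) is
  not fully determined by the source description; we add it at the fixed
  1 ms macro-step. Halving the macro-step changes ensemble σ estimates by
  less than their across-realization SEM in spot checks, so conclusions do
  not hinge on this choice.

## Two-oscillator locking oracle

For two identical oscillators coupled symmetrically with per-link strength
`κ` (rad/ms) and delay `τ`, in-phase locking satisfies
`Ω = ω − κ sin(Ωτ)` and is stable iff `cos(Ωτ) > 0`; anti-phase locking
satisfies `Ω = ω + κ sin(Ωτ)` and is stable iff `cos(Ωτ) < 0`. Both
branches' roots are found by a bracketed scan of `[ω − κ, ω + κ]` (4001
points) refined with Brent's method — chosen over damped fixed-point
iteration because it finds *all* roots, which matters in the wide bistable
windows at κ = 0.25. The classification (`in_phase`, `anti_phase`,
`bistable`, `drift`) is the package's independent verification oracle: on a
10×10 (ν, τ) grid, noise-free simulations must agree with it on ≥95% of
points away from classification boundaries, with bistable points accepting
either locked outcome.

Two corollaries of the oracle shape the acceptance experiments:

* **Delay sets the rate.** The ensemble-averaged σ(ν) of a pair crosses zero
  near ν* ≈ 1/(4τ) (in kHz·ms units), so doubling the delay halves the
  crossing frequency. The law is exact in the weak-coupling limit; at
  per-link κ = 0.0625 the bistable window (halfwidth κ/2π in ν, independent
  of τ) shifts the crossing additively by several Hz and degrades the
  factor-two ratio to ~1.8. The rate experiment therefore uses link weight
  0.1 (κ = 0.025) — the weak-link regime typical of connectome edges, where
  the ratio is 2.0 on a 2 Hz grid.
* **Weight sets the amplitude.** With noise, the stationary spread of the
  locked phase difference scales inversely with κ·|cos(Ωτ)|, so weaker links
  have |σ| pulled further from 1 throughout the sweep: the peak-to-trough
  amplitude of σ(ν) grows with weight (0.15 vs 0.25 contrast, τ = 10 ms).

## Synthetic connectome generator

Real human connectome matrices are not redistributable here, so a generator
emulates their gross statistics: 66 nodes in two hemispheric 80×100×80 mm
boxes (coordinates rescaled to a 158 mm maximal span), six spatially
clustered modules with dense intra-module (p = 0.65), sparse same-hemisphere
inter-module (0.15) and cross-hemisphere (0.08) wiring plus preferentially
linked homotopic pairs (0.9); guaranteed connectivity by joining components
at their closest node pair; edge weights log-uniform over five decades
multiplied by an exponential distance rule `exp(−d/40 mm)`, renormalized to
max 1, thresholded at 1e-5. The bundled instance (seed 1) spans exactly
5 decades of weight, has negative weight–distance correlation, ~20% density
and delays up to ~28 ms at 5 m/s.

What the generator does *not* emulate: the empirical degree sequence and
hub structure, the log-normal (rather than log-uniform) weight histogram,
geometric cortical folding, and tract-length vs Euclidean-distance
discrepancies. Tests passing on these networks therefore demonstrate the
mechanism (delay- and weight-dependence of frequency-resolved correlations),
not a quantitative fit to any empirical connectome; the similarity-minimum
frequency in particular is expected to match the published ~30 Hz band only
in location of the band, not digit-for-digit.

## Experiment drivers and controls

`run_experiment` executes a frequency sweep (ensemble FC per band, the
structure–function similarity curve, and weight-/distance-binned summaries)
and writes a manifest with every parameter, per-realization seed and output
checksum; reruns are bitwise identical. Binned summaries use half-open bins
of width 0.05 (weight) and 16 mm (distance) centred on a covering grid or on
requested centres, with 95% t-intervals across contributing pairs.

The binary-network control binarizes the weights so distance affects only
the delay. Binarizing at fixed K/N would multiply each node's summed input
by roughly the inverse mean edge weight (weights span five decades) and
drive the network into global synchrony, saturating σ ≈ 1 and hiding
precisely the delay effect the control isolates; the driver therefore
rescales the coupling by the weighted network's mean edge weight, keeping
the mean input strength fixed. The fixed-delay control keeps the weights and
sets every delay to τ0 = 10 ms, so only amplitude differences between weight
bins remain.

## Problem sizes

Default test and acceptance runs use: 20 realizations × 3 s recording
(7 s transient) for the 66-node band sweep; 16 realizations × 1 s for
two-node σ(ν) curves on a 2–70 Hz grid in 2 Hz steps; scale 0.1
(20 realizations × 1.2 s) for the structural controls on a 24-node
synthetic network with a 6 Hz frequency grid. Full scale
(200 × 12 s, 2 Hz grids) is one flag away (`--scale 1`).

## Known limitations

* σ is the only FC estimator; no PLV, coherence or band-filtered variants.
* The similarity distance is computed over directly connected upper-triangle
  pairs by default (an `all`-pairs mask exists); the exact vectorization the
  original analysis used is ambiguous, and the argmin frequency is reported
  at the resolution of the frequency grid used.
* Directed networks are simulated as directed, but σ and the binned
  summaries symmetrize weights as (W + Wᵀ)/2 for pair-level comparisons.
* The stochastic scheme commits to noise at the 1 ms macro-step; very short
  delays (< 1 ms) rely on extrapolated history within the current step.
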