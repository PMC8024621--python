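# phasefc

Frequency-resolved functional connectivity from delay-coupled phase
oscillators on brain connectomes.

Whole-brain electrophysiology (MEG/EEG) shows that the brain's functional
networks differ across frequency bands. This package implements a
computational account of that observation: the generalized Kuramoto model
with distance-dependent transmission delays,

    dθi/dt = ωi + ξi(t) + (K/N) Σj aij sin(θj(t − τij) − θi(t)),

run on a weighted structural connectome (normalized fiber counts or tracer
FLN fractions, plus Euclidean distances in mm). Pairwise synchrony is
measured by the correlation index σij = ⟨cos(θi − θj)⟩ ∈ [−1, 1], averaged
over a 12 s recording window and 200 realizations at full scale. Sweeping
the mean natural frequency ν0 across the theta–high-gamma bands yields one
functional network per band and lets the package quantify two separate
structural influences:

* **transmission delay** (τij = dij / v, conduction speed v = 5 m/s by
  default) sets the *rate* at which a pair's correlation oscillates with
  frequency — the σ(ν) zero crossing scales as 1/(4τ);
* **connection weight** sets the *amplitude* of those oscillations.

It is aimed at computational neuroscientists studying structure–function
coupling in large-scale brain models: it provides the simulator (an adaptive
Bogacki–Shampine 3(2) delay-differential integrator with Euler–Maruyama
noise, numba-accelerated), connectome I/O and a statistics-matched synthetic
connectome generator, correlation-index functional networks with confidence
bands, weight/distance binning, a structure–function similarity distance,
the analytic two-oscillator locking oracle used for verification, and
reproducible experiment drivers with manifests. See `docs/methods.md` for
the numerical details and design choices.

## Worked example

Simulate a two-node system with a 5 ms delay at theta and high-gamma
frequencies, and compare with the analytic locking oracle:

```python
import phasefc as pf

c, delays = pf.two_node_system(weight=1.0, tau_ms=5.0)
for nu in (10.0, 70.0):
    cfg = pf.SimConfig(mean_freq=nu, coupling_scale=0.05, noise_sd=0.0,
                       freq_sd=0.0, t_transient=1.0, t_record=1.0,
                       n_realizations=1)
    traj = pf.simulate(c, delays, cfg, seed=4)
    sigma = pf.correlation_index(traj).sigma[0, 1]
    oracle = pf.two_node_locked_state(K=0.05, tau=5.0, nu=nu)
    print(f"nu = {nu:2.0f} Hz: sigma = {sigma:+.3f}  oracle: {oracle.classification}")
```

prints

```
nu = 10 Hz: sigma = +1.000  oracle: in_phase
nu = 70 Hz: sigma = -1.000  oracle: anti_phase
```

At 10 Hz the round-trip phase lag 2πν·τ ≈ 0.31 rad keeps the pair in-phase
(σ = +1); at 70 Hz the lag ≈ 2.2 rad lies in the anti-phase stability window
(σ = −1). The same mechanism, summed over a whole connectome's delay
distribution, is what makes high-frequency functional networks
anticorrelated at long distances.

A connectome-level sweep from the command line:

```sh
phasefc fig2 --synthetic --synthetic-n 66 --synthetic-seed 1 \
    --scale 0.1 --seed 11 --outdir out/fig2
```

writes one FC matrix per band (3/11/23/35/51 Hz), the structure–function
similarity curve, binned summaries, and a manifest that reproduces the run
bitwise. `phasefc fig4`, `phasefc control-binary` and
`phasefc control-fixed-delay` drive the binned-curve and control
experiments; `phasefc density`, `oracle`, `bin`, `similarity` expose the
individual analyses.

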