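"""Noisy delayed Kuramoto dynamics on a connectome.

Each node i is a phase oscillator

    dtheta_i/dt = omega_i + xi_i(t) + (K/N) * sum_j a_ij sin(theta_j(t - tau_ij) - theta_i(t))

with natural angular frequency ``omega_i = 2 pi nu_i`` (``nu_i`` drawn from a
narrow normal distribution), Gaussian white noise ``xi_i``, coupling weights
``a_ij`` from the structural network and transmission delays ``tau_ij``.

The deterministic part is advanced with an adaptive embedded Bogacki-Shampine
3(2) pair over fixed macro-steps of one recording interval; one
Euler-Maruyama noise increment of standard deviation ``noise_sd * sqrt(dt)``
is added per macro-step.  See :mod:`phasefc._bs23` for the stepper.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._bs23 import integrate
from .connectome import Connectome, DelayMatrix

__all__ = [
    "SimConfig",
    "PhaseTrajectory",
    "draw_natural_frequencies",
    "simulate",
    "run_ensemble",
    "realization_seed",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Attributes
    ----------
    mean_freq : float
        Mean natural frequency nu0 in Hz.
    freq_sd : float
        Standard deviation of the natural-frequency distribution, Hz.
    coupling_scale : float
        Coupling scale K/N (dimensionless), applied to the weighted sum.
    noise_sd : float
        White-noise intensity in rad/sqrt(ms): each macro-step of length
        ``record_dt`` receives a Gaussian increment of sd
        ``noise_sd * sqrt(record_dt)``.
    t_transient : float
        Discarded initial interval, seconds.
    t_record : float
        Recorded interval, seconds.
    record_dt : float
        Recording interval and noise macro-step, ms.
    abs_tol, rel_tol : float
        Local error tolerances of the adaptive stepper.
    min_step : float
        Smallest adaptive substep, ms.
    n_realizations : int
        Ensemble size (fresh initial phases and frequency draws each).
    seed : int
        Master seed; per-realization seeds are spawned from it.
    """

    mean_freq: float = 10.0
    freq_sd: float = 0.1
    coupling_scale: float = 0.25
    noise_sd: float = 0.05
    t_transient: float = 7.0
    t_record: float = 12.0
    record_dt: float = 1.0
    abs_tol: float = 1e-8
    rel_tol: float = 1e-5
    min_step: float = 0.001
    n_realizations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_freq <= 0:
            raise ValueError("mean_freq must be positive")
        if self.freq_sd < 0:
            raise ValueError("freq_sd must be non-negative")
        if min(self.t_transient, self.t_record, self.record_dt, self.min_step) <= 0:
            raise ValueError("all times must be positive")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        # the recording grid must resolve the fastest oscillations
        if self.record_dt > 1000.0 / (4.0 * self.mean_freq):
            raise ValueError(
                "record_dt too coarse for mean_freq: need record_dt <= 1/(4 nu0)"
            )

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PhaseTrajectory:
    """Sampled oscillator phases over the recording window.

    ``times`` is a uniform grid in ms; ``phases`` is an (n, T) array of phases
    wrapped to (-pi, pi].  ``stats`` carries integrator diagnostics
    (accepted/rejected substeps, seed).
    """

    times: np.ndarray
    phases: np.ndarray
    stats: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.phases.shape[0]

    def unwrapped(self) -> np.ndarray:
        """Phases unwrapped along time (diagnostic view)."""
        return np.unwrap(self.phases, axis=1)


def draw_natural_frequencies(
    n: int, nu0: float, sd: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw angular frequencies omega_i = 2 pi nu_i in rad/ms.

    nu_i ~ Normal(nu0, sd) with nu0, sd in Hz.  Deterministic under ``seed``.
    """
    if nu0 <= 0:
        raise ValueError("mean frequency must be positive")
    if sd < 0:
        raise ValueError("frequency sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nu = rng.normal(nu0, sd, size=n)
    return 2.0 * np.pi * nu / 1000.0  # Hz -> rad/ms


def _edge_csr(c: Connectome, delays: DelayMatrix):
    """CSR arrays over receiving rows: inputs to node i are row i's entries."""
    w = c.weights
    rows, cols = np.nonzero(w)
    order = np.argsort(rows, kind="stable")
    rows, cols = rows[order], cols[order]
    indptr = np.zeros(c.n + 1, dtype=np.int64)
    np.add.at(indptr, rows + 1, 1)
    indptr = np.cumsum(indptr)
    return (
        indptr,
        cols.astype(np.int64),
        w[rows, cols].astype(np.float64),
        delays.tau[rows, cols].astype(np.float64),
    )


def simulate(
    c: Connectome,
    delays: DelayMatrix,
    config: SimConfig,
    seed: int | None = None,
) -> PhaseTrajectory:
    """Integrate one realization and return the post-transient trajectory.

    Initial phases are uniform on [0, 2pi); the pre-history for t < 0 holds
    each oscillator at its initial phase.  ``seed`` (default ``config.seed``)
    controls initial phases, the natural-frequency draw and the noise path.
    """
    if delays.tau.shape != c.weights.shape:
        raise ValueError("delay matrix incompatible with connectome")
    if np.any((delays.tau > 0) & ~c.edge_mask):
        raise ValueError("delays present on non-edges")
    t_transient_ms = config.t_transient * 1000.0
    if delays.max_delay_ms >= t_transient_ms:
        raise ValueError("max delay must be smaller than the transient window")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=c.n)
    omega = draw_natural_frequencies(c.n, config.mean_freq, config.freq_sd, rng)

    dt = config.record_dt
    n_trans = int(round(t_transient_ms / dt))
    n_rec = int(round(config.t_record * 1000.0 / dt))
    n_steps = n_trans + n_rec
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd * np.sqrt(dt), size=(n_steps, c.n))
    else:
        noise = np.zeros((n_steps, c.n))

    indptr, cols, wts, taus = _edge_csr(c, delays)
    hist, n_accept, n_reject, ok = integrate(
        theta0,
        omega,
        indptr,
        cols,
        wts,
        taus,
        config.coupling_scale,
        dt,
        n_steps,
        noise,
        config.abs_tol,
        config.rel_tol,
        config.min_step,
    )
    if not ok:
        raise FloatingPointError(
            f"non-finite state during integration at macro-step {n_accept}"
        )
    times = t_transient_ms + dt * np.arange(n_rec + 1)
    phases = hist[n_trans:].T  # (n, n_rec + 1), unwrapped
    wrapped = ((phases + np.pi) % (2.0 * np.pi)) - np.pi
    # map -pi -> pi so the interval is (-pi, pi]
    wrapped[wrapped == -np.pi] = np.pi
    return PhaseTrajectory(
        times=times,
        phases=wrapped,
        stats={
            "n_accept": int(n_accept),
            "n_reject": int(n_reject),
            "seed": int(config.seed if seed is None else seed),
        },
    )


def realization_seed(master_seed: int, r: int) -> int:
    """Stable per-realization seed: SeedSequence(master).spawn, folded to < 2^31.

    Documented contract: realization r uses
    ``SeedSequence(master_seed).generate_state(r + 1)[-1] % 2**31``.
    """
    state = np.random.SeedSequence(master_seed).generate_state(r + 1, dtype=np.uint64)
    return int(state[-1] % (2**31))


def run_ensemble(
    c: Connectome,
    delays: DelayMatrix,
    config: SimConfig,
) -> list[PhaseTrajectory]:
    """Run ``config.n_realizations`` independent realizations.

    Each realization gets fresh initial phases, a fresh natural-frequency draw
    and a fresh noise path, with per-realization seeds derived reproducibly
    from ``config.seed`` via :func:`realization_seed`.
    """
    return [
        simulate(c, delays, config, seed=realization_seed(config.seed, r))
        for r in range(config.n_realizations)
    ]
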