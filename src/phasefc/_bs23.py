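"""Adaptive Bogacki-Shampine 3(2) core for the noisy delayed Kuramoto system.

The delay differential equation is advanced deterministically over fixed
macro-steps of one recording interval each; after every macro-step a single
Gaussian increment (Euler-Maruyama) is added.  Delayed states are evaluated by
cubic Hermite interpolation on the macro-step grid, where both the phase and
its derivative are stored.  Phases are kept unwrapped internally so the
interpolant never sees a branch cut.

All times are in ms, angular frequencies in rad/ms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TWO_PI = 2.0 * np.pi


@njit(cache=True, inline="always")
def _hist_eval(td, j, filled, hist_th, hist_dth, dt):
    """Cubic Hermite evaluation of oscillator j's phase at time td.

    ``filled`` is the index of the last completed grid point.  Times before 0
    return the initial phase (constant pre-history); times beyond the filled
    grid extrapolate the last completed segment.
    """
    if td <= 0.0:
        return hist_th[0, j]
    m = int(td / dt)
    if m >= filled:
        m = filled - 1
        if m < 0:
            # nothing integrated yet: linear extrapolation from t = 0
            return hist_th[0, j] + hist_dth[0, j] * td
    s = td / dt - m
    s2 = s * s
    s3 = s2 * s
    y0 = hist_th[m, j]
    y1 = hist_th[m + 1, j]
    d0 = hist_dth[m, j] * dt
    d1 = hist_dth[m + 1, j] * dt
    return (
        (2.0 * s3 - 3.0 * s2 + 1.0) * y0
        + (s3 - 2.0 * s2 + s) * d0
        + (-2.0 * s3 + 3.0 * s2) * y1
        + (s3 - s2) * d1
    )


@njit(cache=True)
def _rhs(t, y, filled, hist_th, hist_dth, dt, omega, kc, indptr, cols, wts, taus, out):
    n = y.shape[0]
    for i in range(n):
        acc = 0.0
        for e in range(indptr[i], indptr[i + 1]):
            j = cols[e]
            tau = taus[e]
            if tau == 0.0:
                thj = y[j]  # exact: reduces to the classic (delay-free) model
            else:
                thj = _hist_eval(t - tau, j, filled, hist_th, hist_dth, dt)
            acc += wts[e] * np.sin(thj - y[i])
        out[i] = omega[i] + kc * acc


@njit(cache=True)
def integrate(
    theta0,
    omega,
    indptr,
    cols,
    wts,
    taus,
    kc,
    dt,
    n_steps,
    noise,
    atol,
    rtol,
    min_step,
):
    """Integrate the delayed Kuramoto system over ``n_steps`` macro-steps.

    Parameters
    ----------
    theta0 : (n,) initial phases (rad); also the constant history for t < 0.
    omega : (n,) natural angular frequencies, rad/ms.
    indptr, cols, wts, taus : CSR edge structure; row i lists inputs to i.
    kc : coupling scale K/N.
    dt : macro-step = recording interval, ms.
    noise : (n_steps, n) pre-scaled Gaussian increments added per macro-step.
    atol, rtol : per-substep error tolerances; the relative part is measured
        against the phase wrapped to (-pi, pi] so accuracy does not degrade as
        the unwrapped phase grows.
    min_step : smallest adaptive substep, ms.

    Returns
    -------
    hist_th : (n_steps + 1, n) unwrapped phases on the macro grid.
    n_accept, n_reject : adaptive-substep statistics.
    ok : False if a non-finite state appeared (with step index in n_accept).
    """
    n = theta0.shape[0]
    hist_th = np.empty((n_steps + 1, n))
    hist_dth = np.empty((n_steps + 1, n))
    hist_th[0] = theta0
    _rhs(0.0, theta0, 0, hist_th, hist_dth, dt, omega, kc, indptr, cols, wts, taus, hist_dth[0])

    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    ytmp = np.empty(n)
    ynew = np.empty(n)
    y = theta0.copy()

    n_accept = 0
    n_reject = 0
    h_prop = dt  # controller's proposed substep, persists across macro-steps

    for step in range(n_steps):
        t = step * dt
        t_end = t + dt
        for i in range(n):
            k1[i] = hist_dth[step, i]
        while t < t_end - 1e-12:
            rem = t_end - t
            h = h_prop if h_prop < rem else rem
            if h < min_step:
                h = min_step
            for i in range(n):
                ytmp[i] = y[i] + 0.5 * h * k1[i]
            _rhs(t + 0.5 * h, ytmp, step, hist_th, hist_dth, dt, omega, kc, indptr, cols, wts, taus, k2)
            for i in range(n):
                ytmp[i] = y[i] + 0.75 * h * k2[i]
            _rhs(t + 0.75 * h, ytmp, step, hist_th, hist_dth, dt, omega, kc, indptr, cols, wts, taus, k3)
            for i in range(n):
                ynew[i] = y[i] + h * (
                    (2.0 / 9.0) * k1[i] + (1.0 / 3.0) * k2[i] + (4.0 / 9.0) * k3[i]
                )
            _rhs(t + h, ynew, step, hist_th, hist_dth, dt, omega, kc, indptr, cols, wts, taus, k4)
            # embedded 2nd-order error estimate
            err_norm = 0.0
            for i in range(n):
                e = h * (
                    (2.0 / 9.0 - 7.0 / 24.0) * k1[i]
                    + (1.0 / 3.0 - 1.0 / 4.0) * k2[i]
                    + (4.0 / 9.0 - 1.0 / 3.0) * k3[i]
                    - (1.0 / 8.0) * k4[i]
                )
                sc = atol + rtol * abs(ynew[i])
                r = e / sc
                err_norm += r * r
            err_norm = np.sqrt(err_norm / n)
            accepted = err_norm <= 1.0 or h <= min_step
            if accepted:
                t += h
                for i in range(n):
                    y[i] = ynew[i]
                    k1[i] = k4[i]  # FSAL
                n_accept += 1
            else:
                n_reject += 1
            if err_norm > 1e-300:
                fac = 0.9 * err_norm ** (-1.0 / 3.0)
            else:
                fac = 2.0
            if fac < 0.2:
                fac = 0.2
            elif fac > 2.0:
                fac = 2.0
            cand = h * fac
            if accepted and h < h_prop:
                # endpoint-truncated step: don't let it shrink the proposal
                if cand > h_prop:
                    h_prop = cand
            else:
                h_prop = cand
            if h_prop < min_step:
                h_prop = min_step
        # Euler-Maruyama noise increment at the end of the macro-step
        for i in range(n):
            y[i] += noise[step, i]
            if not np.isfinite(y[i]):
                return hist_th, step, n_reject, False
            hist_th[step + 1, i] = y[i]
        # Derivative at the new grid point.  Delays shorter than one
        # macro-step would make this self-referential (the segment ending at
        # step+1 needs the derivative being computed), so the last completed
        # segment is [step-1, step]: sub-dt delayed states extrapolate it,
        # matching the in-step policy.
        _rhs(
            t_end, y, step, hist_th, hist_dth, dt,
            omega, kc, indptr, cols, wts, taus, hist_dth[step + 1],
        )
        for i in range(n):
            if not np.isfinite(hist_dth[step + 1, i]):
                return hist_th, step, n_reject, False
    return hist_th, n_accept, n_reject, True
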