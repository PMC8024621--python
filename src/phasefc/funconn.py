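"""Correlation-index functional connectivity.

The pairwise synchrony measure is the correlation index

    sigma_ij = < cos(theta_i(t) - theta_j(t)) >

averaged over the recording window and, for ensembles, over realizations with
fresh initial conditions.  sigma is 1 for fully correlated (in-phase) pairs,
-1 for anti-correlated (anti-phase) pairs and 0 for uncorrelated phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .dynamics import PhaseTrajectory

__all__ = ["FCMatrix", "correlation_index", "ensemble_fc"]


@dataclass
class FCMatrix:
    """Symmetric correlation-index matrix with ensemble metadata.

    ``sigma`` is (n, n) in [-1, 1] with unit diagonal.  ``sem`` (optional) is
    the across-realization standard error of each element, supporting 95%
    confidence bands.
    """

    sigma: np.ndarray
    mean_freq: float | None = None
    n_realizations_averaged: int = 1
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(s, s.T, atol=1e-9):
            raise ValueError("sigma must be symmetric")
        if np.any(np.abs(s) > 1.0 + 1e-9):
            raise ValueError("sigma entries must lie in [-1, 1]")
        self.sigma = s

    @property
    def n(self) -> int:
        return self.sigma.shape[0]

    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        """95% t-interval (low, high) of each element across realizations."""
        if self.sem is None or self.n_realizations_averaged < 2:
            return self.sigma.copy(), self.sigma.copy()
        tcrit = stats.t.ppf(0.975, self.n_realizations_averaged - 1)
        return self.sigma - tcrit * self.sem, self.sigma + tcrit * self.sem

    def write(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write sigma as tab-delimited text plus a small metadata sidecar."""
        np.savetxt(path, self.sigma, fmt="%.12g", delimiter="\t")
        if meta_path is not None:
            import json

            meta = {
                "mean_freq_hz": self.mean_freq,
                "n_realizations_averaged": self.n_realizations_averaged,
            }
            Path(meta_path).write_text(json.dumps(meta, indent=1) + "\n")


def correlation_index(traj: PhaseTrajectory) -> FCMatrix:
    """Time-averaged correlation index of one trajectory.

    sigma_ij = mean_t cos(theta_i(t) - theta_j(t)), computed via complex
    exponentials: sigma = Re(Z Z*ᵀ) / T with Z = exp(i theta).
    """
    if traj.phases.size == 0 or traj.phases.shape[1] == 0:
        raise ValueError("empty trajectory")
    z = np.exp(1j * traj.phases)
    sigma = (z @ z.conj().T).real / traj.phases.shape[1]
    sigma = (sigma + sigma.T) / 2.0
    np.clip(sigma, -1.0, 1.0, out=sigma)
    np.fill_diagonal(sigma, 1.0)
    return FCMatrix(sigma=sigma)


def ensemble_fc(
    trajs: list[PhaseTrajectory], mean_freq: float | None = None
) -> FCMatrix:
    """Element-wise mean of per-realization correlation indices.

    Time-averaging happens first within each realization, then the realization
    average; the across-realization SEM is retained for confidence bands.
    """
    if not trajs:
        raise ValueError("empty trajectory list")
    shapes = {t.phases.shape for t in trajs}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous trajectory shapes: {shapes}")
    stack = np.stack([correlation_index(t).sigma for t in trajs])
    mean = stack.mean(axis=0)
    r = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(r) if r > 1 else None
    np.fill_diagonal(mean, 1.0)
    return FCMatrix(
        sigma=mean, mean_freq=mean_freq, n_realizations_averaged=r, sem=sem
    )
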