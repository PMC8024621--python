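"""Structural connectomes: containers, file I/O, synthetic generation, delays.

A connectome here is a weighted graph between brain regions together with the
Euclidean distances between the regions.  Weights are dimensionless coupling
strengths normalized to a maximum of 1 (fiber counts or tracer FLN fractions
after rescaling); distances are in millimetres.  Signal-transmission delays are
derived from the distances assuming a constant conduction speed, or set to a
uniform value for control experiments.

Unit convention (package-wide): time in ms, frequency in Hz, distance in mm,
speed in m/s.  1 m/s equals 1 mm/ms, so ``tau_ms = d_mm / speed_m_per_s``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

#: Weights below this value are treated as absent edges.  Empirical connectome
#: dumps use tiny positive values as numerical background; normalized fiber
#: counts span roughly five orders of magnitude down from 1, so anything below
#: 1e-5 carries no signal.
WEIGHT_EPS = 1e-5

_DIST_SYM_RTOL = 1e-6


class ConnectomeError(ValueError):
    """Raised for structurally invalid connectome data."""


@dataclass
class Connectome:
    """Weighted structural network with inter-node Euclidean distances.

    Parameters
    ----------
    weights
        ``(n, n)`` non-negative coupling matrix, zero diagonal, max <= 1.
        ``weights[i, j] > 0`` means node *j* projects onto node *i*.
    distances
        ``(n, n)`` symmetric non-negative Euclidean distance matrix in mm with
        zero diagonal.  Every edge must have a positive distance.
    directed
        If False, ``weights`` must be symmetric.
    hemisphere
        Optional per-node ``'L'``/``'R'`` labels.
    module
        Optional per-node integer community labels.
    coords
        Optional ``(n, 3)`` node coordinates in mm (synthetic connectomes).
    weight_scale
        Factor by which raw weights were divided during normalization.
    """

    weights: np.ndarray
    distances: np.ndarray
    directed: bool = False
    hemisphere: np.ndarray | None = None
    module: np.ndarray | None = None
    coords: np.ndarray | None = None
    weight_scale: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.hemisphere is not None:
            self.hemisphere = np.asarray(self.hemisphere)
        if self.module is not None:
            self.module = np.asarray(self.module, dtype=int)
        self.validate()

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        """Number of nodes."""
        return self.weights.shape[0]

    @property
    def edge_mask(self) -> np.ndarray:
        """Boolean (n, n) mask of existing edges (positive weight)."""
        return self.weights > 0

    @property
    def n_edges(self) -> int:
        """Number of edges: directed entries, or unordered pairs if undirected."""
        m = int(np.count_nonzero(self.weights))
        return m if self.directed else m // 2

    def validate(self) -> None:
        w, d = self.weights, self.distances
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weights must be square, got shape {w.shape}")
        if d.shape != w.shape:
            raise ConnectomeError(
                f"dimension mismatch: weights {w.shape} vs distances {d.shape}"
            )
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(d)):
            raise ConnectomeError("non-finite entries in weights or distances")
        if np.any(w < 0):
            raise ConnectomeError("negative weights")
        if np.any(np.diag(w) != 0):
            raise ConnectomeError("weights diagonal must be zero")
        if w.max(initial=0.0) > 1.0 + 1e-12:
            raise ConnectomeError("weights must not exceed 1 (normalize first)")
        if np.any(d < 0) or np.any(np.diag(d) != 0):
            raise ConnectomeError("distances must be non-negative with zero diagonal")
        if not np.allclose(d, d.T, rtol=_DIST_SYM_RTOL, atol=1e-9):
            raise ConnectomeError("distance matrix is asymmetric beyond tolerance")
        if not self.directed and not np.allclose(w, w.T, rtol=1e-9, atol=1e-12):
            raise ConnectomeError("undirected connectome requires symmetric weights")
        if np.any((w > 0) & (d <= 0)):
            raise ConnectomeError("every edge must have a positive distance")
        for name in ("hemisphere", "module"):
            lab = getattr(self, name)
            if lab is not None and lab.shape != (w.shape[0],):
                raise ConnectomeError(f"{name} labels must have length n")

    # -- derived views ----------------------------------------------------
    def edge_list(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) index arrays of connected pairs.

        A pair counts as connected if an edge exists in either direction.
        """
        conn = self.edge_mask
        if self.directed:
            conn = conn | conn.T
        iu, ju = np.triu_indices(self.n, k=1)
        keep = conn[iu, ju]
        return iu[keep], ju[keep]

    def symmetric_weights(self) -> np.ndarray:
        """Weights symmetrized as (W + W.T) / 2 (identity for undirected)."""
        return (self.weights + self.weights.T) / 2.0


@dataclass(frozen=True)
class DelayMatrix:
    """Per-edge transmission delays in ms.

    ``tau[i, j]`` is the delay on the edge from *j* to *i*; zero where there is
    no edge.  ``speed`` records the conduction speed in m/s when delays are
    distance-derived, ``tau0`` the uniform delay when they are fixed.
    """

    tau: np.ndarray
    speed: float | None = None
    tau0: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau", np.asarray(self.tau, dtype=float))
        if np.any(self.tau < 0) or not np.all(np.isfinite(self.tau)):
            raise ValueError("delays must be finite and non-negative")

    @property
    def max_delay_ms(self) -> float:
        return float(self.tau.max(initial=0.0))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path, header: bool = False) -> np.ndarray:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    skiprows = 1 if header else 0
    try:
        arr = np.loadtxt(path, delimiter=delimiter, skiprows=skiprows, ndmin=2)
    except ValueError:
        if not header:
            raise
        arr = None
    if header:
        # drop a leading label column as well
        raw = np.loadtxt(
            path, delimiter=delimiter, skiprows=1, dtype=str, ndmin=2
        )
        arr = raw[:, 1:].astype(float)
    return arr


def load_connectome(
    weights_file: str | Path,
    distances_file: str | Path,
    directed: bool = False,
    header: bool = False,
    weight_eps: float = WEIGHT_EPS,
) -> Connectome:
    """Load a connectome from two delimited square matrix files.

    Files may be whitespace- or comma-delimited.  ``header=True`` skips one
    label row and column.  Raw weights are rescaled so the maximum is 1 (the
    applied factor is recorded in ``weight_scale``), the diagonal is cleared,
    and weights below ``weight_eps`` are treated as absent.
    """
    w = _read_matrix(weights_file, header=header)
    d = _read_matrix(distances_file, header=header)
    if w.shape != d.shape or w.shape[0] != w.shape[1]:
        raise ConnectomeError(
            f"matrix files must be square and matched: {w.shape} vs {d.shape}"
        )
    if np.any(w < 0):
        raise ConnectomeError("negative weights in input file")
    np.fill_diagonal(w, 0.0)
    np.fill_diagonal(d, 0.0)
    scale = float(w.max())
    if scale > 0 and not np.isclose(scale, 1.0):
        w = w / scale
    else:
        scale = 1.0
    w[w < weight_eps] = 0.0
    if not directed:
        w = np.maximum(w, w.T)  # tolerate minor asymmetry in undirected dumps
    d = (d + d.T) / 2.0
    return Connectome(weights=w, distances=d, directed=directed, weight_scale=scale)


def write_connectome(
    c: Connectome,
    weights_file: str | Path,
    distances_file: str | Path,
    fmt: str = "%.12g",
) -> None:
    """Write the weight and distance matrices as tab-delimited text."""
    np.savetxt(weights_file, c.weights, fmt=fmt, delimiter="\t")
    np.savetxt(distances_file, c.distances, fmt=fmt, delimiter="\t")


# ---------------------------------------------------------------------------
# Synthetic connectomes
# ---------------------------------------------------------------------------

def generate_synthetic_connectome(
    n: int,
    n_modules: int = 6,
    weight_decades: int = 5,
    decay_length_mm: float = 40.0,
    seed: int = 0,
    p_intra: float = 0.65,
    p_inter: float = 0.15,
    p_cross: float = 0.08,
    p_homotopic: float = 0.9,
    max_span_mm: float = 158.0,
) -> Connectome:
    """Generate a human-like modular, spatially embedded connectome.

    Emulates the gross statistics of cortical connectomes: two hemispheric
    blocks, ``n_modules`` spatial communities with dense intra-module and
    sparse inter-module wiring, edge weights spanning ``weight_decades`` orders
    of magnitude, and an exponential fall-off of weight with distance
    (length constant ``decay_length_mm``) so strong links concentrate at short
    range.  Nodes are placed in two 80x100x80 mm boxes and coordinates are
    rescaled so the largest inter-node distance is ``max_span_mm``.

    Deterministic for a given ``seed``; the result is undirected.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if weight_decades < 1:
        raise ValueError("weight_decades must be >= 1")
    rng = np.random.default_rng(seed)

    n_left = (n + 1) // 2
    hemisphere = np.array(["L"] * n_left + ["R"] * (n - n_left))

    # modules split as evenly as possible across hemispheres
    mods_left = (n_modules + 1) // 2
    module = np.empty(n, dtype=int)
    module[:n_left] = np.arange(n_left) * mods_left // max(n_left, 1)
    module[n_left:] = mods_left + np.arange(n - n_left) * (
        n_modules - mods_left
    ) // max(n - n_left, 1)
    module = np.clip(module, 0, n_modules - 1)

    # spatially clustered module centres inside each hemispheric box
    box = np.array([80.0, 100.0, 80.0])
    offset = np.array([82.0, 0.0, 0.0])  # right-hemisphere box shifted in x
    centers = rng.uniform(0.15, 0.85, size=(n_modules, 3)) * box
    coords = np.empty((n, 3))
    for i in range(n):
        jitter = rng.uniform(-20.0, 20.0, size=3)
        pos = np.clip(centers[module[i]] + jitter, 0.0, box)
        if hemisphere[i] == "R":
            pos = pos + offset
        coords[i] = pos
    diff = coords[:, None, :] - coords[None, :, :]
    distances = np.sqrt((diff**2).sum(axis=-1))
    dmax = distances.max()
    if dmax > 0:
        coords *= max_span_mm / dmax
        distances *= max_span_mm / dmax

    # modular edge placement
    iu, ju = np.triu_indices(n, k=1)
    same_mod = module[iu] == module[ju]
    same_hemi = hemisphere[iu] == hemisphere[ju]
    p = np.where(same_mod, p_intra, np.where(same_hemi, p_inter, p_cross))
    # homotopic (mirror) pairs link hemispheres preferentially
    homot = (~same_hemi) & (iu + n_left == ju)
    p = np.where(homot, p_homotopic, p)
    edge = rng.random(p.shape) < p

    adj = np.zeros((n, n), dtype=bool)
    adj[iu[edge], ju[edge]] = True
    adj |= adj.T

    # guarantee a connected graph: join components via their closest node pair
    ncomp, labels = connected_components(csr_matrix(adj), directed=False)
    while ncomp > 1:
        in0 = labels == labels[0]
        d_cross = distances.copy()
        d_cross[~in0, :] = np.inf
        d_cross[:, in0] = np.inf
        i, j = np.unravel_index(np.argmin(d_cross), d_cross.shape)
        adj[i, j] = adj[j, i] = True
        ncomp, labels = connected_components(csr_matrix(adj), directed=False)

    # log-uniform weights shaped by an exponential distance rule
    w = np.zeros((n, n))
    ei, ej = np.nonzero(np.triu(adj, k=1))
    raw = 10.0 ** (-rng.uniform(0.0, weight_decades, size=ei.size))
    raw *= np.exp(-distances[ei, ej] / decay_length_mm)
    w[ei, ej] = raw
    w += w.T
    w /= w.max()
    w[w < WEIGHT_EPS] = 0.0

    return Connectome(
        weights=w,
        distances=distances,
        directed=False,
        hemisphere=hemisphere,
        module=module,
        coords=coords,
    )


def weight_distance_correlation(c: Connectome, log_weights: bool = False) -> float:
    """Pearson correlation between weight and distance over existing edges."""
    i, j = c.edge_list()
    w = c.symmetric_weights()[i, j]
    d = c.distances[i, j]
    if log_weights:
        w = np.log10(w)
    return float(np.corrcoef(w, d)[0, 1])


# ---------------------------------------------------------------------------
# Transforms and delays
# ---------------------------------------------------------------------------

def binarize(c: Connectome) -> Connectome:
    """Replace every positive weight by exactly 1; distances unchanged."""
    w = (c.weights > 0).astype(float)
    return dataclasses.replace(c, weights=w)


def compute_delays(c: Connectome, speed: float) -> DelayMatrix:
    """Distance-proportional delays: ``tau_ij = d_ij / speed`` on edges (ms).

    ``speed`` is in m/s; since 1 m/s = 1 mm/ms, the quotient of mm by m/s is
    already in ms.  Non-edges get zero delay.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    tau = np.where(c.edge_mask, c.distances / speed, 0.0)
    return DelayMatrix(tau=tau, speed=float(speed))


def uniform_delays(c: Connectome, tau0: float) -> DelayMatrix:
    """Fixed delay ``tau0`` (ms) on every edge; zero on non-edges."""
    if tau0 < 0:
        raise ValueError("tau0 must be non-negative")
    tau = np.where(c.edge_mask, float(tau0), 0.0)
    return DelayMatrix(tau=tau, tau0=float(tau0))
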