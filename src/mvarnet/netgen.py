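"""Ground-truth network generation for MVAR benchmarks.

A network configuration is a directed connectivity matrix ``A`` (the AR
coefficients of the noise-diffusion dynamics ``x_t = A x_{t-1} + zeta_t``)
plus the covariance ``Sigma`` of the Gaussian innovations ``zeta_t``.  Four
topology families are supported:

``random``
    Erdos-Renyi: every entry (including the diagonal, i.e. self-connections)
    exists independently with probability ``density``.
``modular``
    Two equal groups linked only through a small set of hub nodes; no direct
    edges between non-hub nodes of different groups.
``hierarchical``
    Three feedforward layers: one center node projecting to 5-10 intermediate
    nodes, each projecting to 5-10 leaves; every node keeps a self-connection.
    Much sparser than the other families.
``ei``
    Random topology in which a fraction of source nodes is inhibitory: all of
    their outgoing weights are negative.

Weights of existing edges are drawn uniformly on ``[w_min, w_max]``.
Stationarity is enforced by rescaling all weights by ``0.95 / rho`` whenever
the companion spectral radius ``rho`` reaches 0.95; the factor is recorded on
the returned object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from ._seeds import rng_from
from .exceptions import (
    DegenerateConfigurationError,
    ParameterError,
    ShapeError,
)

Topology = Literal["random", "modular", "hierarchical", "ei"]

#: Companion spectral radius above which weights are rescaled.
STABILITY_RADIUS = 0.95

_MAX_RESCALE_ITER = 8


@dataclass
class ConnectivityMatrix:
    """Ground-truth (or estimated) connectivity of an MVAR network.

    ``weights[i, j]`` is the coefficient of the directed edge j -> i.  For
    order-2 configurations ``weights2``/``mask2`` hold the second-lag matrix;
    a given edge is nonzero in at most one of the two.
    """

    weights: np.ndarray
    mask: np.ndarray
    topology_tag: str = "random"
    weights2: np.ndarray | None = None
    mask2: np.ndarray | None = None
    node_labels: np.ndarray | None = None
    rescale_factor: float = 1.0
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def order(self) -> int:
        return 2 if self.weights2 is not None else 1

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ShapeError(f"connectivity must be square, got {w.shape}")
        self.weights = w
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != w.shape:
            raise ShapeError("mask shape does not match weights")


@dataclass
class InputCovariance:
    """Innovation covariance ``Sigma = M M^T`` with its mixing matrix M."""

    sigma: np.ndarray
    mixing: np.ndarray
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.sigma.shape[0]


def companion_matrix(conn: ConnectivityMatrix) -> np.ndarray:
    """Companion form: A itself for order 1, the 2N x 2N block matrix
    ``[[A1, A2], [I, 0]]`` for order 2."""
    a1 = conn.weights
    if conn.order == 1:
        return a1
    n = a1.shape[0]
    top = np.hstack([a1, conn.weights2])
    bottom = np.hstack([np.eye(n), np.zeros((n, n))])
    return np.vstack([top, bottom])


def companion_spectral_radius(conn: ConnectivityMatrix | np.ndarray) -> float:
    """Largest eigenvalue modulus of the (companion-form) connectivity."""
    if isinstance(conn, np.ndarray):
        a = np.asarray(conn, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ShapeError(f"expected square matrix, got {a.shape}")
        c = a
    else:
        c = companion_matrix(conn)
    if not np.all(np.isfinite(c)):
        raise ParameterError("connectivity contains non-finite weights")
    if c.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(c))))


def _random_mask(rng, n, density, include_diagonal=True):
    mask = rng.random((n, n)) < density
    if not include_diagonal:
        np.fill_diagonal(mask, False)
    return mask


def _modular_mask(rng, n, density):
    """Two equal groups plus hubs; hubs connect into and from both groups."""
    hub_fraction = rng.uniform(0.05, 0.15)
    n_hub = max(1, int(round(hub_fraction * n)))
    n_rest = n - n_hub
    n_g1 = n_rest // 2
    labels = np.empty(n, dtype=object)
    labels[:n_g1] = "group1"
    labels[n_g1:n_rest] = "group2"
    labels[n_rest:] = "hub"
    g1 = np.arange(n_g1)
    g2 = np.arange(n_g1, n_rest)
    hubs = np.arange(n_rest, n)

    mask = np.zeros((n, n), dtype=bool)
    for grp in (g1, g2):
        mask[np.ix_(grp, grp)] = rng.random((len(grp), len(grp))) < density
    # hub <-> group edges, both directions, plus hub-hub
    for grp in (g1, g2):
        mask[np.ix_(grp, hubs)] = rng.random((len(grp), n_hub)) < density
        mask[np.ix_(hubs, grp)] = rng.random((n_hub, len(grp))) < density
    mask[np.ix_(hubs, hubs)] = rng.random((n_hub, n_hub)) < density
    # diagonal (self-connections) at the same density
    diag = rng.random(n) < density
    mask[np.diag_indices(n)] = diag
    # guarantee every hub projects into both groups
    for h in hubs:
        for grp in (g1, g2):
            if not mask[grp, h].any():
                mask[rng.choice(grp), h] = True
    return mask, labels


def _hierarchical_mask(rng, n_branches=None, n_leaves=None):
    """One center -> B intermediates -> L leaves each; self edges everywhere."""
    b = int(n_branches) if n_branches is not None else int(rng.integers(5, 11))
    leaves = int(n_leaves) if n_leaves is not None else int(rng.integers(5, 11))
    n = 1 + b + b * leaves
    labels = np.empty(n, dtype=object)
    labels[0] = "center"
    labels[1 : 1 + b] = "intermediate"
    labels[1 + b :] = "leaf"
    mask = np.zeros((n, n), dtype=bool)
    mask[1 : 1 + b, 0] = True  # center -> intermediate
    for k in range(b):
        lo = 1 + b + k * leaves
        mask[lo : lo + leaves, 1 + k] = True  # intermediate -> its leaves
    mask[np.diag_indices(n)] = True
    return mask, labels


def generate_connectivity(
    topology: Topology = "random",
    n: int | None = 70,
    density: float = 0.2,
    w_min: float = 0.01,
    w_max: float = 0.05,
    seed: int = 0,
    *,
    order: int = 1,
    inhibitory_ratio: float = 0.2,
    include_diagonal: bool = True,
    n_branches: int | None = None,
    n_leaves: int | None = None,
) -> ConnectivityMatrix:
    """Draw a ground-truth connectivity matrix.

    Parameters
    ----------
    topology : {"random", "modular", "hierarchical", "ei"}
    n : network size (ignored for hierarchical, where it follows from the
        branching draw).
    density : edge probability in [0, 1] (random/modular/ei).
    w_min, w_max : bounds of the uniform weight distribution.
    order : 1 or 2.  For order 2 each drawn edge is assigned to exactly one
        of the two lag matrices with equal probability.
    inhibitory_ratio : for ``ei``, fraction of source nodes whose outgoing
        weights are negated.
    include_diagonal : whether random/ei topologies may carry
        self-connections (each with probability ``density``).

    Deterministic given ``seed``.  Weights are rescaled for stationarity
    whenever the companion spectral radius reaches 0.95.
    """
    if not 0.0 <= density <= 1.0:
        raise ParameterError(f"density must lie in [0, 1], got {density}")
    if w_min > w_max:
        raise ParameterError(f"w_min={w_min} > w_max={w_max}")
    if w_min < 0:
        raise ParameterError("weights must be nonnegative (ei negates them per source)")
    if order not in (1, 2):
        raise ParameterError(f"order must be 1 or 2, got {order}")
    if topology != "hierarchical" and (n is None or n < 2):
        raise ParameterError("need n >= 2 nodes")

    rng = rng_from(seed, 0)
    labels = None
    if topology in ("random", "ei"):
        mask = _random_mask(rng, n, density, include_diagonal)
    elif topology == "modular":
        mask, labels = _modular_mask(rng, n, density)
    elif topology == "hierarchical":
        mask, labels = _hierarchical_mask(rng, n_branches, n_leaves)
        n = mask.shape[0]
    else:
        raise ParameterError(f"unknown topology {topology!r}")

    weights = np.zeros((n, n))
    weights[mask] = rng.uniform(w_min, w_max, size=int(mask.sum()))
    if w_min == w_max:
        weights[mask] = w_min

    if topology == "ei":
        if not 0.0 <= inhibitory_ratio <= 1.0:
            raise ParameterError("inhibitory_ratio must lie in [0, 1]")
        n_inh = int(round(inhibitory_ratio * n))
        inh = set(rng.choice(n, size=n_inh, replace=False).tolist())
        weights[:, sorted(inh)] *= -1.0
        labels = np.array(["inhibitory" if i in inh else "excitatory" for i in range(n)], dtype=object)

    weights2 = mask2 = None
    if order == 2:
        # each existing edge lives in exactly one of the two lag matrices
        in_second = rng.random((n, n)) < 0.5
        mask2 = mask & in_second
        mask = mask & ~in_second
        weights2 = np.where(mask2, weights, 0.0)
        weights = np.where(mask, weights, 0.0)

    conn = ConnectivityMatrix(
        weights=weights,
        mask=mask,
        topology_tag=topology,
        weights2=weights2,
        mask2=mask2,
        node_labels=labels,
        seed=seed,
    )

    factor = 1.0
    for _ in range(_MAX_RESCALE_ITER):
        rho = companion_spectral_radius(conn)
        if rho < STABILITY_RADIUS:
            break
        step = STABILITY_RADIUS / rho * (1.0 - 1e-12)
        # scaling A1 by s and A2 by s^2 scales companion eigenvalues by s
        conn.weights = conn.weights * step
        if conn.weights2 is not None:
            conn.weights2 = conn.weights2 * step**2
        factor *= step
    else:
        raise DegenerateConfigurationError(
            f"could not stabilize configuration (rho={companion_spectral_radius(conn):.3f})"
        )
    conn.rescale_factor = factor
    return conn


def generate_input_covariance(
    n: int, cross_corr_strength: float = 0.0, seed: int = 0
) -> InputCovariance:
    """Innovation covariance by mixing independent Gaussian processes.

    ``Sigma = M M^T`` with ``M = D + c R`` where ``D`` is diagonal positive
    (entries uniform on [0.5, 1.5]) and ``R`` a dense random matrix with
    N(0, 1/n) entries, so the induced cross-correlation level is O(c^2)
    independently of ``n``.  ``c = 0`` gives a diagonal Sigma.
    """
    if n < 1:
        raise ParameterError("need n >= 1")
    if cross_corr_strength < 0:
        raise ParameterError("cross_corr_strength must be >= 0")
    rng = rng_from(seed, 1)
    d = rng.uniform(0.5, 1.5, size=n)
    m = np.diag(d)
    if cross_corr_strength > 0:
        m = m + cross_corr_strength * rng.standard_normal((n, n)) / np.sqrt(n)
    sigma = m @ m.T
    return InputCovariance(sigma=sigma, mixing=m, seed=seed)


# ---------------------------------------------------------------------------
# serialization

def save_network(path, conn: ConnectivityMatrix, sigma: InputCovariance | None = None) -> None:
    """Write a network to a directory of delimited-text matrices + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "weights.csv", conn.weights, delimiter=",")
    if conn.weights2 is not None:
        np.savetxt(path / "weights2.csv", conn.weights2, delimiter=",")
    if sigma is not None:
        np.savetxt(path / "sigma.csv", sigma.sigma, delimiter=",")
        np.savetxt(path / "mixing.csv", sigma.mixing, delimiter=",")
    meta = {
        "topology_tag": conn.topology_tag,
        "seed": conn.seed,
        "rescale_factor": conn.rescale_factor,
        "order": conn.order,
        "node_labels": None if conn.node_labels is None else list(map(str, conn.node_labels)),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_network(path):
    """Inverse of :func:`save_network`; returns (ConnectivityMatrix, InputCovariance | None)."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    weights = np.atleast_2d(np.loadtxt(path / "weights.csv", delimiter=","))
    weights2 = None
    if (path / "weights2.csv").exists():
        weights2 = np.atleast_2d(np.loadtxt(path / "weights2.csv", delimiter=","))
    labels = meta.get("node_labels")
    conn = ConnectivityMatrix(
        weights=weights,
        mask=weights != 0,
        topology_tag=meta.get("topology_tag", "random"),
        weights2=weights2,
        mask2=None if weights2 is None else weights2 != 0,
        node_labels=None if labels is None else np.array(labels, dtype=object),
        rescale_factor=meta.get("rescale_factor", 1.0),
        seed=meta.get("seed"),
    )
    sigma = None
    if (path / "sigma.csv").exists():
        s = np.atleast_2d(np.loadtxt(path / "sigma.csv", delimiter=","))
        if (path / "mixing.csv").exists():
            m = np.atleast_2d(np.loadtxt(path / "mixing.csv", delimiter=","))
        else:
            m = np.linalg.cholesky(s)
        sigma = InputCovariance(sigma=s, mixing=m)
    return conn, sigma
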