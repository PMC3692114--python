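"""Elastic-network normal modes of a pseudo-atom model.

The network connects every atom pair closer than a cutoff R_c with a
harmonic spring of uniform stiffness C whose rest length is the pair
distance in the reference conformation:

    E = (C/2) · Σ_{d⁰_ij < R_c} (d_ij − d⁰_ij)²

so the reference conformation is the energy minimum by construction and no
minimization is needed. Diagonalizing the (mass-weighted) Hessian of E at
the reference yields orthonormal normal modes; a connected network has
exactly six zero-frequency rigid-body modes (3 translations + 3 rotations),
so flexible modes start at index 7. All pseudo-atoms are given unit mass —
they carry no physical mass, and uniform masses leave mode shapes unchanged
up to an overall frequency scale. C only sets the energy scale and defaults
to 1 (arbitrary units), as do the reported frequencies ω = sqrt(λ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.spatial import cKDTree

from .coarse_grain import PseudoAtomModel

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticNetwork", "NormalModeSet",
    "build_network", "potential_energy", "build_hessian",
    "compute_modes", "count_rigid_modes", "rigid_body_basis",
]

#: modes with λ below this times max(λ, 1) count as rigid-body
RIGID_TOL = 1e-6

#: dense diagonalization below this many coordinates, sparse shift-invert above
DENSE_LIMIT = 3000


@dataclass
class ElasticNetwork:
    """Cutoff-defined spring graph over pseudo-atoms with rest lengths."""

    positions: np.ndarray          # (N, 3) reference conformation, Å
    edges: np.ndarray              # (E, 2) int pairs i < j
    rest_lengths: np.ndarray       # (E,) d⁰_ij, Å
    cutoff: float                  # R_c, Å
    spring_constant: float = 1.0   # C, arbitrary units
    n_components: int = 1

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        if not self.spring_constant > 0:
            raise ValueError("spring constant must be positive")
        if self.edges.size and (
            np.any(self.edges[:, 0] >= self.edges[:, 1])
            or np.any(self.rest_lengths <= 0)
            or np.any(self.rest_lengths >= self.cutoff)
        ):
            raise ValueError("edges must satisfy i < j and 0 < d⁰ < cutoff")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


@dataclass
class NormalModeSet:
    """Ascending-eigenvalue orthonormal modes of an elastic network.

    ``vectors[k]`` is the (3N,) unit-norm eigenvector of mode k+1 — mode
    indexing is 1-based and includes the rigid-body modes, so for a
    connected network the first flexible mode is mode 7. ``frequencies``
    are sqrt(max(λ, 0)) in arbitrary units.
    """

    vectors: np.ndarray            # (M, 3N)
    eigenvalues: np.ndarray        # (M,) ascending
    n_rigid: int
    positions: np.ndarray          # reference conformation the modes refer to
    frequencies: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.eigenvalues = np.atleast_1d(np.asarray(self.eigenvalues, dtype=float))
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.frequencies is None:
            self.frequencies = np.sqrt(np.maximum(self.eigenvalues, 0.0))

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def mode(self, index: int) -> np.ndarray:
        """Mode vector by 1-based index (rigid-body modes included)."""
        if not 1 <= index <= self.n_modes:
            raise IndexError(f"mode index {index} outside 1..{self.n_modes}")
        return self.vectors[index - 1]

    def is_rigid(self, index: int) -> bool:
        return index <= self.n_rigid


def build_network(
    model: PseudoAtomModel | np.ndarray,
    cutoff: float,
    spring_constant: float = 1.0,
) -> ElasticNetwork:
    """Link every atom pair strictly closer than ``cutoff`` (Å) by a spring.

    Ties at exactly the cutoff are excluded. The connected-component count
    is recorded on the network (and logged if > 1, since each extra
    component contributes six more zero modes).
    """
    positions = model.positions if isinstance(model, PseudoAtomModel) else np.asarray(model, float)
    if positions.shape[0] < 2:
        raise ValueError("need at least 2 atoms to build a network")
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    pairs = cKDTree(positions).query_pairs(cutoff, output_type="ndarray")
    if pairs.size:
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
        d0 = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
        strict = d0 < cutoff
        pairs, d0 = pairs[strict], d0[strict]
    else:
        pairs = pairs.reshape(0, 2)
        d0 = np.empty(0)
    n = positions.shape[0]
    if len(pairs):
        adj = sp.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        n_comp, _ = connected_components(adj, directed=False)
    else:
        n_comp = n
    if n_comp > 1:
        logger.warning("elastic network has %d connected components", n_comp)
    return ElasticNetwork(positions, pairs, d0, float(cutoff), spring_constant, n_comp)


def potential_energy(net: ElasticNetwork, positions: np.ndarray) -> float:
    """E = (C/2) Σ_edges (d_ij − d⁰_ij)²; zero at the reference conformation."""
    positions = np.asarray(positions, dtype=float).reshape(net.n_atoms, 3)
    if net.n_edges == 0:
        return 0.0
    d = np.linalg.norm(
        positions[net.edges[:, 0]] - positions[net.edges[:, 1]], axis=1
    )
    return float(0.5 * net.spring_constant * np.sum((d - net.rest_lengths) ** 2))


def build_hessian(net: ElasticNetwork, sparse: bool = True):
    """Analytic 3N×3N Hessian of the network potential at the reference.

    For each edge (i, j) with separation Δr, the off-diagonal 3×3 block is
    −C·(Δr)(Δr)ᵀ/|Δr|² and each diagonal block accumulates the negated sum
    of its atom's off-diagonal blocks. The matrix is symmetric positive
    semidefinite with zero row sums (translational invariance). Unit
    masses make mass-weighting the identity.
    """
    n = net.n_atoms
    i, j = net.edges[:, 0], net.edges[:, 1]
    dr = net.positions[i] - net.positions[j]
    d2 = np.sum(dr ** 2, axis=1)
    # per-edge 3x3 block C (Δr Δrᵀ)/|Δr|²
    blocks = net.spring_constant * dr[:, :, None] * dr[:, None, :] / d2[:, None, None]

    a = np.arange(3)
    rr = np.repeat(a, 3)[None, :]          # (1, 9) row offsets within a block
    cc = np.tile(a, 3)[None, :]            # (1, 9) col offsets within a block
    bi = (3 * i)[:, None]
    bj = (3 * j)[:, None]
    b = blocks.reshape(-1, 9)
    rows = np.concatenate(
        [bi + rr, bj + rr, bi + rr, bj + rr], axis=None
    )
    cols = np.concatenate(
        [bj + cc, bi + cc, bi + cc, bj + cc], axis=None
    )
    vals = np.concatenate([-b, -b, b, b], axis=None)
    H = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n)).tocsr()
    return H if sparse else H.toarray()


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude component positive."""
    out = vectors.copy()
    for k in range(out.shape[0]):
        idx = np.argmax(np.abs(out[k]))
        if out[k, idx] < 0:
            out[k] = -out[k]
    return out


def compute_modes(net: ElasticNetwork, n_modes: int = 20) -> NormalModeSet:
    """Lowest-eigenvalue normal modes of the network, ascending.

    Dense diagonalization for 3N ≤ 3000; sparse shift-invert around a small
    negative shift above (identical results within tolerance). Rigid-body
    modes (λ < 1e-6·max(λ, 1)) are counted; a connected network has exactly
    six. A disconnected network only logs a warning — it simply has more
    zero modes.
    """
    n3 = 3 * net.n_atoms
    if not 1 <= n_modes <= n3:
        raise ValueError(f"n_modes must be in 1..{n3}")
    if net.n_edges == 0:
        raise ValueError("network has no edges; all modes would be rigid")
    if net.n_components > 1:
        logger.warning(
            "computing modes of a %d-component network: expect %d zero modes",
            net.n_components, 6 * net.n_components,
        )
    if n3 <= DENSE_LIMIT:
        H = build_hessian(net, sparse=False)
        lam, vec = np.linalg.eigh(H)
        lam, vec = lam[:n_modes], vec[:, :n_modes]
    else:
        H = build_hessian(net, sparse=True)
        # H is PSD; shift-invert about a small negative sigma keeps the
        # factorized matrix nonsingular while targeting the smallest λ
        lam, vec = eigsh(H, k=n_modes, sigma=-0.05, which="LM")
        order = np.argsort(lam)
        lam, vec = lam[order], vec[:, order]
    vectors = _fix_signs(vec.T)
    n_rigid = int(np.sum(lam < RIGID_TOL * max(lam.max(initial=0.0), 1.0)))
    return NormalModeSet(
        vectors=vectors,
        eigenvalues=lam,
        n_rigid=n_rigid,
        positions=net.positions.copy(),
    )


def count_rigid_modes(modes: NormalModeSet, tol: float | None = None) -> int:
    """Count modes with eigenvalue below ``tol`` (default: the rigid tolerance)."""
    if tol is None:
        tol = RIGID_TOL * max(float(modes.eigenvalues.max(initial=0.0)), 1.0)
    return int(np.sum(modes.eigenvalues < tol))


def rigid_body_basis(positions: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3N) of rigid translations and rotations.

    Rotations are taken about the centroid; the six vectors span the
    null space of any connected elastic network's Hessian.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = positions.shape[0]
    centered = positions - positions.mean(axis=0)
    basis = np.zeros((6, 3 * n))
    for d in range(3):
        basis[d, d::3] = 1.0
    for d, (u, v) in enumerate(((1, 2), (2, 0), (0, 1))):
        # infinitesimal rotation about axis d: δr = e_d × r
        basis[3 + d, u::3] = -centered[:, v]
        basis[3 + d, v::3] = centered[:, u]
    # orthonormalize (QR); degenerate rotations (collinear atoms) dropped
    q, r = np.linalg.qr(basis.T)
    keep = np.abs(np.diag(r)) > 1e-10
    return q.T[keep]
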