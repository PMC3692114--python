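"""Approximate a masked density volume by weighted isotropic 3D Gaussians.

The coarse-grain representation ("pseudo-atoms") approximates the density

    V̂(r) = Σ_i  w_i · exp(−|r − r_i|² / (2σ²)),

i.e. a linear combination of amplitude-1 Gaussians of shared standard
deviation σ, scaled by positive weights. The fit grows the atom count
adaptively until a target relative error is reached (or a hard cap of
9999 atoms, the largest model forwarded to normal-mode analysis).

The error metric is the masked relative L1 deviation
``Σ_mask |V − V̂| / Σ_mask |V|``: parameter-free, in [0, 1] for
non-negative maps, and robust to bright outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .volume_io import BinaryMask, DensityVolume

logger = logging.getLogger(__name__)

__all__ = [
    "PseudoAtomModel", "FitConfig", "DistanceHistogram",
    "render_model", "approximation_error", "fit_pseudo_atoms",
    "nn_distance_histogram", "suggest_cutoff",
]

MAX_ATOM_CAP = 9999  # hard cap on pseudo-atoms forwarded to the NMA step

#: Gaussians are evaluated only within this many σ of their center.
GAUSSIAN_TRUNCATION = 4.0


@dataclass
class PseudoAtomModel:
    """N weighted Gaussian centers approximating a density volume.

    ``positions`` are in Å, ``weights`` in density units (the value each
    Gaussian contributes at its own center), ``sigma`` is the shared
    standard deviation in Å.
    """

    positions: np.ndarray
    weights: np.ndarray
    sigma: float
    achieved_error: float = float("nan")
    seed: int = 0
    source: str = ""
    error_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.positions.shape != (self.weights.size, 3):
            raise ValueError("positions must be (N, 3) matching N weights")
        if self.n_atoms < 1:
            raise ValueError("a model needs at least one pseudo-atom")
        if self.n_atoms > MAX_ATOM_CAP:
            raise ValueError(f"pseudo-atom count exceeds the {MAX_ATOM_CAP} cap")
        if not np.all(self.weights > 0):
            raise ValueError("all pseudo-atom weights must be positive")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def n_atoms(self) -> int:
        return self.weights.size


@dataclass
class FitConfig:
    """Parameters of the adaptive volume-to-pseudo-atoms conversion.

    ``sigma_voxels`` sets the Gaussian standard deviation in voxel units
    (the rule of thumb is a σ similar to the voxel size, reasonable values
    run from 1, smaller pseudo-atoms, to 5, larger ones); the model stores
    it in Å. ``target_error`` is the relative L1 error at which growth
    stops; ``max_atoms`` caps the count at 9999.
    """

    sigma_voxels: float = 1.0
    target_error: float = 0.06
    max_atoms: int = MAX_ATOM_CAP
    initial_atoms: int = 100
    max_outer_iters: int = 80
    convergence_tol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_error < 1:
            raise ValueError("target_error must be in [0, 1)")
        if not 1 <= self.max_atoms <= MAX_ATOM_CAP:
            raise ValueError(f"max_atoms must be in [1, {MAX_ATOM_CAP}]")
        if not self.sigma_voxels > 0:
            raise ValueError("sigma_voxels must be positive")
        if self.initial_atoms < 1:
            raise ValueError("initial_atoms must be >= 1")


@dataclass
class DistanceHistogram:
    """Histogram of per-atom nearest-neighbor distances (Å)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    definition: str = "per-atom nearest-neighbor distances"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


# ---------------------------------------------------------------------------
# Separable Gaussian grid kernel
# ---------------------------------------------------------------------------

class _GridKernel:
    """Evaluates truncated separable Gaussians of a fixed atom set on a grid.

    Every atom owns a fixed-width voxel window (half-width ⌈4σ/voxel⌉
    around the nearest voxel) on a zero-padded copy of the grid, so
    rendering, its adjoint, and position gradients are batched axis-outer
    products — no per-atom Python loop. Atoms are processed in chunks to
    bound the (n_chunk × w³) temporaries.
    """

    _CHUNK_ELEMENTS = 3.0e7

    def __init__(self, positions, sigma, shape, voxel_size, origin):
        self.sigma = float(sigma)
        self.shape = tuple(int(s) for s in shape)
        self.voxel_size = float(voxel_size)
        self.origin = np.asarray(origin, dtype=float)
        self.positions = np.atleast_2d(np.asarray(positions, dtype=float))
        self.n = self.positions.shape[0]
        self.halfw = int(np.ceil(GAUSSIAN_TRUNCATION * self.sigma / self.voxel_size))
        self.w = 2 * self.halfw + 1
        self.pad = self.halfw + 1
        self.pshape = tuple(s + 2 * self.pad for s in self.shape)
        g = (self.positions - self.origin) / self.voxel_size + self.pad
        base = np.rint(g).astype(np.int64) - self.halfw  # (n, 3) window lows
        # clamp windows fully inside the padded grid (atoms far outside the
        # grid keep a valid window; their Gaussians land in the zero pad)
        base = np.clip(base, 0, np.array(self.pshape) - self.w)
        self.base = base
        ar = np.arange(self.w)
        # physical offsets voxel-center − atom-center, per axis: (n, w)
        self.off = [
            ((base[:, d, None] + ar) - g[:, d, None]) * self.voxel_size
            for d in range(3)
        ]
        s2 = 2.0 * self.sigma ** 2
        self.gauss = [np.exp(-(o ** 2) / s2) for o in self.off]
        self.chunk = max(1, int(self._CHUNK_ELEMENTS // self.w ** 3))

    def _flat_idx(self, sl: slice) -> np.ndarray:
        sx, sy, sz = self.pshape
        ar = np.arange(self.w)
        ix = self.base[sl, 0, None] + ar
        iy = self.base[sl, 1, None] + ar
        iz = self.base[sl, 2, None] + ar
        return (
            ix[:, :, None, None] * (sy * sz)
            + iy[:, None, :, None] * sz
            + iz[:, None, None, :]
        )

    def _unpad(self, padded_flat: np.ndarray) -> np.ndarray:
        p = self.pad
        out = padded_flat.reshape(self.pshape)
        return out[p:-p, p:-p, p:-p]

    def _pad(self, grid: np.ndarray) -> np.ndarray:
        return np.pad(grid, self.pad)

    def render(self, weights: np.ndarray) -> np.ndarray:
        flat = np.zeros(int(np.prod(self.pshape)))
        for s in range(0, self.n, self.chunk):
            sl = slice(s, min(s + self.chunk, self.n))
            vals = np.einsum(
                "ni,nj,nk->nijk",
                weights[sl, None] * self.gauss[0][sl],
                self.gauss[1][sl], self.gauss[2][sl],
            )
            flat += np.bincount(
                self._flat_idx(sl).ravel(), weights=vals.ravel(),
                minlength=flat.size,
            )
        return self._unpad(flat).copy()

    def correlate(self, grid: np.ndarray) -> np.ndarray:
        """Adjoint of render: per-atom inner product <grid, g_i>."""
        pf = self._pad(grid).ravel()
        out = np.empty(self.n)
        for s in range(0, self.n, self.chunk):
            sl = slice(s, min(s + self.chunk, self.n))
            cubes = pf[self._flat_idx(sl)]
            out[sl] = np.einsum(
                "nijk,ni,nj,nk->n", cubes,
                self.gauss[0][sl], self.gauss[1][sl], self.gauss[2][sl],
            )
        return out

    def position_gradient(self, resid: np.ndarray, weights: np.ndarray):
        """∂(½Σ resid²)/∂r_i with resid = V̂ − V, plus the Gauss-Newton
        diagonal curvature used to scale the step."""
        pf = self._pad(resid).ravel()
        grad = np.empty((self.n, 3))
        s2 = self.sigma ** 2
        gx, gy, gz = self.gauss
        for s in range(0, self.n, self.chunk):
            sl = slice(s, min(s + self.chunk, self.n))
            cubes = pf[self._flat_idx(sl)]
            grad[sl, 0] = np.einsum(
                "nijk,ni,nj,nk->n", cubes, gx[sl] * self.off[0][sl], gy[sl], gz[sl]
            )
            grad[sl, 1] = np.einsum(
                "nijk,ni,nj,nk->n", cubes, gx[sl], gy[sl] * self.off[1][sl], gz[sl]
            )
            grad[sl, 2] = np.einsum(
                "nijk,ni,nj,nk->n", cubes, gx[sl], gy[sl], gz[sl] * self.off[2][sl]
            )
        grad *= (weights / s2)[:, None]
        ssq = (
            (gx ** 2).sum(axis=1) * (gy ** 2).sum(axis=1) * (gz ** 2).sum(axis=1)
        )
        curv = np.maximum(weights ** 2 * ssq / s2, 1e-30)
        return grad, curv


def render_model(
    model: PseudoAtomModel,
    dims: tuple[int, int, int],
    voxel_size: float,
    origin=(0.0, 0.0, 0.0),
) -> DensityVolume:
    """Render the model's Gaussian sum on a grid (truncated at 4σ).

    ``V̂(r) = Σ_i w_i exp(−|r − r_i|²/(2σ²))`` evaluated at voxel centers;
    all output densities are ≥ 0 since weights are positive.
    """
    kern = _GridKernel(model.positions, model.sigma, dims, voxel_size, origin)
    return DensityVolume(kern.render(model.weights), voxel_size, np.asarray(origin))


def render_on(model: PseudoAtomModel, like: DensityVolume) -> DensityVolume:
    """Render the model on the grid of an existing volume."""
    return render_model(model, like.data.shape, like.voxel_size, like.origin)


def approximation_error(
    vol: DensityVolume, model: PseudoAtomModel, mask: BinaryMask | None = None
) -> float:
    """Masked relative L1 approximation error Σ_mask|V − V̂| / Σ_mask|V|.

    Zero iff the rendered model matches the volume exactly on the mask.
    Raises ``ValueError`` if the masked volume is all zero.
    """
    m = np.ones(vol.data.shape, dtype=bool) if mask is None else mask.data.astype(bool)
    denom = np.abs(vol.data[m]).sum()
    if denom == 0:
        raise ValueError("masked volume is all zero; relative error undefined")
    approx = render_on(model, vol)
    return float(np.abs(vol.data[m] - approx.data[m]).sum() / denom)


# ---------------------------------------------------------------------------
# Adaptive fit
# ---------------------------------------------------------------------------

def _masked_l1_error(V, maskb, rendered, denom):
    return float(np.abs(V[maskb] - rendered[maskb]).sum() / denom)


def _refine_weights(kern, V, maskb, weights, denom, n_updates=6):
    """Multiplicative nonnegative least-squares updates of the weights.

    The design (Gaussian basis on the mask) and the data are nonnegative,
    so the classic NMF update  w ← w · (AᵀV) / (AᵀÂ)  keeps every weight
    strictly positive and monotonically decreases the masked L2 misfit.
    The accepted update is damped (ratio^β) if it would worsen the L1
    error that the fit reports, so that error never increases either.
    """
    err0 = _masked_l1_error(V, maskb, kern.render(weights), denom)
    cV = kern.correlate(V)  # AᵀV; V is already masked
    w = weights
    for _ in range(n_updates):
        rendered = kern.render(w) * maskb
        cR = kern.correlate(rendered)  # Aᵀ Â
        ratio = cV / np.maximum(cR, 1e-300)
        w = w * ratio
    err = _masked_l1_error(V, maskb, kern.render(w), denom)
    if err < err0:
        return w, err
    # damp the total multiplicative step until the L1 error improves
    with np.errstate(divide="ignore", invalid="ignore"):
        total = np.where(weights > 0, w / weights, 1.0)
    for beta in (0.5, 0.25, 0.125):
        trial = weights * total ** beta
        err = _masked_l1_error(V, maskb, kern.render(trial), denom)
        if err < err0:
            return trial, err
    return weights, err0


def _refine_positions(kern_args, positions, weights, V, maskb, denom, err0):
    """One damped Gauss-Newton step on all atom centers, accepted only if
    the L1 error improves; steps are capped at half a voxel."""
    shape, voxel_size, origin, sigma = kern_args
    kern = _GridKernel(positions, sigma, shape, voxel_size, origin)
    rendered = kern.render(weights)
    grad, curv = kern.position_gradient((rendered - V) * maskb, weights)
    step = -grad / curv[:, None]
    cap = 0.5 * voxel_size
    norms = np.linalg.norm(step, axis=1)
    too_big = norms > cap
    step[too_big] *= (cap / norms[too_big])[:, None]
    for alpha in (1.0, 0.5, 0.25):
        trial = positions + alpha * step
        kt = _GridKernel(trial, sigma, shape, voxel_size, origin)
        err = _masked_l1_error(V, maskb, kt.render(weights), denom)
        if err < err0:
            return trial, kt, err
    return positions, kern, err0


def fit_pseudo_atoms(
    vol: DensityVolume, mask: BinaryMask, config: FitConfig | None = None
) -> PseudoAtomModel:
    """Adaptively fit pseudo-atoms to a masked volume.

    Starting from ``initial_atoms`` centers sampled with probability
    proportional to the masked density, the fit alternates weight
    refinement (linear least squares with nonnegativity) and position
    refinement (damped Gauss-Newton) against the residual, then adds a
    batch of atoms at the voxels of largest positive residual whenever the
    error still exceeds the target. Growth stops when the achieved error
    reaches the target, the atom cap is hit, or outer iterations are
    exhausted. Deterministic for a fixed seed; the per-iteration error is
    non-increasing and recorded in ``error_history``.
    """
    if config is None:
        config = FitConfig()
    maskb = mask.data.astype(bool)
    if maskb.shape != vol.data.shape:
        raise ValueError("mask dimensions do not match the volume")
    V = vol.data * maskb
    denom = np.abs(V[maskb]).sum()
    if not maskb.any() or denom == 0:
        raise ValueError("masked volume has no density to fit")

    rng = np.random.default_rng(config.seed)
    sigma = config.sigma_voxels * vol.voxel_size
    shape = vol.data.shape
    kern_args = (shape, vol.voxel_size, vol.origin, sigma)

    # initial centers: voxel centers sampled ∝ masked density, jittered
    # uniformly inside the voxel so atoms never coincide exactly
    flat_idx = np.flatnonzero(maskb.ravel() & (V.ravel() > 0))
    probs = V.ravel()[flat_idx]
    probs = probs / probs.sum()
    n0 = min(config.initial_atoms, config.max_atoms, flat_idx.size)
    chosen = rng.choice(flat_idx, size=n0, replace=False if n0 <= flat_idx.size else True, p=probs)
    ijk = np.stack(np.unravel_index(chosen, shape), axis=1).astype(float)
    jitter = rng.uniform(-0.45, 0.45, size=ijk.shape)
    positions = vol.origin + vol.voxel_size * (ijk + jitter)
    weights = V.ravel()[chosen].astype(float)

    history: list[float] = []
    err = np.inf
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(config.max_outer_iters):
        # alternate weight / position refinement until the improvement per
        # round falls below 1% — while the model is still growing, finer
        # polish would be redone after the next batch anyway
        kern = _GridKernel(positions, sigma, shape, vol.voxel_size, vol.origin)
        weights, err = _refine_weights(kern, V, maskb, weights, denom)
        for _inner in range(10):
            prev = err
            positions, kern, err = _refine_positions(
                kern_args, positions, weights, V, maskb, denom, err
            )
            weights, err = _refine_weights(kern, V, maskb, weights, denom)
            if err <= config.target_error or prev - err < 0.01 * max(prev, 1e-30):
                break

        # prune near-zero weights (below the cap) or clamp them (at the cap,
        # where removing atoms would just trigger another add round)
        floor = 1e-6 * weights.max()
        at_cap = weights.size >= config.max_atoms
        dead = weights < floor
        if dead.any():
            if at_cap:
                weights = np.maximum(weights, floor)
            else:
                positions, weights = positions[~dead], weights[~dead]
                kern = _GridKernel(positions, sigma, shape, vol.voxel_size, vol.origin)
                weights, err = _refine_weights(kern, V, maskb, weights, denom)

        # the last batch of atoms may fail to pay off (overlapping Gaussians
        # can overshoot in ways refinement cannot undo); in that case revert
        # to the best model seen and stop growing — the error stays monotone
        if best is not None and err > best[2] * (1 + 1e-12):
            positions, weights, err = best[0], best[1], best[2]
            logger.warning(
                "fit: additions stopped reducing the error; stopping at "
                "N=%d, error %.4g", weights.size, err,
            )
            history.append(err)
            break
        if best is None or err < best[2]:
            best = (positions.copy(), weights.copy(), err)
        history.append(err)

        if err <= config.target_error:
            break
        if weights.size >= config.max_atoms:
            # the cap is a hard termination condition: polish in place
            # until the improvement stalls, then stop
            for _inner in range(3):
                prev = err
                positions, kern, err = _refine_positions(
                    kern_args, positions, weights, V, maskb, denom, err
                )
                weights, err = _refine_weights(kern, V, maskb, weights, denom)
                history.append(err)
                if prev - err < config.convergence_tol * max(prev, 1e-30):
                    break
            break

        # grow: new atoms at the voxels of largest positive residual
        kern = _GridKernel(positions, sigma, shape, vol.voxel_size, vol.origin)
        resid = (V - kern.render(weights)) * maskb
        batch = min(max(32, weights.size // 10), config.max_atoms - weights.size)
        flat = resid.ravel()
        top = np.argpartition(flat, -batch)[-batch:]
        top = top[flat[top] > 0]
        if top.size == 0:
            logger.info("fit: no positive residual left; stopping growth")
            break
        ijk = np.stack(np.unravel_index(top, shape), axis=1).astype(float)
        jitter = rng.uniform(-0.45, 0.45, size=ijk.shape)
        new_pos = vol.origin + vol.voxel_size * (ijk + jitter)
        # start new atoms well below the residual amplitude: a clustered
        # batch of overlapping Gaussians at full amplitude overshoots badly
        new_w = 0.1 * flat[top].astype(float)
        positions = np.vstack([positions, new_pos])
        weights = np.concatenate([weights, new_w])
    else:
        logger.warning("fit: outer iteration budget exhausted at error %.4g", err)

    if err > config.target_error and weights.size >= config.max_atoms:
        logger.warning(
            "fit: target error %.4g unreachable at the %d-atom cap "
            "(achieved %.4g)", config.target_error, config.max_atoms, err,
        )

    model = PseudoAtomModel(
        positions=positions,
        weights=weights,
        sigma=sigma,
        achieved_error=err,
        seed=config.seed,
        source=f"fit(sigma_voxels={config.sigma_voxels}, "
               f"target_error={config.target_error}, seed={config.seed})",
    )
    model.error_history = history
    return model


# ---------------------------------------------------------------------------
# Neighbor distances and cutoff suggestion
# ---------------------------------------------------------------------------

def _nn_distances(positions: np.ndarray) -> np.ndarray:
    tree = cKDTree(positions)
    d, _ = tree.query(positions, k=2)
    return d[:, 1]


def nn_distance_histogram(model: PseudoAtomModel, n_bins: int = 50) -> DistanceHistogram:
    """Histogram of each atom's nearest-neighbor distance; counts sum to N."""
    if model.n_atoms < 2:
        raise ValueError("need at least 2 atoms for a distance histogram")
    nn = _nn_distances(model.positions)
    counts, edges = np.histogram(nn, bins=n_bins)
    return DistanceHistogram(bin_edges=edges, counts=counts)


def _is_connected(positions: np.ndarray, cutoff: float) -> bool:
    n = positions.shape[0]
    pairs = cKDTree(positions).query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return n == 1
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


def suggest_cutoff(model: PseudoAtomModel, fraction: float = 0.95) -> float:
    """Elastic-network cutoff such that ~95% of neighbor distances fall below it.

    Returns the ``fraction`` quantile of per-atom nearest-neighbor
    distances. If the resulting network would be disconnected, the cutoff
    is raised to (just above) the smallest distance that connects the model
    into a single component, and the adjustment is logged.
    """
    if model.n_atoms < 2:
        raise ValueError("need at least 2 atoms to suggest a cutoff")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    nn = _nn_distances(model.positions)
    cutoff = float(np.quantile(nn, fraction, method="higher"))
    cutoff = np.nextafter(cutoff, np.inf)  # edge rule is strict '<'
    if _is_connected(model.positions, cutoff):
        return float(cutoff)
    # bottleneck search: smallest radius with a single connected component
    lo, hi = cutoff, cutoff
    while not _is_connected(model.positions, hi):
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _is_connected(model.positions, mid):
            hi = mid
        else:
            lo = mid
        if hi - lo <= 1e-9 * hi:
            break
    adjusted = hi + 1e-6
    logger.info(
        "suggest_cutoff: raised cutoff from %.3f to %.3f Å to keep the "
        "network connected", cutoff, adjusted,
    )
    return float(adjusted)
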