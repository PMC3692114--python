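"""Collectivity scoring, mode deformations, trajectories and overlap analysis.

Deforming the reference conformation along modes is linear:

    r'_i = r_i + Σ_n a_n · u_{n,i}

with unit-norm (over all 3N coordinates) mode vectors u_n and dimensionless
amplitudes a_n, so an amplitude is in Å·(vector-norm) terms — e.g. the
conventional animation amplitude of 50 displaces atom i by at most
50·|u_{n,i}| Å.

The collectivity degree κ of a mode measures how many atoms it displaces
significantly (an exponentiated Shannon entropy of the per-atom squared
displacement distribution): κ = 1/N for a single displaced atom, κ = 1 when
every atom moves with the same magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coarse_grain import PseudoAtomModel
from .enm_nma import NormalModeSet, rigid_body_basis

logger = logging.getLogger(__name__)

__all__ = [
    "Deformation", "Trajectory", "CollectivityReport",
    "deform", "collectivity", "collectivity_report",
    "make_trajectory", "mode_overlap",
]


@dataclass
class Deformation:
    """Linear combination of modes: list of (1-based mode index, amplitude)."""

    terms: list[tuple[int, float]]

    def __post_init__(self) -> None:
        idx = [int(n) for n, _ in self.terms]
        if len(set(idx)) != len(idx):
            raise ValueError("mode indices in a deformation must be distinct")
        if any(n < 1 for n in idx):
            raise ValueError("mode indices are 1-based")


@dataclass
class Trajectory:
    """Ordered frames of deformed pseudo-atom positions for animation export."""

    frames: np.ndarray             # (K, N, 3) Å
    mode_index: int
    amplitude: float
    phases: np.ndarray             # per-frame phase in [0, 2π)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames of (N, 3) positions")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class CollectivityReport:
    """Per-mode collectivity κ ∈ [1/N, 1] with its rigid-body flag."""

    kappa: np.ndarray
    n_rigid: int
    eigenvalues: np.ndarray
    frequencies: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.kappa.size

    def rows(self):
        """Iterate (mode, eigenvalue, frequency, collectivity, is_rigid)."""
        for k in range(self.n_modes):
            yield (
                k + 1,
                float(self.eigenvalues[k]),
                float(self.frequencies[k]),
                float(self.kappa[k]),
                k < self.n_rigid,
            )


def deform(
    model: PseudoAtomModel | np.ndarray,
    modes: NormalModeSet,
    d: Deformation,
) -> np.ndarray:
    """Apply r' = r + Σ_n a_n u_n to the reference positions.

    Accepts a model or a raw (N, 3) position array; mode indices are
    1-based and must be within the computed set.
    """
    ref = model.positions if isinstance(model, PseudoAtomModel) else np.asarray(model, float)
    ref = np.atleast_2d(ref)
    out = ref.copy()
    for n, a in d.terms:
        out += a * modes.mode(n).reshape(-1, 3)
    return out


def collectivity(u: np.ndarray, n_atoms: int | None = None) -> float:
    """Collectivity degree κ of a 3N displacement vector.

    With per-atom squared displacements p_i = |u_i|² and normalization
    α = 1/Σ_i p_i (so Σ α·p_i = 1):

        κ = (1/N) · exp(−Σ_i α·p_i · ln(α·p_i))

    Atoms with zero displacement contribute nothing to the entropy sum.
    κ is invariant to rescaling of u and bounded in [1/N, 1].
    """
    u = np.asarray(u, dtype=float).ravel()
    if u.size % 3:
        raise ValueError("displacement vector length must be a multiple of 3")
    n = u.size // 3
    if n_atoms is not None and n_atoms != n:
        raise ValueError(f"vector encodes {n} atoms, expected {n_atoms}")
    p = np.sum(u.reshape(-1, 3) ** 2, axis=1)
    total = p.sum()
    if total == 0:
        raise ValueError("collectivity of an all-zero vector is undefined")
    q = p / total
    nz = q > 0
    entropy = -np.sum(q[nz] * np.log(q[nz]))
    return float(np.exp(entropy) / n)


def collectivity_report(modes: NormalModeSet) -> CollectivityReport:
    """κ for every computed mode; rigid-body modes are included but flagged."""
    kappa = np.array([collectivity(modes.vectors[k]) for k in range(modes.n_modes)])
    return CollectivityReport(
        kappa=kappa,
        n_rigid=modes.n_rigid,
        eigenvalues=modes.eigenvalues.copy(),
        frequencies=modes.frequencies.copy(),
    )


def make_trajectory(
    model: PseudoAtomModel,
    modes: NormalModeSet,
    mode_index: int,
    amplitude: float = 50.0,
    n_frames: int = 10,
    schedule: str = "sine",
) -> Trajectory:
    """Animate one mode over a full oscillation cycle.

    Frame k (k = 0..K−1) deforms the reference by a_k = A·sin(2πk/K), so
    frame 0 is the reference itself and the animation loops seamlessly.
    ``schedule='ramp'`` instead sweeps linearly from −A to +A. Requesting a
    rigid-body mode is allowed but logged as a warning.
    """
    if n_frames < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    if schedule not in ("sine", "ramp"):
        raise ValueError("schedule must be 'sine' or 'ramp'")
    if modes.is_rigid(mode_index):
        logger.warning(
            "mode %d is a rigid-body mode; its animation is a pure "
            "translation/rotation", mode_index,
        )
    k = np.arange(n_frames)
    if schedule == "sine":
        phases = 2 * np.pi * k / n_frames
        amps = amplitude * np.sin(phases)
    else:
        phases = np.pi * k / (n_frames - 1)
        amps = np.linspace(-amplitude, amplitude, n_frames)
        # keep the frame-0 = reference contract by rolling the ramp
        amps = np.concatenate([[0.0], amps[:-1]])
    u = modes.mode(mode_index).reshape(-1, 3)
    frames = model.positions[None, :, :] + amps[:, None, None] * u[None, :, :]
    return Trajectory(frames=frames, mode_index=mode_index,
                      amplitude=amplitude, phases=phases)


def mode_overlap(
    modes: NormalModeSet,
    target_displacement: np.ndarray,
    project_rigid: bool = True,
) -> tuple[np.ndarray, int]:
    """Normalized overlap of each mode with an observed displacement.

    overlap_n = |u_n · Δr| / (|u_n|·|Δr|) ∈ [0, 1]. By default the
    rigid-body component of the target is projected out first, so residual
    superposition error between the two conformations does not leak into
    the scores (the two structures should still be pre-superposed).
    Returns (per-mode overlaps, 1-based argmax mode index).
    """
    t = np.asarray(target_displacement, dtype=float).ravel()
    if t.size != 3 * modes.n_atoms:
        raise ValueError(
            f"target length {t.size} != 3N = {3 * modes.n_atoms}"
        )
    if project_rigid:
        basis = rigid_body_basis(modes.positions)
        t = t - basis.T @ (basis @ t)
    norm = np.linalg.norm(t)
    if norm == 0:
        raise ValueError("target displacement is zero (after rigid-body projection)")
    overlaps = np.abs(modes.vectors @ t) / (
        np.linalg.norm(modes.vectors, axis=1) * norm
    )
    return overlaps, int(np.argmax(overlaps)) + 1
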