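"""Serialize pseudo-atom models, mode sets and trajectories as text formats.

Pseudo-atom models use a small PDB dialect: one HETATM record per atom
(element C, residue PSA), coordinates to 3 decimals, and the weight stored
in the occupancy column as ``weight / weight_scale`` (occupancy is 2-decimal,
so raw weights would be destroyed; the scale, the model's maximum weight,
travels in a REMARK). The shared Gaussian σ also travels in a REMARK and is
required when reading — downstream rendering needs it. The 9999-atom cap
keeps serial numbers inside PDB's fixed-width fields.

Mode sets are written as a directory of per-mode text vectors (3N floats)
plus a tab-separated metadata table and the reference positions.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .coarse_grain import PseudoAtomModel
from .enm_nma import NormalModeSet
from .mode_tools import Trajectory

__all__ = [
    "write_pseudo_pdb", "read_pseudo_pdb",
    "write_trajectory_pdb", "read_trajectory_pdb",
    "write_modes", "read_modes",
    "write_collectivity_table", "write_distance_histogram",
]

_REMARK_SIGMA = "REMARK 250 SIGMA_ANGSTROM"
_REMARK_SCALE = "REMARK 250 WEIGHT_SCALE"
_REMARK_ERROR = "REMARK 250 ACHIEVED_ERROR"
_REMARK_SEED = "REMARK 250 SEED"


def _hetatm_line(serial: int, pos, occupancy: float) -> str:
    return (
        f"HETATM{serial:5d}  C   PSA A{serial % 10000:4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {'C':>2s}\n"
    )


def write_pseudo_pdb(model: PseudoAtomModel, path: str | os.PathLike) -> None:
    """Write a pseudo-atom model in the HETATM/occupancy dialect."""
    scale = float(model.weights.max())
    lines = [
        f"{_REMARK_SIGMA} {model.sigma:.10g}\n",
        f"{_REMARK_SCALE} {scale:.10g}\n",
    ]
    if np.isfinite(model.achieved_error):
        lines.append(f"{_REMARK_ERROR} {model.achieved_error:.10g}\n")
    lines.append(f"{_REMARK_SEED} {model.seed}\n")
    occ = np.clip(model.weights / scale, 0.0, 1.0)
    for k in range(model.n_atoms):
        lines.append(_hetatm_line(k + 1, model.positions[k], occ[k]))
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def _parse_hetatm(line: str, path, lineno: int):
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60])
    except ValueError as exc:
        raise ValueError(
            f"{path}:{lineno}: malformed HETATM/ATOM coordinates: {line.rstrip()!r}"
        ) from exc
    return (x, y, z), occ


def read_pseudo_pdb(path: str | os.PathLike) -> PseudoAtomModel:
    """Read a pseudo-atom PDB; the σ REMARK is mandatory.

    Occupancy quantization bounds the weight round-trip error at half a
    unit in the second decimal of ``weight / weight_scale``.
    """
    sigma = scale = error = None
    seed = 0
    positions, occs = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith(_REMARK_SIGMA):
            sigma = float(line.split()[-1])
        elif line.startswith(_REMARK_SCALE):
            scale = float(line.split()[-1])
        elif line.startswith(_REMARK_ERROR):
            error = float(line.split()[-1])
        elif line.startswith(_REMARK_SEED):
            seed = int(line.split()[-1])
        elif line.startswith(("HETATM", "ATOM  ")):
            pos, occ = _parse_hetatm(line, path, lineno)
            positions.append(pos)
            occs.append(occ)
    if sigma is None:
        raise ValueError(
            f"{path}: missing '{_REMARK_SIGMA}' record — σ is required to "
            "render or analyze the model"
        )
    if not positions:
        raise ValueError(f"{path}: no HETATM/ATOM records found")
    if scale is None:
        scale = 1.0
    weights = np.asarray(occs) * scale
    weights = np.maximum(weights, 1e-12 * scale)  # occupancy 0.00 still > 0
    return PseudoAtomModel(
        positions=np.asarray(positions),
        weights=weights,
        sigma=sigma,
        achieved_error=float("nan") if error is None else error,
        seed=seed,
        source=f"read_pseudo_pdb({os.fspath(path)!r})",
    )


def write_trajectory_pdb(
    traj: Trajectory, path: str | os.PathLike, sigma: float | None = None
) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL, 1-based)."""
    lines = [
        f"REMARK 250 MODE {traj.mode_index}\n",
        f"REMARK 250 AMPLITUDE {traj.amplitude:.10g}\n",
    ]
    if sigma is not None:
        lines.append(f"{_REMARK_SIGMA} {sigma:.10g}\n")
    for m in range(traj.n_frames):
        lines.append(f"MODEL {m + 1:8d}\n")
        for k in range(traj.frames.shape[1]):
            lines.append(_hetatm_line(k + 1, traj.frames[m, k], 1.0))
        lines.append("ENDMDL\n")
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def read_trajectory_pdb(path: str | os.PathLike) -> Trajectory:
    """Read back a multi-model pseudo-atom PDB as a Trajectory."""
    frames: list[list[tuple[float, float, float]]] = []
    mode_index, amplitude = 0, float("nan")
    current: list[tuple[float, float, float]] | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("REMARK 250 MODE "):
            mode_index = int(line.split()[-1])
        elif line.startswith("REMARK 250 AMPLITUDE"):
            amplitude = float(line.split()[-1])
        elif line.startswith("MODEL"):
            current = []
        elif line.startswith("ENDMDL"):
            if current is None:
                raise ValueError(f"{path}:{lineno}: ENDMDL without MODEL")
            frames.append(current)
            current = None
        elif line.startswith(("HETATM", "ATOM  ")) and current is not None:
            pos, _ = _parse_hetatm(line, path, lineno)
            current.append(pos)
    if len(frames) < 2:
        raise ValueError(f"{path}: fewer than 2 MODEL blocks")
    arr = np.asarray(frames, dtype=float)
    k = np.arange(arr.shape[0])
    return Trajectory(
        frames=arr, mode_index=mode_index, amplitude=amplitude,
        phases=2 * np.pi * k / arr.shape[0],
    )


# ---------------------------------------------------------------------------
# Mode sets
# ---------------------------------------------------------------------------

def write_modes(modes: NormalModeSet, directory: str | os.PathLike) -> None:
    """Write one text vector per mode plus metadata and reference positions.

    Layout: ``mode_0001.txt`` … (3N whitespace-separated floats each),
    ``modes.tsv`` (mode, eigenvalue, frequency, rigid flag) and
    ``positions.txt`` (N rows of x y z).
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for k in range(modes.n_modes):
        np.savetxt(d / f"mode_{k + 1:04d}.txt", modes.vectors[k], fmt="%.17g")
    with open(d / "modes.tsv", "w") as fh:
        fh.write("mode\teigenvalue\tfrequency\trigid\n")
        for k in range(modes.n_modes):
            fh.write(
                f"{k + 1}\t{modes.eigenvalues[k]:.17g}\t"
                f"{modes.frequencies[k]:.17g}\t{int(k < modes.n_rigid)}\n"
            )
    np.savetxt(d / "positions.txt", modes.positions, fmt="%.17g")


def read_modes(directory: str | os.PathLike) -> NormalModeSet:
    """Read a mode directory written by :func:`write_modes`."""
    d = Path(directory)
    positions = np.atleast_2d(np.loadtxt(d / "positions.txt"))
    n3 = 3 * positions.shape[0]
    rows = []
    with open(d / "modes.tsv") as fh:
        header = fh.readline()
        if not header.startswith("mode\t"):
            raise ValueError(f"{d / 'modes.tsv'}: unrecognized metadata header")
        for line in fh:
            idx, lam, freq, rigid = line.split("\t")
            rows.append((int(idx), float(lam), float(freq), int(rigid)))
    vectors = np.empty((len(rows), n3))
    for idx, _, _, _ in rows:
        f = d / f"mode_{idx:04d}.txt"
        v = np.loadtxt(f)
        if v.size != n3:
            raise ValueError(f"{f}: vector length {v.size} != 3N = {n3}")
        vectors[idx - 1] = v
    return NormalModeSet(
        vectors=vectors,
        eigenvalues=np.array([r[1] for r in rows]),
        n_rigid=int(sum(r[3] for r in rows)),
        positions=positions,
        frequencies=np.array([r[2] for r in rows]),
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_collectivity_table(report, path: str | os.PathLike) -> None:
    """Tab-separated table: mode, eigenvalue, frequency, collectivity, rigid."""
    with open(path, "w") as fh:
        fh.write("mode\teigenvalue\tfrequency\tcollectivity\trigid\n")
        for mode, lam, freq, kappa, rigid in report.rows():
            fh.write(f"{mode}\t{lam:.10g}\t{freq:.10g}\t{kappa:.6f}\t{int(rigid)}\n")


def write_distance_histogram(hist, path: str | os.PathLike) -> None:
    """Two-column text: bin center (Å) and count."""
    with open(path, "w") as fh:
        fh.write("# bin_center_A\tcount\n")
        for c, n in zip(hist.bin_centers, hist.counts):
            fh.write(f"{c:.6f}\t{int(n)}\n")
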