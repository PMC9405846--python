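"""Conformation metrics for molecular-dynamics trajectories.

Aptamer sensor behaviour is interpreted through three standard observables
computed from ordered coordinate frames (Å):

* **Radius of gyration** — mass-weighted RMS distance of atoms from their
  centre of mass; a compactness proxy, rising when the aptamer elongates.
* **RMSD** — root-mean-square deviation between two conformations, with
  optional mass-weighted least-squares rigid-body superposition (Kabsch), so
  that pure rotations/translations score zero.
* **RMSF** — per-atom (or per-residue) root-mean-square fluctuation about
  the mean structure over a trajectory; a flexibility measure that drops
  where a rigid binding pocket forms.

The RMSF reference follows the common MD-analysis convention: frames are
first superposed onto frame 1, the mean structure is taken, and each frame
is re-superposed onto that mean (one iteration) before fluctuations are
accumulated.

Readers accept multi-model PDB and XYZ files (via MDAnalysis); masses are
inferred from element symbols, with an explicit override table available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class Trajectory:
    """Ordered coordinate frames (F, N, 3) with per-atom masses and labels."""

    frames: np.ndarray
    masses: np.ndarray
    atom_labels: tuple[str, ...]
    residue_index: np.ndarray

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (F, N, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        n = self.frames.shape[1]
        if self.masses.shape != (n,) or (self.masses <= 0).any():
            raise ValueError("masses must be positive, one per atom")
        if len(self.atom_labels) != n or self.residue_index.shape != (n,):
            raise ValueError("atom_labels/residue_index must match atom count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray) -> float:
    """Rg = sqrt( Σ mᵢ ‖rᵢ − r_com‖² / Σ mᵢ ), r_com the mass-weighted centroid."""
    frame = np.asarray(frame, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3 or frame.shape[0] == 0:
        raise ValueError(f"frame must be a non-empty (N, 3) array, got {frame.shape}")
    if masses.shape != (frame.shape[0],):
        raise ValueError("one mass per atom required")
    com = np.average(frame, axis=0, weights=masses)
    sq = ((frame - com) ** 2).sum(axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def _kabsch(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Optimal weighted rigid-body superposition of mobile onto reference.

    Returns the transformed mobile coordinates (rotation + translation only;
    reflections are excluded by the sign correction on the smallest singular
    vector).
    """
    w = weights / weights.sum()
    mu_m = (w[:, None] * mobile).sum(axis=0)
    mu_r = (w[:, None] * reference).sum(axis=0)
    A = mobile - mu_m
    B = reference - mu_r
    H = (w[:, None] * A).T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return A @ R.T + mu_r


def rmsd(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    superpose: bool = True,
    masses: Optional[np.ndarray] = None,
) -> float:
    """RMSD between two conformations, optionally after rigid superposition.

    With ``superpose`` the mobile frame (``frame_a``) is fitted onto
    ``frame_b`` by weighted least squares before the deviation is computed,
    so rigid motions contribute nothing.  The per-atom average is
    mass-weighted when masses are given, plain otherwise.
    """
    A = np.asarray(frame_a, dtype=float)
    B = np.asarray(frame_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"frames must share an (N, 3) shape, got {A.shape} vs {B.shape}")
    w = np.ones(A.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    if superpose:
        A = _kabsch(A, B, w)
    sq = ((A - B) ** 2).sum(axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


def rmsf(
    traj: Trajectory,
    group_by_residue: bool = False,
    superpose: bool = True,
) -> np.ndarray:
    """Per-atom (or per-residue) RMS fluctuation about the mean structure.

    Frames are superposed onto frame 1, averaged into a mean structure, and
    re-superposed onto that mean (one iteration); then
    RMSFᵢ = sqrt(⟨‖rᵢ(t) − ⟨rᵢ⟩‖²⟩).  With ``group_by_residue`` the per-atom
    values are combined as the mass-weighted mean within each residue, in
    order of first appearance.  Superposition can be disabled to measure raw
    (lab-frame) fluctuations.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least two frames")
    frames = traj.frames.astype(float)
    w = traj.masses.astype(float)
    if superpose:
        fitted = np.stack([_kabsch(f, frames[0], w) for f in frames])
        mean = fitted.mean(axis=0)
        fitted = np.stack([_kabsch(f, mean, w) for f in frames])
    else:
        fitted = frames
    mean = fitted.mean(axis=0)
    per_atom = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))
    if not group_by_residue:
        return per_atom
    out = []
    seen: list[int] = []
    for res in traj.residue_index:
        if res not in seen:
            seen.append(res)
    for res in seen:
        sel = traj.residue_index == res
        out.append(float(np.average(per_atom[sel], weights=w[sel])))
    return np.array(out)


def rg_series(traj: Trajectory) -> np.ndarray:
    """Radius of gyration of every frame (the classic Rg-vs-time curve)."""
    return np.array([radius_of_gyration(f, traj.masses) for f in traj.frames])


def rmsd_series(traj: Trajectory, superpose: bool = True) -> np.ndarray:
    """RMSD of every frame to frame 1 (the equilibration diagnostic)."""
    return np.array(
        [rmsd(f, traj.frames[0], superpose=superpose, masses=traj.masses)
         for f in traj.frames]
    )


def read_trajectory(
    path: str | Path,
    mass_overrides: Optional[dict[str, float]] = None,
) -> Trajectory:
    """Read a multi-model PDB or XYZ file into a :class:`Trajectory`.

    Masses come from MDAnalysis' element/name-based guesser; entries of
    ``mass_overrides`` (atom label -> amu) take precedence, which also covers
    formats whose labels the guesser cannot resolve.
    """
    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        u = mda.Universe(str(path))
        labels = tuple(u.atoms.names)
        masses = np.array(u.atoms.masses, dtype=float)
        if mass_overrides:
            for i, lab in enumerate(labels):
                if lab in mass_overrides:
                    masses[i] = mass_overrides[lab]
        try:
            residues = np.array(u.atoms.resids, dtype=int)
        except mda.exceptions.NoDataError:
            residues = np.zeros(len(labels), dtype=int)
        frames = np.stack([u.atoms.positions.astype(float).copy() for _ in u.trajectory])
    if (masses <= 0).any():
        missing = sorted({labels[i] for i in np.flatnonzero(masses <= 0)})
        raise ValueError(
            f"{path}: could not infer positive masses for atoms {missing}; "
            "supply mass_overrides"
        )
    return Trajectory(
        frames=frames, masses=masses, atom_labels=labels, residue_index=residues
    )
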