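"""Trajectory analysis: superposition, RMSD/RMSF, essential dynamics.

Operates on :class:`TrajectoryEnsemble` objects — frames of coordinates
over a fixed topology — as produced by multi-model PDB readers or the
synthetic trajectory generator.  Superposition uses the Kabsch (SVD)
algorithm; essential dynamics is the eigen-decomposition of the 3N x 3N
covariance matrix of (typically C-alpha) coordinate fluctuations after
removal of overall translation and rotation.

Coordinates are mass-unweighted throughout; covariance uses 1/n_frames
normalization; eigenvalues are sorted descending and each eigenvector's
first nonzero component is made positive so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_io import AssemblyModel

__all__ = [
    "TrajectoryEnsemble",
    "EssentialDynamicsResult",
    "select_atoms",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "pca_essential_dynamics",
]


@dataclass
class TrajectoryEnsemble:
    """Frames of coordinates (Angstrom) over a fixed topology."""

    topology: AssemblyModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None  # ns, optional

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology {self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


def select_atoms(
    topology: AssemblyModel,
    selection: str = "calpha",
    chains: Sequence[str] | None = None,
) -> np.ndarray:
    """Indices (into the flat atom order) matching a named selection.

    ``"calpha"`` — CA atoms of polymer residues; ``"heavy"`` — all
    non-hydrogen atoms; ``"all"`` — everything.  ``chains`` restricts to
    the given chain ids.
    """
    idx = []
    i = 0
    for res in topology.residues():
        for atom in res.atoms:
            keep = chains is None or res.chain_id in chains
            if keep:
                if selection == "calpha":
                    keep = atom.name == "CA" and not res.is_hetero
                elif selection == "heavy":
                    keep = not atom.is_hydrogen
                elif selection == "all":
                    keep = True
                else:
                    raise ValueError(f"unknown selection {selection!r}")
            if keep:
                idx.append(i)
            i += 1
    return np.array(idx, dtype=int)


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    least-squares sense; the rotation is proper (det +1) and the returned
    RMSD is the global minimum over rigid transforms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    h = mc.T @ rc
    u, s, vt = np.linalg.svd(h)
    # collinear selections leave the rotation about the line undetermined
    if np.count_nonzero(s > max(s.max(), 1e-300) * 1e-9) < 2 and mc.std() > 0:
        raise ValueError("degenerate (collinear) selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = reference.mean(axis=0) - rot @ mobile.mean(axis=0)
    fitted = mc @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - rc) ** 2, axis=1))))
    return rot, trans, rmsd


def _fit_frames(
    frames: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray
) -> np.ndarray:
    """Superpose every frame onto the reference using the fit selection."""
    fitted = np.empty_like(frames)
    for i, frame in enumerate(frames):
        rot, trans, _ = kabsch_superpose(frame[fit_idx], reference[fit_idx])
        fitted[i] = frame @ rot.T + trans
    return fitted


def rmsd_series(
    traj: TrajectoryEnsemble,
    selection: np.ndarray | None = None,
    reference_frame: int = 0,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) vs a reference frame.

    With ``fit=True`` (default) each frame is first optimally superposed on
    the reference over the selection; with ``fit=False`` the raw coordinate
    RMSD is reported.
    """
    if selection is None:
        selection = np.arange(traj.n_atoms)
    if not 0 <= reference_frame < traj.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    ref = traj.frames[reference_frame][selection]
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        mob = frame[selection]
        if fit:
            _, _, out[i] = kabsch_superpose(mob, ref)
        else:
            out[i] = np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))
    return out


def rmsf(
    traj: TrajectoryEnsemble,
    selection: np.ndarray | None = None,
    fit: bool = True,
    per_residue: bool = True,
) -> np.ndarray:
    """Root-mean-square fluctuation about the time-average position.

    Per atom: sqrt(mean over frames of squared deviation from the mean
    position).  With ``per_residue=True`` atom values are averaged over the
    selected atoms of each residue (selection order defines residue order).
    With ``fit=True`` frames are first superposed on frame 0 over the
    selection, removing rigid-body motion.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if selection is None:
        selection = np.arange(traj.n_atoms)
    frames = traj.frames
    if fit:
        frames = _fit_frames(frames, frames[0], selection)
    sub = frames[:, selection, :]
    mean_pos = sub.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((sub - mean_pos) ** 2, axis=2), axis=0))
    if not per_residue:
        return per_atom
    atom_res = traj.topology.atom_residues()
    groups: list[list[int]] = []
    last_key = None
    for j, ai in enumerate(selection):
        key = atom_res[ai].key
        if key != last_key:
            groups.append([])
            last_key = key
        groups[-1].append(j)
    return np.array([per_atom[g].mean() for g in groups])


@dataclass
class EssentialDynamicsResult:
    """Eigen-decomposition of the coordinate covariance matrix."""

    eigenvalues: np.ndarray  # A^2, descending, full spectrum
    variance_fractions: np.ndarray  # sum to 1
    eigenvectors: np.ndarray  # (3N, k) leading modes, orthonormal columns
    projections: np.ndarray  # (n_frames, k)

    def __post_init__(self) -> None:
        tol = 1e-8 * max(1.0, float(self.eigenvalues.max(initial=0.0)))
        if np.any(self.eigenvalues < -tol):
            raise ValueError("covariance eigenvalues must be non-negative")
        if abs(self.variance_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("variance fractions must sum to 1")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("eigenvectors must be orthonormal")


def pca_essential_dynamics(
    traj: TrajectoryEnsemble,
    selection: np.ndarray | None = None,
    k: int = 3,
    fit: bool = False,
) -> EssentialDynamicsResult:
    """Essential dynamics PCA of selected coordinates.

    Frames are assumed already superposed on a common reference (set
    ``fit=True`` to superpose on frame 0 internally).  The covariance of
    the 3N selected coordinates (1/n_frames normalization) is
    diagonalized; ``variance_fractions`` are eigenvalues over their sum and
    ``projections`` are dot products of centered frame coordinates with
    the leading ``k`` modes.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if selection is None:
        selection = select_atoms(traj.topology, "calpha")
    frames = traj.frames
    if fit:
        frames = _fit_frames(frames, frames[0], selection)
    x = frames[:, selection, :].reshape(traj.n_frames, -1)  # (T, 3N)
    xc = x - x.mean(axis=0)
    cov = (xc.T @ xc) / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: first component of each mode that is nonzero -> positive
    for j in range(evecs.shape[1]):
        col = evecs[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            evecs[:, j] = -col
    k = min(k, evecs.shape[1])
    total = evals.sum()
    fractions = evals / total if total > 0 else np.full_like(evals, 1.0 / len(evals))
    return EssentialDynamicsResult(
        eigenvalues=evals,
        variance_fractions=fractions,
        eigenvectors=evecs[:, :k],
        projections=xc @ evecs[:, :k],
    )
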