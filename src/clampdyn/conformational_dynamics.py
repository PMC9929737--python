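"""Collective-motion analysis: superposition, RMSF, trajectory PCA, and an
anisotropic network model (ANM) on Cα atoms.

PCA of the aligned Cα fluctuations gives the dominant motions actually
sampled; the ANM gives the motions implied by the contact topology alone.
Agreement of the two (via mode overlap) is the evidence that a motion — such
as the anti-phase swing-out of a two-lobe dimer — emerges from the global
structure rather than from sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, svd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist
from scipy.spatial.transform import Rotation

from .io_formats import Structure, Trajectory


@dataclass(frozen=True)
class ModeSet:
    """Ordered set of collective modes.

    ``vectors`` has one unit-norm 3N eigenvector per row.  For PCA modes the
    eigenvalues are coordinate variances (Å²) sorted descending and
    ``variance_fraction`` sums to 1; for ANM modes the eigenvalues are
    Hessian stiffnesses sorted ascending (softest first) with the six
    rigid-body null modes removed.
    """

    vectors: np.ndarray  # (n_modes, 3N)
    eigenvalues: np.ndarray
    source: str  # "pca" | "anm"
    variance_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        gram = self.vectors @ self.vectors.T
        if not np.allclose(gram, np.eye(len(self.vectors)), atol=1e-8):
            raise ValueError("mode vectors must be orthonormal")
        if self.source == "pca":
            if self.variance_fraction is None or \
               abs(self.variance_fraction.sum() - 1.0) > 1e-9:
                raise ValueError("PCA variance fractions must sum to 1")
        if self.source == "anm" and np.any(self.eigenvalues < -1e-9):
            raise ValueError("ANM eigenvalues must be non-negative")

    @property
    def n_modes(self) -> int:
        return len(self.vectors)

    def mode(self, k: int) -> np.ndarray:
        return self.vectors[k]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,), Å
    rmsd: float  # post-fit, Å

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: largest-magnitude component positive."""
    k = np.argmax(np.abs(vec))
    return vec if vec[k] >= 0 else -vec


def superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: np.ndarray | None = None,
) -> tuple[SuperpositionResult, np.ndarray]:
    """Least-squares (Kabsch) fit of a frame onto a reference.

    The rotation/translation is determined on ``selection`` (positional atom
    indices; all atoms when omitted) and applied to the whole frame.
    Returns the fit result and the aligned frame.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    mob = mobile[sel]
    ref = reference[sel]
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    translation = ref.mean(axis=0) - mob.mean(axis=0) @ R.T
    aligned = mobile @ R.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((aligned[sel] - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=translation, rmsd=rmsd), aligned


def align_trajectory(
    traj: Trajectory, reference: np.ndarray | None = None,
    selection: np.ndarray | None = None,
) -> Trajectory:
    """Superpose every frame onto a common reference (default: frame 0)."""
    ref = traj.frames[0] if reference is None else reference
    aligned = np.empty_like(traj.frames)
    for t in range(traj.n_frames):
        _, aligned[t] = superpose(traj.frames[t], ref, selection)
    return Trajectory(structure=traj.structure, frames=aligned, dt=traj.dt,
                      metadata={**traj.metadata, "aligned": True})


def rmsf(traj: Trajectory, selection: np.ndarray | None = None) -> np.ndarray:
    """Root-mean-square fluctuation per atom about its trajectory mean (Å)."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.arange(traj.structure.n_atoms) if selection is None else selection
    x = traj.frames[:, sel]
    dev = x - x.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def pca_modes(traj: Trajectory, selection: np.ndarray | None = None) -> ModeSet:
    """PCA of Cα fluctuations about the global trajectory mean.

    Frames must be pre-aligned (see :func:`align_trajectory`); replica
    trajectories can be pooled by concatenating their frames first.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    sel = np.arange(traj.structure.n_atoms) if selection is None else selection
    X = traj.frames[:, sel].reshape(traj.n_frames, -1)
    X = X - X.mean(axis=0)
    _, s, vt = svd(X, full_matrices=False)
    lam = s**2 / (traj.n_frames - 1)
    total = lam.sum()
    if total <= 1e-14:
        raise ValueError("zero total variance: static trajectory")
    keep = lam > 1e-12 * lam[0]
    vectors = np.array([_fix_sign(v) for v in vt[keep]])
    return ModeSet(vectors=vectors, eigenvalues=lam[keep], source="pca",
                   variance_fraction=lam[keep] / lam[keep].sum())


def anm_hessian(
    positions: np.ndarray, cutoff: float = 15.0, gamma: float = 1.0,
) -> np.ndarray:
    """Standard superelement ANM Hessian with uniform spring constant."""
    n = len(positions)
    dmat = squareform(pdist(positions))
    adj = (dmat < cutoff) & ~np.eye(n, dtype=bool)
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"elastic network disconnected at cutoff {cutoff} Å "
            f"({n_comp} components)"
        )
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in np.flatnonzero(adj[i]):
            if j <= i:
                continue
            e = positions[j] - positions[i]
            block = -gamma * np.outer(e, e) / (e @ e)
            H[3*i:3*i+3, 3*j:3*j+3] = block
            H[3*j:3*j+3, 3*i:3*i+3] = block
            H[3*i:3*i+3, 3*i:3*i+3] -= block
            H[3*j:3*j+3, 3*j:3*j+3] -= block
    return H


def anm_modes(
    structure: Structure, cutoff: float = 15.0, gamma: float = 1.0,
) -> ModeSet:
    """ANM normal modes, softest first, rigid-body null space removed."""
    H = anm_hessian(structure.positions, cutoff=cutoff, gamma=gamma)
    evals, evecs = eigh(H)
    zero = np.abs(evals) < 1e-8 * evals.max()
    evals = np.clip(evals, 0.0, None)
    # collinear geometries have one fewer rotational degree of freedom
    centered = structure.positions - structure.positions.mean(axis=0)
    expected = 5 if np.linalg.matrix_rank(centered, tol=1e-8) < 2 else 6
    if zero.sum() != expected:
        raise ValueError(
            f"expected {expected} rigid-body modes, found {int(zero.sum())}"
        )
    keep = ~zero
    vectors = np.array([_fix_sign(v) for v in evecs[:, keep].T])
    return ModeSet(vectors=vectors, eigenvalues=evals[keep], source="anm")


def mode_overlap(mode: np.ndarray, direction: np.ndarray) -> float:
    """|cosine| between a mode and a reference displacement direction."""
    a = np.asarray(mode, float).ravel()
    b = np.asarray(direction, float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    return float(abs(a @ b) / (na * nb))
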