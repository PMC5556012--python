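"""Cα trajectory analysis: superposition, covariance PCA, collectivity, DCCM.

Global translation and rotation are removed by a two-pass RMS fit: fit on all
residues, rank residues by RMSF, refit on the least-fluctuating fraction
(default 15%).  PCA diagonalizes the 3N×3N Cα covariance matrix; each
eigenvalue is the mean-square fluctuation along its mode.  The collectivity
index

    κ = (1/N) exp( − Σ_i Δr_i² ln Δr_i² ),   Σ_i Δr_i² = 1

measures how many of the N atoms a mode involves: κ = 1 for a uniform mode,
κ = 1/N when a single atom moves (natural logarithm — required for the
uniform-mode value of exactly 1).  The dynamic cross-correlation map uses the
vector-dot-product convention C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import TrajectoryEnsemble

__all__ = [
    "PCAResult",
    "rms_fit_least_fluctuating",
    "superpose",
    "covariance_pca",
    "collectivity",
    "cross_correlation",
    "block_mean_correlation",
]


@dataclass
class PCAResult:
    """Eigenmodes of the Cα coordinate covariance.

    ``eigenvalues`` (Å², descending), ``eigenvectors`` as rows over the 3N
    coordinates, orthonormal; ``variance_fraction`` sums to 1.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_modes, 3N)
    mean_structure: np.ndarray  # (N, 3)
    variance_fraction: np.ndarray

    def mode_displacements(self, m: int) -> np.ndarray:
        """Per-atom displacement vectors (N, 3) of mode m."""
        return self.eigenvectors[m].reshape(-1, 3)


def _kabsch(mobile: np.ndarray, ref: np.ndarray, weights: np.ndarray | None = None):
    """Optimal rotation+translation of ``mobile`` onto ``ref`` (weighted)."""
    if weights is None:
        weights = np.ones(len(ref))
    w = weights / weights.sum()
    mc = (mobile * w[:, None]).sum(axis=0)
    rc = (ref * w[:, None]).sum(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc, weights=weights)
    return rot, mc, rc


def superpose(traj: TrajectoryEnsemble, selection: np.ndarray | None = None,
              reference: np.ndarray | None = None) -> TrajectoryEnsemble:
    """Superpose every frame on a reference using the selected residues.

    Default reference is the first frame (refined below in the two-pass fit);
    the transform is fitted on ``selection`` but applied to all atoms.
    """
    coords = traj.coords
    ref = coords[0] if reference is None else reference
    sel = np.arange(coords.shape[1]) if selection is None else np.asarray(selection)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, mc, rc = _kabsch(coords[f, sel], ref[sel])
        out[f] = rot.apply(coords[f] - mc) + rc
    return TrajectoryEnsemble(out, traj.times.copy(), list(traj.residue_ids))


def rms_fit_least_fluctuating(
    traj: TrajectoryEnsemble, fraction: float = 0.15
) -> tuple[TrajectoryEnsemble, np.ndarray]:
    """Two-pass RMS fit on the least-fluctuating residue fraction.

    Pass 1 fits all frames on the all-residue mean, computes per-residue
    RMSF, and selects the lowest ``fraction``; pass 2 refits on that
    selection.  Returns the aligned trajectory and the selected indices.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    pass1 = superpose(traj)
    # iterate the mean once so the reference is the ensemble mean, not frame 0
    pass1 = superpose(pass1, reference=pass1.coords.mean(axis=0))
    rmsf = _rmsf(pass1.coords)
    n_sel = max(3, int(round(fraction * len(rmsf))))
    selection = np.sort(np.argsort(rmsf, kind="stable")[:n_sel])
    aligned = superpose(traj, selection=selection)
    aligned = superpose(aligned, selection=selection, reference=aligned.coords.mean(axis=0))
    return aligned, selection


def _rmsf(coords: np.ndarray) -> np.ndarray:
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


def covariance_pca(traj: TrajectoryEnsemble) -> PCAResult:
    """Eigendecomposition of the 3N×3N Cα covariance of an aligned trajectory."""
    if traj.n_frames < 2:
        raise ValueError("need at least two frames for a covariance")
    flat = traj.coords.reshape(traj.n_frames, -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PCAResult(evals, evecs, mean.reshape(-1, 3), frac)


def collectivity(mode: np.ndarray, subset: np.ndarray | None = None) -> float:
    """Collectivity index κ of a mode over an atom subset.

    ``mode`` is (N, 3) or flat 3N; squared per-atom displacements are
    renormalized to sum to 1 over the subset before evaluating
    κ = (1/N) exp(−Σ Δr_i² ln Δr_i²).  Invariant to overall mode scaling;
    bounded by 1/N ≤ κ ≤ 1.
    """
    disp = np.asarray(mode, dtype=float).reshape(-1, 3)
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValueError("subset must be nonempty")
        disp = disp[subset]
    n = len(disp)
    sq = (disp**2).sum(axis=1)
    total = sq.sum()
    if total <= 0:
        raise ValueError("mode has zero displacement on the subset; κ undefined")
    sq = sq / total
    nz = sq[sq > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    return float(np.exp(entropy) / n)


def cross_correlation(traj: TrajectoryEnsemble) -> np.ndarray:
    """DCCM: C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩) over frames.

    Zero-variance residues get 0 off-diagonal (with a warning); the diagonal
    is 1.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    dev = traj.coords - traj.coords.mean(axis=0)
    # ⟨Δr_i·Δr_j⟩: sum over xyz of per-component covariances
    inner = np.einsum("fik,fjk->ij", dev, dev) / traj.n_frames
    var = np.diag(inner).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance residues; correlations set to 0")
        var[zero] = 1.0
    c = inner / np.sqrt(np.outer(var, var))
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def block_mean_correlation(
    corr: np.ndarray,
    block_i: np.ndarray,
    block_j: np.ndarray,
) -> float:
    """Mean correlation over the inter-block entries (blocks must be disjoint)."""
    bi = np.asarray(block_i)
    bj = np.asarray(block_j)
    if bi.size == 0 or bj.size == 0:
        raise ValueError("blocks must be nonempty")
    if np.intersect1d(bi, bj).size:
        raise ValueError("blocks must be disjoint")
    return float(corr[np.ix_(bi, bj)].mean())
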