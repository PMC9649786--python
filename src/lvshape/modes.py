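"""Principal-component shape modes of the atlas momenta.

PCA is run on the per-subject *initial momenta* (not on vertex
displacements), under the deformation-kernel inner product

    <m, m'>_K = sum_ab K(c_a, c_b; lambda_diffeos) m_a . m'_b

which is the natural metric of a kernel control-point atlas (a plain
euclidean metric is available as a fallback).  The decomposition is done
on the n x n centred Gram matrix, so it stays cheap for any number of
control points.  Per-mode "inertia" is the percentage of total variance
carried by the mode; subjects' coordinates along the modes are the shape
vectors used by the association layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas, MomentaField
from .kernels import gaussian_kernel_matrix
from .mesh import TriangleMesh, write_mesh

__all__ = [
    "ShapeModeBasis",
    "ShapeScores",
    "compute_modes",
    "subject_scores",
    "reconstruct_at_sd",
    "cumulative_inertia",
    "save_modes",
]

_DEFAULT_CUMULATIVE_TARGET = 54.0  # % variance the retained modes must reach


@dataclass
class ShapeModeBasis:
    """Eigenstructure of the centred momenta under the declared metric."""

    eigenvectors: np.ndarray  # (n_modes, n_cp, 3), orthonormal under metric
    eigenvalues: np.ndarray  # (n_modes,), non-increasing, > 0
    inertia_pct: np.ndarray  # (n_modes,), sums to 100
    cumulative_pct: np.ndarray
    metric: str  # "kernel" or "euclidean"
    mean_momenta: np.ndarray = field(default=None)  # (n_cp, 3)
    n_retained: int = 0

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ShapeScores:
    """Per-subject coordinates along the shape modes ("shape vectors")."""

    matrix: np.ndarray  # (n_subjects, n_modes)
    subject_ids: list[str]

    @property
    def n_modes(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"M{k + 1}" for k in range(self.n_modes)]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def _metric_gram(momenta: np.ndarray, atlas: Atlas, metric: str) -> np.ndarray:
    """Gram matrix G_st = <m_s, m_t> under the chosen metric."""
    if metric == "kernel":
        K = gaussian_kernel_matrix(
            atlas.control_points.points,
            atlas.control_points.points,
            atlas.control_points.kernel_width,
        )
        A = np.einsum("ab,sbk->sak", K, momenta)
        return np.einsum("sak,tak->st", A, momenta)
    if metric == "euclidean":
        flat = momenta.reshape(len(momenta), -1)
        return flat @ flat.T
    raise ValueError(f"unknown metric '{metric}'")


def _metric_inner(m: np.ndarray, w: np.ndarray, atlas: Atlas, metric: str) -> np.ndarray:
    """<m_s, w_k> for stacked momenta m (s,P,3) and modes w (k,P,3)."""
    if metric == "kernel":
        K = gaussian_kernel_matrix(
            atlas.control_points.points,
            atlas.control_points.points,
            atlas.control_points.kernel_width,
        )
        A = np.einsum("ab,kbj->kaj", K, w)
        return np.einsum("saj,kaj->sk", m, A)
    flat_m = m.reshape(len(m), -1)
    flat_w = w.reshape(len(w), -1)
    return flat_m @ flat_w.T


def compute_modes(atlas: Atlas, metric: str = "kernel") -> ShapeModeBasis:
    """Eigen-decompose the centred momenta Gram matrix into shape modes.

    Eigenvalues are variances with the (n-1) sample normalisation, so a
    mode's eigenvalue equals the variance of the subjects' scores along
    it.  Modes with numerically zero variance are dropped; inertia
    percentages are computed over every positive mode and sum to 100.
    """
    M = atlas.momenta_array()
    n = len(M)
    if n < 3:
        raise ValueError("mode extraction requires at least 3 subjects")
    mean = M.mean(axis=0)
    Mc = M - mean
    G = _metric_gram(Mc, atlas, metric)
    G = 0.5 * (G + G.T)  # deterministic symmetrisation
    total_var = np.trace(G) / (n - 1)
    if total_var <= 1e-30:
        raise ValueError("degenerate population: all subjects identical")
    sigma, U = np.linalg.eigh(G)
    order = np.argsort(sigma)[::-1]
    sigma, U = sigma[order], U[:, order]
    keep = sigma > max(sigma[0] * 1e-12, 1e-30)
    sigma, U = sigma[keep], U[:, keep]

    # momentum-space directions, orthonormal under the metric
    W = np.einsum("sk,spj->kpj", U / np.sqrt(sigma)[None, :], Mc)

    # deterministic sign convention: largest-|.| loading positive
    for k in range(len(sigma)):
        flat = W[k].ravel()
        j = int(np.argmax(np.abs(flat)))
        if flat[j] < 0:
            W[k] = -W[k]
            U[:, k] = -U[:, k]

    eigenvalues = sigma / (n - 1)
    inertia = 100.0 * eigenvalues / eigenvalues.sum()
    cumulative = np.cumsum(inertia)
    n_retained = int(np.searchsorted(cumulative, _DEFAULT_CUMULATIVE_TARGET) + 1)
    n_retained = min(n_retained, len(sigma))
    return ShapeModeBasis(
        eigenvectors=W,
        eigenvalues=eigenvalues,
        inertia_pct=inertia,
        cumulative_pct=cumulative,
        metric=metric,
        mean_momenta=mean,
        n_retained=n_retained,
    )


def subject_scores(atlas: Atlas, basis: ShapeModeBasis) -> ShapeScores:
    """Project each subject's centred momenta onto the modes.

    Score columns are exactly centred and their sample variances equal
    the corresponding eigenvalues.
    """
    M = atlas.momenta_array()
    if basis.mean_momenta.shape != M.shape[1:]:
        raise ValueError("basis does not match this atlas (control-point mismatch)")
    Mc = M - basis.mean_momenta
    S = _metric_inner(Mc, basis.eigenvectors, atlas, basis.metric)
    return ShapeScores(matrix=S, subject_ids=atlas.subject_ids)


def reconstruct_at_sd(
    atlas: Atlas,
    basis: ShapeModeBasis,
    mode_index: int,
    sd_multiple: float = 2.7,
    n_steps: int | None = None,
) -> tuple[TriangleMesh, TriangleMesh]:
    """Template shot to +/- ``sd_multiple`` standard deviations of a mode.

    The conventional visualisation of mode extremities: the template is
    deformed along ``+/- sd * sqrt(eigenvalue) * mode`` (mode_index is
    0-based).
    """
    from .atlas import shoot_and_flow

    if not (0 <= mode_index < basis.n_modes):
        raise ValueError(f"mode_index {mode_index} out of range")
    lam = basis.eigenvalues[mode_index]
    if lam <= 0:
        raise ValueError("zero-variance mode cannot be reconstructed")
    steps = n_steps if n_steps is not None else atlas.n_steps
    amp = sd_multiple * np.sqrt(lam)
    out = []
    for sign in (+1.0, -1.0):
        mom = MomentaField(
            sign * amp * basis.eigenvectors[mode_index],
            atlas.control_points,
            subject_id=f"mode{mode_index + 1}_{'plus' if sign > 0 else 'minus'}",
        )
        mesh = shoot_and_flow(atlas.template, atlas.control_points, mom, steps)
        mesh.label = mom.subject_id
        out.append(mesh)
    return out[0], out[1]


def cumulative_inertia(basis: ShapeModeBasis, k: int) -> float:
    """Percentage of total shape variance carried by the first k modes."""
    if not (1 <= k <= basis.n_modes):
        raise ValueError(f"k must be in [1, {basis.n_modes}]")
    return float(basis.cumulative_pct[k - 1])


def save_modes(
    atlas: Atlas,
    basis: ShapeModeBasis,
    scores: ShapeScores,
    directory: str | Path,
    sd_multiple: float = 2.7,
    write_reconstructions: bool = True,
) -> None:
    """Write eigen.csv, scores.csv and the mode-extremity meshes."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    eig = pd.DataFrame(
        {
            "mode": np.arange(1, basis.n_modes + 1),
            "eigenvalue": basis.eigenvalues,
            "inertia_pct": basis.inertia_pct,
            "cumulative_pct": basis.cumulative_pct,
        }
    )
    eig.to_csv(d / "eigen.csv", index=False)
    scores.to_frame().iloc[:, : basis.n_retained + 1].to_csv(d / "scores.csv", index=False)
    if write_reconstructions:
        for k in range(basis.n_retained):
            plus, minus = reconstruct_at_sd(atlas, basis, k, sd_multiple)
            write_mesh(plus, d / f"mode{k + 1}_plus{sd_multiple}sd.ply")
            write_mesh(minus, d / f"mode{k + 1}_minus{sd_multiple}sd.ply")
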