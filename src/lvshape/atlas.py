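"""Kernel control-point atlas estimation for LV surface populations.

The deformation model is the standard control-point parameterisation of
diffeomorphic flows: a regular grid of control points carries momentum
vectors, the induced velocity field is a Gaussian-kernel interpolation,
and shapes are advected by integrating the Hamiltonian point system with
explicit Euler steps.  The data-attachment term is an unoriented varifold
metric (correspondence-free, robust to the open base rim of a clipped LV
surface).  Atlas estimation alternates gradient steps on per-subject
momenta and on the template vertices, with backtracking line searches so
the objective never increases on an accepted step.

Two kernel widths control the model, following the usual convention of
naming them after their roles:

* ``lambda_diffeos`` (default 35 mm) -- width of the deformation kernel;
  larger values give stiffer, more global deformations.
* ``lambda_surface`` (default 11 mm) -- width of the varifold kernel;
  larger values ignore smaller surface features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kernels import (
    gaussian_kernel_matrix,
    kernel_apply,
    kernel_apply_vjp,
    momentum_drift,
    momentum_drift_vjp,
)
from .mesh import TriangleMesh, write_mesh, read_mesh
from .remesh import closest_point_on_surface

__all__ = [
    "ControlPointSet",
    "MomentaField",
    "Atlas",
    "build_control_grid",
    "shoot_and_flow",
    "varifold_distance",
    "estimate_atlas",
    "atlas_residual",
    "save_atlas",
    "load_atlas",
]


@dataclass
class ControlPointSet:
    """Regular grid of deformation control points (spacing = kernel width)."""

    points: np.ndarray
    kernel_width: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class MomentaField:
    """Momentum vectors attached to a control-point set, for one subject."""

    momenta: np.ndarray
    control_points: ControlPointSet
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.momenta = np.asarray(self.momenta, dtype=np.float64)
        if self.momenta.shape != (self.control_points.n_points, 3):
            raise ValueError(
                f"momenta shape {self.momenta.shape} does not match "
                f"{self.control_points.n_points} control points"
            )
        if not np.all(np.isfinite(self.momenta)):
            raise ValueError("momenta contain non-finite values")

    def kernel_norm_sq(self) -> float:
        """|p|^2_K = sum_ab K(c_a, c_b) p_a . p_b."""
        K = gaussian_kernel_matrix(
            self.control_points.points, self.control_points.points, self.control_points.kernel_width
        )
        return float(np.einsum("ab,ak,bk->", K, self.momenta, self.momenta))


@dataclass
class Atlas:
    """Estimated template plus the per-subject deformations around it."""

    template: TriangleMesh
    control_points: ControlPointSet
    subject_momenta: list[MomentaField]
    attachment_width: float
    loss_trace: list[float] = field(default_factory=list)
    residuals: dict[str, dict[str, float]] = field(default_factory=dict)
    reg_weight: float = 1e-2
    n_steps: int = 10
    converged: bool = True

    @property
    def n_subjects(self) -> int:
        return len(self.subject_momenta)

    @property
    def subject_ids(self) -> list[str]:
        return [m.subject_id for m in self.subject_momenta]

    def momenta_array(self) -> np.ndarray:
        """(n_subjects, n_cp, 3) stacked momenta."""
        return np.stack([m.momenta for m in self.subject_momenta])


def build_control_grid(
    meshes: list[TriangleMesh], kernel_width: float = 35.0, margin: float = 0.0
) -> ControlPointSet:
    """Axis-aligned grid over the population bounding box, spacing = width.

    Each axis gets ``ceil(extent / spacing) + 1`` points (minimum 2), so the
    grid always covers the box plus the margin.
    """
    if not meshes:
        raise ValueError("no meshes supplied")
    if kernel_width <= 0:
        raise ValueError("kernel_width must be positive")
    lo = np.min([m.vertices.min(axis=0) for m in meshes], axis=0) - margin
    hi = np.max([m.vertices.max(axis=0) for m in meshes], axis=0) + margin
    extent = hi - lo
    if np.any(extent <= 0):
        raise ValueError("degenerate bounding box")
    axes = []
    for k in range(3):
        n = max(int(np.ceil(extent[k] / kernel_width)) + 1, 2)
        # centre the grid on the box
        span = (n - 1) * kernel_width
        start = lo[k] - (span - extent[k]) / 2.0
        axes.append(start + kernel_width * np.arange(n))
    g = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([a.ravel() for a in g], axis=1)
    return ControlPointSet(pts, kernel_width)


# ---------------------------------------------------------------------------
# geodesic shooting
# ---------------------------------------------------------------------------

def _flow_forward(
    x0: np.ndarray, c0: np.ndarray, p0: np.ndarray, width: float, n_steps: int
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Explicit-Euler integration of the Hamiltonian point system.

    Returns the full trajectory [(x_t, c_t, p_t)] for t = 0..n_steps; the
    trajectory is needed for the reverse-mode pass.
    """
    h = 1.0 / n_steps
    traj = [(x0, c0, p0)]
    x, c, p = x0, c0, p0
    for _ in range(n_steps):
        dx = kernel_apply(x, c, p, width)
        dc = kernel_apply(c, c, p, width)
        dp = momentum_drift(c, p, width)
        x = x + h * dx
        c = c + h * dc
        p = p + h * dp
        traj.append((x, c, p))
    return traj


def _flow_backward(
    traj: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    width: float,
    gx_final: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Reverse-mode sweep: returns (dL/dx0, dL/dp0) given dL/dx_final."""
    n_steps = len(traj) - 1
    h = 1.0 / n_steps
    gx = gx_final.copy()
    gc = np.zeros_like(traj[0][1])
    gp = np.zeros_like(traj[0][2])
    for t in range(n_steps - 1, -1, -1):
        x, c, p = traj[t]
        # x_{t+1} = x + h K(x,c) p
        vy, vz, vq = kernel_apply_vjp(x, c, p, width, gx)
        # c_{t+1} = c + h K(c,c) p  (y and z are both c)
        cy, cz, cq = kernel_apply_vjp(c, c, p, width, gc)
        # p_{t+1} = p + h * drift(c, p)
        dc_, dp_ = momentum_drift_vjp(c, p, width, gp)
        gx_new = gx + h * vy
        gc_new = gc + h * (vz + cy + cz + dc_)
        gp_new = gp + h * (vq + cq + dp_)
        gx, gc, gp = gx_new, gc_new, gp_new
    return gx, gp


def shoot_and_flow(
    template: TriangleMesh,
    cps: ControlPointSet,
    momenta: MomentaField,
    n_steps: int = 10,
) -> TriangleMesh:
    """Deform a mesh by geodesic shooting of the control-point system.

    Zero momenta return the template unchanged (exact identity); face
    connectivity is never altered.  A warning reports any triangle whose
    orientation flips relative to its own initial normal (a sign the
    deformation stopped being diffeomorphic at this step size).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if momenta.control_points is not cps and not np.array_equal(
        momenta.control_points.points, cps.points
    ):
        raise ValueError("momenta are not paired with the given control points")
    p0 = momenta.momenta
    if not np.all(np.isfinite(p0)):
        raise ValueError("momenta contain non-finite values")
    if np.allclose(p0, 0.0):
        return template.copy()
    traj = _flow_forward(template.vertices, cps.points, p0, cps.kernel_width, n_steps)
    out = TriangleMesh(traj[-1][0], template.faces.copy(), template.label)
    n_before, _ = template.face_normals_area()
    n_after, _ = out.face_normals_area()
    flips = int(((n_before * n_after).sum(axis=1) < 0).sum())
    if flips:
        warnings.warn(
            f"shoot_and_flow: {flips} triangle(s) flipped orientation; "
            "deformation is not diffeomorphic at this resolution",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# varifold attachment
# ---------------------------------------------------------------------------

def _face_rep(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Face centers, area-weighted normals N (|N| = area), areas."""
    a, b, c = mesh.face_corners()
    centers = (a + b + c) / 3.0
    N = 0.5 * np.cross(b - a, c - a)
    area = np.linalg.norm(N, axis=1)
    return centers, N, area


def _varifold_inner(
    cx: np.ndarray, Nx: np.ndarray, ax: np.ndarray,
    cy: np.ndarray, Ny: np.ndarray, ay: np.ndarray,
    width: float,
) -> float:
    """sum_fg rho(c_f, c_g) (N_f . N_g)^2 / (a_f a_g)  (unoriented varifold)."""
    rho = gaussian_kernel_matrix(cx, cy, width)
    dots = Nx @ Ny.T
    denom = np.maximum(ax[:, None] * ay[None, :], 1e-30)
    return float((rho * dots**2 / denom).sum())


def varifold_distance(a: TriangleMesh, b: TriangleMesh, width: float = 11.0) -> float:
    """Squared varifold norm of the difference between two surfaces.

    Gaussian kernel of the given width on face centers; unoriented unit
    normals weighted by face areas.  Symmetric, zero iff the surfaces carry
    the same varifold; no point correspondence is required.
    """
    ca, Na, aa = _face_rep(a)
    cb, Nb, ab = _face_rep(b)
    return (
        _varifold_inner(ca, Na, aa, ca, Na, aa, width)
        - 2.0 * _varifold_inner(ca, Na, aa, cb, Nb, ab, width)
        + _varifold_inner(cb, Nb, ab, cb, Nb, ab, width)
    )


def _varifold_grad_vertices(
    mesh_x: TriangleMesh, target: TriangleMesh, width: float,
    target_self: float | None = None,
) -> tuple[float, np.ndarray]:
    """d(X, target) and its gradient w.r.t. the vertices of X.

    ``target_self`` may carry the precomputed <T, T> term (it does not
    depend on X and dominates repeated evaluations against a fixed
    subject).  Each kernel block is computed once and shared between the
    value and the gradient.
    """
    cx, Nx, ax = _face_rep(mesh_x)
    ct, Nt, at = _face_rep(target)
    w2 = width**2

    def block(cy, Ny, ay):
        rho = gaussian_kernel_matrix(cx, cy, width)
        dots = Nx @ Ny.T
        denom = np.maximum(ax[:, None] * ay[None, :], 1e-30)
        w = dots**2 / denom
        value = float((rho * w).sum())
        # center gradient: -(2/w2) sum_g rho w (c_f - c_g)
        rw = rho * w * (2.0 / w2)
        g_c = -(rw.sum(axis=1)[:, None] * cx - rw @ cy)
        # normal gradient
        g_N = (rho * 2.0 * dots / denom) @ Ny
        coef2 = (rho * w / np.maximum(ax, 1e-30)[:, None] ** 2).sum(axis=1)
        g_N -= coef2[:, None] * Nx
        return value, g_c, g_N

    exx, gc1, gN1 = block(cx, Nx, ax)
    ext, gc2, gN2 = block(ct, Nt, at)
    ett = (
        target_self
        if target_self is not None
        else _varifold_inner(ct, Nt, at, ct, Nt, at, width)
    )
    value = exx - 2.0 * ext + ett
    g_c = 2.0 * gc1 - 2.0 * gc2  # <X,X> is quadratic in X; <X,T> linear
    g_N = 2.0 * gN1 - 2.0 * gN2

    # chain to vertices: c_f = (v0+v1+v2)/3 ; N_f = 0.5 (v1-v0) x (v2-v0)
    grad = np.zeros_like(mesh_x.vertices)
    f = mesh_x.faces
    v = mesh_x.vertices
    va, vb, vc = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    for k in range(3):
        np.add.at(grad, f[:, k], g_c / 3.0)
    np.add.at(grad, f[:, 0], 0.5 * np.cross(vb - vc, g_N))
    np.add.at(grad, f[:, 1], 0.5 * np.cross(vc - va, g_N))
    np.add.at(grad, f[:, 2], 0.5 * np.cross(va - vb, g_N))
    return value, grad


# ---------------------------------------------------------------------------
# atlas estimation
# ---------------------------------------------------------------------------

def _subject_loss_and_grads(
    template_v: np.ndarray,
    faces: np.ndarray,
    c0: np.ndarray,
    p0: np.ndarray,
    target: TriangleMesh,
    width_def: float,
    width_att: float,
    reg_weight: float,
    att_norm: float,
    n_steps: int,
    need_grads: bool = True,
    target_self: float | None = None,
):
    """Loss = varifold/att_norm + reg |p|^2_K and gradients w.r.t. (x0, p0)."""
    traj = _flow_forward(template_v, c0, p0, width_def, n_steps)
    deformed = TriangleMesh(traj[-1][0], faces)
    if need_grads:
        att, g_xT = _varifold_grad_vertices(deformed, target, width_att, target_self)
    else:
        cx, Nx, ax = _face_rep(deformed)
        ct, Nt, at = _face_rep(target)
        ett = (
            target_self
            if target_self is not None
            else _varifold_inner(ct, Nt, at, ct, Nt, at, width_att)
        )
        att = (
            _varifold_inner(cx, Nx, ax, cx, Nx, ax, width_att)
            - 2.0 * _varifold_inner(cx, Nx, ax, ct, Nt, at, width_att)
            + ett
        )
    Kcc = gaussian_kernel_matrix(c0, c0, width_def)
    reg = float(np.einsum("ab,ak,bk->", Kcc, p0, p0))
    loss = att / att_norm + reg_weight * reg
    if not need_grads:
        return loss, None, None
    g_x0, g_p0 = _flow_backward(traj, width_def, g_xT / att_norm)
    g_p0 = g_p0 + reg_weight * 2.0 * (Kcc @ p0)
    return loss, g_x0, g_p0


def estimate_atlas(
    meshes: list[TriangleMesh],
    lambda_diffeos: float = 35.0,
    lambda_surface: float = 11.0,
    reg_weight: float = 1e-2,
    max_iter: int = 200,
    tol: float = 1e-5,
    seed: int = 0,
    n_steps: int = 10,
    control_points: ControlPointSet | None = None,
    grid_margin: float | None = None,
    template_init: str = "medoid",
    inner_iter: int = 5,
) -> Atlas:
    """Estimate the population template and per-subject momenta.

    Minimises, over the template vertices and one momentum field per
    subject,

        sum_s [ varifold(shoot(template, p_s), subject_s) / F_T
                + reg_weight * |p_s|^2_K ]

    (F_T = template face count) by alternating backtracking gradient steps
    on momenta and template.  The loss trace is non-increasing on accepted
    steps; the run is fully deterministic given inputs and seed.
    """
    if len(meshes) < 3:
        raise ValueError("atlas estimation requires at least 3 subjects")
    rng = np.random.default_rng(seed)  # reserved for future stochastic variants
    del rng

    if control_points is None:
        margin = lambda_diffeos / 2.0 if grid_margin is None else grid_margin
        control_points = build_control_grid(meshes, lambda_diffeos, margin)
    c0 = control_points.points

    # template initialisation
    if template_init == "medoid":
        totals = []
        for i, m in enumerate(meshes):
            tot = sum(
                varifold_distance(m, other, lambda_surface)
                for j, other in enumerate(meshes)
                if j != i
            )
            totals.append(tot)
        t_idx = int(np.argmin(totals))
    elif template_init == "first":
        t_idx = 0
    else:
        raise ValueError(f"unknown template_init '{template_init}'")
    template_v = meshes[t_idx].vertices.copy()
    faces = meshes[t_idx].faces.copy()
    att_norm = float(len(faces))
    tself = []
    for m in meshes:
        cm, Nm, am = _face_rep(m)
        tself.append(_varifold_inner(cm, Nm, am, cm, Nm, am, lambda_surface))

    n_cp = control_points.n_points
    momenta = [np.zeros((n_cp, 3)) for _ in meshes]
    step_t = 1.0

    def total_loss() -> float:
        return sum(
            _subject_loss_and_grads(
                template_v, faces, c0, momenta[s], meshes[s],
                lambda_diffeos, lambda_surface, reg_weight, att_norm,
                n_steps, need_grads=False, target_self=tself[s],
            )[0]
            for s in range(len(meshes))
        )

    loss_trace = [total_loss()]
    converged = False
    stall = 0
    for _ in range(max_iter):
        # ---- momenta steps (per subject, separable) ----
        # each subject's registration subproblem is smooth and nearly
        # quadratic in p, so a few warm-started L-BFGS iterations converge
        # far faster than single preconditioned gradient steps; the update
        # is accepted only when it lowers that subject's loss, keeping the
        # total trace non-increasing
        from scipy.optimize import minimize as _minimize

        for s in range(len(meshes)):

            def _obj(pf, s=s):
                loss, _, gp = _subject_loss_and_grads(
                    template_v, faces, c0, pf.reshape(n_cp, 3), meshes[s],
                    lambda_diffeos, lambda_surface, reg_weight, att_norm,
                    n_steps, target_self=tself[s],
                )
                return loss, gp.ravel()

            cur_s = _obj(momenta[s].ravel())[0]
            res = _minimize(
                _obj, momenta[s].ravel(), jac=True, method="L-BFGS-B",
                options={"maxiter": inner_iter},
            )
            if res.fun < cur_s:
                momenta[s] = res.x.reshape(n_cp, 3)

        # ---- template step (joint over subjects) ----
        g_t = np.zeros_like(template_v)
        cur = 0.0
        for s in range(len(meshes)):
            loss_s, g_x, _ = _subject_loss_and_grads(
                template_v, faces, c0, momenta[s], meshes[s],
                lambda_diffeos, lambda_surface, reg_weight, att_norm, n_steps,
                target_self=tself[s],
            )
            g_t += g_x
            cur += loss_s
        gn = np.linalg.norm(g_t)
        if gn > 1e-14:
            K_vv = gaussian_kernel_matrix(template_v, template_v, lambda_surface)
            g_t = K_vv @ g_t / len(template_v)  # Sobolev-smoothed descent direction
            eta = step_t
            for _bt in range(30):
                trial_v = template_v - eta * g_t
                trial_loss = sum(
                    _subject_loss_and_grads(
                        trial_v, faces, c0, momenta[s], meshes[s],
                        lambda_diffeos, lambda_surface, reg_weight, att_norm,
                        n_steps, need_grads=False, target_self=tself[s],
                    )[0]
                    for s in range(len(meshes))
                )
                if trial_loss < cur:
                    template_v = trial_v
                    step_t = eta * 1.5
                    cur = trial_loss
                    break
                eta *= 0.5
            else:
                step_t = max(eta, 1e-16)

        # ---- momenta centering (template identifiability) ----
        # With a weak momentum penalty the attachment term alone leaves the
        # template position nearly degenerate (momenta can absorb any common
        # offset).  The standard fix: shoot the template along the mean
        # momenta and subtract the mean from every subject, which strictly
        # reduces the penalty term while leaving the fits almost unchanged.
        # The move is accepted only if the total loss does not increase.
        p_mean = np.mean(momenta, axis=0)
        if np.linalg.norm(p_mean) > 1e-12:
            traj = _flow_forward(template_v, c0, p_mean, lambda_diffeos, n_steps)
            cand_v = traj[-1][0]
            cand_momenta = [m - p_mean for m in momenta]
            cand_loss = sum(
                _subject_loss_and_grads(
                    cand_v, faces, c0, cand_momenta[s], meshes[s],
                    lambda_diffeos, lambda_surface, reg_weight, att_norm,
                    n_steps, need_grads=False, target_self=tself[s],
                )[0]
                for s in range(len(meshes))
            )
            if cand_loss <= cur:
                template_v, momenta, cur = cand_v, cand_momenta, cand_loss
        loss_trace.append(cur)

        # convergence: relative change < tol over 5 consecutive iterations
        if len(loss_trace) >= 6:
            ref = loss_trace[-6]
            rel = abs(ref - loss_trace[-1]) / max(abs(ref), 1e-30)
            if rel < tol:
                stall += 1
                if stall >= 1:
                    converged = True
                    break
            else:
                stall = 0

    if not converged:
        warnings.warn(
            "estimate_atlas: maximum iterations reached without convergence; "
            "returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    template = TriangleMesh(template_v, faces, label="template")
    subject_momenta = [
        MomentaField(momenta[s], control_points, subject_id=meshes[s].label or f"subject_{s}")
        for s in range(len(meshes))
    ]
    atlas = Atlas(
        template=template,
        control_points=control_points,
        subject_momenta=subject_momenta,
        attachment_width=lambda_surface,
        loss_trace=loss_trace,
        reg_weight=reg_weight,
        n_steps=n_steps,
        converged=converged,
    )
    atlas.residuals = atlas_residual(atlas, meshes)
    return atlas


def atlas_residual(atlas: Atlas, meshes: list[TriangleMesh]) -> dict[str, dict[str, float]]:
    """Point-to-surface misfit of the deformed template, per subject.

    Reports the mean and the max distance from deformed-template vertices
    to the subject surface; the max is what the output labels the "atlas
    error" for a subject.
    """
    by_label = {m.label or f"subject_{i}": m for i, m in enumerate(meshes)}
    out: dict[str, dict[str, float]] = {}
    for mom in atlas.subject_momenta:
        if mom.subject_id not in by_label:
            raise ValueError(f"subject id '{mom.subject_id}' not found among meshes")
        target = by_label[mom.subject_id]
        deformed = shoot_and_flow(atlas.template, atlas.control_points, mom, atlas.n_steps)
        _, d = closest_point_on_surface(deformed.vertices, target)
        out[mom.subject_id] = {"mean_mm": float(d.mean()), "max_mm": float(d.max())}
    return out


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def save_atlas(atlas: Atlas, directory: str | Path) -> None:
    """Write template mesh, control points, momenta and metadata."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_mesh(atlas.template, d / "template.ply")
    np.savetxt(
        d / "control_points.csv", atlas.control_points.points,
        delimiter=",", header="x,y,z", comments="",
    )
    for mom in atlas.subject_momenta:
        np.savetxt(
            d / f"momenta_{mom.subject_id}.csv", mom.momenta,
            delimiter=",", header="px,py,pz", comments="",
        )
    meta = {
        "lambda_diffeos": atlas.control_points.kernel_width,
        "lambda_surface": atlas.attachment_width,
        "reg_weight": atlas.reg_weight,
        "n_steps": atlas.n_steps,
        "converged": atlas.converged,
        "loss_trace": atlas.loss_trace,
        "residuals": atlas.residuals,
        "subject_ids": atlas.subject_ids,
    }
    (d / "atlas.json").write_text(json.dumps(meta, indent=2))


def load_atlas(directory: str | Path) -> Atlas:
    d = Path(directory)
    meta = json.loads((d / "atlas.json").read_text())
    template = read_mesh(d / "template.ply")
    template.label = "template"
    cps = ControlPointSet(
        np.loadtxt(d / "control_points.csv", delimiter=",", skiprows=1),
        meta["lambda_diffeos"],
    )
    momenta = [
        MomentaField(
            np.loadtxt(d / f"momenta_{sid}.csv", delimiter=",", skiprows=1).reshape(-1, 3),
            cps,
            subject_id=sid,
        )
        for sid in meta["subject_ids"]
    ]
    return Atlas(
        template=template,
        control_points=cps,
        subject_momenta=momenta,
        attachment_width=meta["lambda_surface"],
        loss_trace=meta["loss_trace"],
        residuals=meta["residuals"],
        reg_weight=meta["reg_weight"],
        n_steps=meta["n_steps"],
        converged=meta["converged"],
    )
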