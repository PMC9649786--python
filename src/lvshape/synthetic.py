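"""Synthetic cohort generator.

Stands in for the CMR-derived study data so every pipeline stage can be
exercised end-to-end: LV endocardial surfaces, long-axis contours, aortic
arch centerlines and a clinical/strain table with known (planted)
structure.

The LV family is a superellipsoid of revolution,

    r(z) = R (1 - |2 z / L - 1|^e)^(1/e),   z in [0, L],

open at the base pole (a small cap is removed so the surface is open the
way a clipped LV is), with a smooth low-order azimuthal bump field for
surface texture.  Its parameters map onto the interpreted
shape modes through three geometrically independent cohort factors -- an
overall size factor (scales length and radius together), a height/aspect
factor (elongation at fixed volume: length up, radius down), and a waist
factor (rounding at fixed length: equator out, poles in) that carries
the planted group sphericity -- plus the apex exponent e (cone-like at
e ~ 1, ellipsoidal at 2, blunt for large e: the conicity axis).

Strain values are *generated*, not computed from deformation: they follow
a linear model on the planted sphericity with Gaussian noise calibrated
to the target R^2 of each strain component, because feature-tracking
strain is an input to this pipeline, not something it computes.

Arch centerlines are vertically scaled semicircles (exact semicircle at
gothic_height_ratio = 0.5) with an out-of-plane waviness term; only the
three patient groups receive centerlines (healthy controls typically
lack the 3D aortic sequence, so none are generated for them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import TriangleMesh, write_mesh
from .morphometrics import (
    Centerline,
    LVContour,
    write_centerline_csv,
    write_contours_csv,
)

__all__ = [
    "LVShapeParams",
    "CohortSpec",
    "generate_lv_mesh",
    "slice_contours",
    "generate_arch_centerline",
    "generate_cohort",
    "resegment_mesh",
    "DEFAULT_GROUP_PARAMS",
    "DEFAULT_STRAIN_MODELS",
]

GROUPS = ("isolated_CoA", "CoA_BAV", "isolated_BAV", "control")

_CAP_FRACTION = 0.01  # fraction of the long axis removed at the base pole
_WAIST_OFFSET = 0.82  # waist profile b(t) = sin^2(pi t) - offset; the tilt
# keeps the rounding deformation near-orthogonal to uniform scaling under
# the deformation-kernel metric (equator-out motion carries more surface
# area than pole-in motion, so a symmetric profile looks like inflation)

# Group-level generator parameters.  Sphericity means/SDs, group sizes,
# covariate distributions and arch gothicity means follow the clinical
# cohort this generator emulates; the factor SDs (size/height/width) are chosen once to
# give cohort-scale shape variation with distinct per-factor variances.
DEFAULT_GROUP_PARAMS: dict[str, dict] = {
    "isolated_CoA": dict(
        n=25, sphericity_mean=0.62, sphericity_sd=0.08,
        age_mean=37, age_sd=12, bmi_mean=27, bmi_sd=6,
        male_p=0.48, htn_p=0.72,
        ar_probs=(0.88, 0.12, 0.0, 0.0), as_probs=(1.0, 0.0, 0.0, 0.0),
        gothicity_mean=1.19, gothicity_sd=0.17, has_arch=True,
        ef=(65, 8), edv=(76, 19), esv=(27, 8), sv=(51, 16), mass=(62, 26),
        apex_exponent_mean=1.40,
    ),
    "CoA_BAV": dict(
        n=30, sphericity_mean=0.62, sphericity_sd=0.08,
        age_mean=43, age_sd=8, bmi_mean=27, bmi_sd=5,
        male_p=0.53, htn_p=0.37,
        ar_probs=(0.47, 0.43, 0.07, 0.03), as_probs=(0.70, 0.20, 0.07, 0.03),
        gothicity_mean=1.28, gothicity_sd=0.23, has_arch=True,
        ef=(64, 5), edv=(107, 48), esv=(39, 15), sv=(68, 35), mass=(84, 47),
        apex_exponent_mean=1.35,
    ),
    "isolated_BAV": dict(
        n=30, sphericity_mean=0.59, sphericity_sd=0.06,
        age_mean=46, age_sd=14, bmi_mean=26, bmi_sd=5,
        male_p=0.53, htn_p=0.48,
        ar_probs=(0.23, 0.50, 0.17, 0.10), as_probs=(0.50, 0.10, 0.27, 0.13),
        gothicity_mean=1.32, gothicity_sd=0.30, has_arch=True,
        ef=(65, 8), edv=(119, 48), esv=(42, 19), sv=(77, 32), mass=(106, 54),
        apex_exponent_mean=1.35,
    ),
    "control": dict(
        n=25, sphericity_mean=0.57, sphericity_sd=0.06,
        age_mean=45, age_sd=11, bmi_mean=26, bmi_sd=4,
        male_p=0.48, htn_p=0.08,
        ar_probs=(1.0, 0.0, 0.0, 0.0), as_probs=(1.0, 0.0, 0.0, 0.0),
        gothicity_mean=None, gothicity_sd=None, has_arch=False,
        ef=(64, 4), edv=(75, 10), esv=(27, 5), sv=(49, 7), mass=(55, 11),
        apex_exponent_mean=1.20,
    ),
}

# strain ~ a + b * planted_sphericity + N(0, sd); b and sd are calibrated
# so that at the default cohort's realized sphericity SD (0.0705, measured
# over many generated cohorts) the population R^2 of each relation matches
# its clinically reported effect size, and the strain marginals match the
# cohort means/SDs.  Signs encode "rounder LV ->
# reduced strain" (radial strains are positive, longitudinal and
# circumferential negative, so 'reduced magnitude' flips the slope sign).
_SPHERICITY_SD = 0.0705
_SPHERICITY_MEAN = 0.60


def _strain_model(mean: float, total_sd: float, r2: float, sign: float) -> dict:
    b = sign * np.sqrt(r2) * total_sd / _SPHERICITY_SD
    return dict(
        intercept=mean - b * _SPHERICITY_MEAN,
        slope=float(b),
        noise_sd=float(total_sd * np.sqrt(1.0 - r2)),
        target_r2=r2,
    )


DEFAULT_STRAIN_MODELS: dict[str, dict] = {
    "GLS": _strain_model(-17.3, 2.2, 0.04, +1.0),
    "GRS": _strain_model(35.5, 7.1, 0.09, -1.0),
    "GCS": _strain_model(-20.0, 2.3, 0.10, +1.0),
    "apical_radial": _strain_model(44.2, 12.5, 0.17, -1.0),
    "apical_circumferential": _strain_model(-21.6, 6.4, 0.04, +1.0),
}

SEVERITY_LEVELS = ("none", "mild", "moderate", "severe")


@dataclass
class LVShapeParams:
    """Parameters of one synthetic LV surface."""

    length: float  # mm, base-to-apex (full superellipsoid axis)
    equatorial_radius: float  # mm
    apex_exponent: float = 2.0  # >= 1; 2 = ellipsoidal, large = blunt
    waist: float = 0.0  # rounding: equator out / poles in at fixed length
    bump_amplitude: float = 0.5  # mm, smooth azimuthal perturbation
    seed: int = 0
    n_theta: int = 32
    n_z: int = 16

    def __post_init__(self) -> None:
        if self.length <= 0 or self.equatorial_radius <= 0:
            raise ValueError("length and equatorial_radius must be positive")
        if self.apex_exponent < 1:
            raise ValueError("apex_exponent must be >= 1")
        if self.bump_amplitude < 0:
            raise ValueError("bump_amplitude must be non-negative")

    @property
    def true_sphericity(self) -> float:
        gain = 1.0 + (1.0 - _WAIST_OFFSET) * self.waist
        return 2.0 * self.equatorial_radius * gain / self.length


@dataclass
class CohortSpec:
    """Resolved description of a synthetic cohort (the 'stated world')."""

    group_params: dict = field(default_factory=lambda: _deepcopy_dict(DEFAULT_GROUP_PARAMS))
    strain_models: dict = field(default_factory=lambda: _deepcopy_dict(DEFAULT_STRAIN_MODELS))
    base_length: float = 90.0  # mm
    base_sphericity: float = 0.595  # cohort-centre 2R/L before waist/aspect
    size_sd: float = 0.09
    height_sd: float = 0.055
    waist_sd_scale: float = 0.85  # waist sd = scale * group sphericity sd / base
    apex_exponent_sd: float = 0.15
    bump_amplitude: float = 0.5
    arch_waviness: float = 0.05
    arch_span: float = 70.0
    master_seed: int = 0
    mesh_resolution: tuple[int, int] = (32, 16)  # (n_theta, n_z)

    def __post_init__(self) -> None:
        for g in self.group_params:
            if g not in GROUPS:
                raise ValueError(f"unknown group '{g}'")
            if self.group_params[g]["n"] <= 0:
                raise ValueError(f"zero subjects requested in group '{g}'")


def _deepcopy_dict(d: dict) -> dict:
    import copy

    return copy.deepcopy(d)


# ---------------------------------------------------------------------------
# LV surface
# ---------------------------------------------------------------------------

def generate_lv_mesh(params: LVShapeParams) -> TriangleMesh:
    """Superellipsoid of revolution, open at the base pole.

    The apex sits at z = 0 and the open base at z = (1 - cap) * length,
    pointing along +z.  Deterministic in ``params.seed``.
    """
    L, R, e = params.length, params.equatorial_radius, params.apex_exponent
    n_theta, n_z = params.n_theta, params.n_z
    rng = np.random.default_rng(params.seed)

    # low-order azimuthal bump field (zero at the poles)
    coefs = [(k, rng.normal(0, 1.0 / k), rng.normal(0, 1.0 / k)) for k in (2, 3, 4)]

    t_max = 1.0 - _CAP_FRACTION
    ts = np.concatenate([[0.0], np.linspace(1.0 / n_z, t_max, n_z)])
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)

    def radius(t: np.ndarray) -> np.ndarray:
        base = R * np.maximum(1.0 - np.abs(2.0 * t - 1.0) ** e, 0.0) ** (1.0 / e)
        # zero-mean rounding profile: widens the equator, narrows the
        # poles, leaving the average radius (and the length) untouched
        return base * (1.0 + params.waist * (np.sin(np.pi * t) ** 2 - _WAIST_OFFSET))

    verts = [np.array([0.0, 0.0, 0.0])]  # apex pole
    for t in ts[1:]:
        r = radius(np.asarray(t))
        bump = np.zeros_like(thetas)
        for k, a, b in coefs:
            bump += a * np.cos(k * thetas) + b * np.sin(k * thetas)
        rr = r + params.bump_amplitude * bump * np.sin(np.pi * t)
        rr = np.maximum(rr, 0.05 * R)
        for th, radii in zip(thetas, rr):
            verts.append(np.array([radii * np.cos(th), radii * np.sin(th), L * t]))
    V = np.asarray(verts)

    faces = []
    # apex fan
    for j in range(n_theta):
        faces.append([0, 1 + j, 1 + (j + 1) % n_theta])
    # ring strips
    for i in range(n_z - 1):
        base0 = 1 + i * n_theta
        base1 = 1 + (i + 1) * n_theta
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            faces.append([base0 + j, base1 + j, base1 + j2])
            faces.append([base0 + j, base1 + j2, base0 + j2])
    mesh = TriangleMesh(V, np.asarray(faces))
    if mesh.n_faces < 500:
        raise ValueError(
            f"mesh resolution too low ({mesh.n_faces} faces); increase n_theta/n_z"
        )
    return mesh


# ---------------------------------------------------------------------------
# contour extraction (emulated 2ch / 4ch views)
# ---------------------------------------------------------------------------

def _plane_section_path(mesh: TriangleMesh, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Ordered 3D polyline where the plane cuts the surface.

    Works by collecting the intersection segment of every crossing
    triangle and chaining segments through shared edges.  For an open
    mesh the result is an open path whose endpoints lie on the boundary
    rim.
    """
    v = mesh.vertices
    d = (v - origin) @ normal
    # nudge exact-zero vertices so every crossing is a clean edge crossing
    d = np.where(np.abs(d) < 1e-12, 1e-12, d)

    point_of: dict[tuple[int, int], np.ndarray] = {}
    links: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for tri in mesh.faces:
        s = d[tri] > 0
        if s.all() or not s.any():
            continue
        crossing = []
        for k in range(3):
            i, j = tri[k], tri[(k + 1) % 3]
            if (d[i] > 0) != (d[j] > 0):
                key = (i, j) if i < j else (j, i)
                if key not in point_of:
                    t = d[i] / (d[i] - d[j])
                    point_of[key] = v[i] + t * (v[j] - v[i])
                crossing.append(key)
        if len(crossing) != 2:
            continue
        e1, e2 = crossing
        links.setdefault(e1, []).append(e2)
        links.setdefault(e2, []).append(e1)
    if not point_of:
        raise ValueError("section plane misses the mesh")

    # walk the key graph, starting from a boundary key (degree 1) if open
    ends = [k for k, lst in links.items() if len(lst) == 1]
    start = min(ends) if ends else min(links)
    path_keys = [start]
    prev, cur = None, start
    while True:
        nxt = [k for k in links[cur] if k != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        path_keys.append(cur)
    pts = np.asarray([point_of[k] for k in path_keys])
    # drop consecutive duplicates
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    return pts[keep]


def slice_contours(
    mesh: TriangleMesh, long_axis: np.ndarray | None = None
) -> tuple[LVContour, LVContour]:
    """Two long-axis plane sections, 90 degrees apart (emulated 2ch/4ch).

    ``long_axis`` defaults to +z (the generator's orientation).  Each
    section of the open mesh is an open path from rim to rim; its two
    endpoints are used as the mitral landmarks.
    """
    axis = np.array([0.0, 0.0, 1.0]) if long_axis is None else np.asarray(long_axis, float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    origin = mesh.barycentre()

    out = []
    for view, n_vec, in_plane in (("2ch", u, w), ("4ch", w, u)):
        pts3 = _plane_section_path(mesh, origin, n_vec)
        # 2D coordinates in (in_plane, axis)
        p2 = np.column_stack([(pts3 - origin) @ in_plane, (pts3 - origin) @ axis])
        if len(p2) < 20:
            raise ValueError(f"section for view {view} has too few points ({len(p2)})")
        out.append(LVContour(p2, mitral_a=0, mitral_b=len(p2) - 1, view=view))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# aortic arch centerline
# ---------------------------------------------------------------------------

def generate_arch_centerline(
    gothic_height_ratio: float,
    waviness: float = 0.0,
    n_points: int = 200,
    seed: int = 0,
    span: float = 70.0,
) -> Centerline:
    """Vertically scaled semicircular arch with optional out-of-plane waviness.

    At ``gothic_height_ratio = 0.5`` and ``waviness = 0`` the curve is an
    exact semicircle (measured gothicity 0.5, tortuosity 1 - 2/pi).
    Measured gothicity equals the ratio exactly at zero waviness and is
    strictly increasing in it; measured tortuosity is strictly increasing
    in ``waviness``.  Landmarks are the curve endpoints; up_axis is +z.
    """
    if not (0.2 <= gothic_height_ratio <= 2.5):
        raise ValueError("gothic_height_ratio outside documented range [0.2, 2.5]")
    if not (0.0 <= waviness <= 0.4):
        raise ValueError("waviness outside documented range [0, 0.4]")
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    rng = np.random.default_rng(seed)
    theta = np.linspace(np.pi, 0.0, n_points)
    x = 0.5 * span * (1.0 + np.cos(theta))
    z = gothic_height_ratio * span * np.sin(theta)
    t = np.linspace(0.0, 1.0, n_points)
    phase = rng.uniform(0, 2 * np.pi) if waviness > 0 else 0.0
    y = waviness * span * np.sin(4.0 * np.pi * t + phase) * np.sin(np.pi * t)
    y -= np.linspace(y[0], y[-1], n_points)  # pin endpoints to the plane
    pts = np.column_stack([x, y, z])
    return Centerline(pts, idx_stj=0, idx_middesc=n_points - 1, up_axis=np.array([0.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------

def _sample_severity(rng: np.random.Generator, probs: tuple) -> str:
    return SEVERITY_LEVELS[rng.choice(4, p=np.asarray(probs) / np.sum(probs))]


def generate_cohort(
    spec: CohortSpec | None = None, out_dir: str | Path | None = None
) -> dict:
    """Generate a full synthetic cohort.

    Returns a dict with per-subject ``meshes``, ``contours`` (pairs),
    ``centerlines`` (patients only), the ``subjects`` clinical table and
    the ``ground_truth`` table of every planted parameter.  Fully
    deterministic in ``spec.master_seed``; if ``out_dir`` is given, all
    artifacts are also written to disk.
    """
    spec = spec or CohortSpec()
    root = np.random.SeedSequence(spec.master_seed)
    n_total = sum(gp["n"] for gp in spec.group_params.values())
    seeds = root.spawn(n_total + 1)
    n_theta, n_z = spec.mesh_resolution

    meshes: list[TriangleMesh] = []
    contours: dict[str, tuple[LVContour, LVContour]] = {}
    centerlines: dict[str, Centerline] = {}
    subj_rows: list[dict] = []
    truth_rows: list[dict] = []

    i = 0
    for group in GROUPS:
        if group not in spec.group_params:
            continue
        gp = spec.group_params[group]
        for k in range(gp["n"]):
            rng = np.random.default_rng(seeds[i])
            sid = f"{group}_{k:03d}"

            # three geometrically independent factors: uniform size, an
            # aspect (height-at-fixed-volume) elongation, and a waist
            # (rounding) term that carries the planted group sphericity
            size = np.clip(rng.normal(1.0, spec.size_sd), 0.7, 1.3)
            aspect = np.clip(rng.normal(1.0, spec.height_sd), 0.85, 1.18)
            gain = 1.0 - _WAIST_OFFSET  # sphericity leverage of the waist
            waist_mean = (gp["sphericity_mean"] / spec.base_sphericity - 1.0) / gain
            waist_sd = spec.waist_sd_scale * gp["sphericity_sd"] / spec.base_sphericity
            waist = np.clip(rng.normal(waist_mean, waist_sd), -0.45, 0.45)
            L = spec.base_length * size * aspect
            R = 0.5 * spec.base_sphericity * spec.base_length * size / aspect
            s_true = spec.base_sphericity * (1.0 + gain * waist) / aspect**2
            e = np.clip(
                rng.normal(gp["apex_exponent_mean"], spec.apex_exponent_sd), 1.05, 2.5
            )
            mesh_seed = int(rng.integers(0, 2**31 - 1))
            params = LVShapeParams(
                length=L, equatorial_radius=R, apex_exponent=e, waist=float(waist),
                bump_amplitude=spec.bump_amplitude, seed=mesh_seed,
                n_theta=n_theta, n_z=n_z,
            )
            mesh = generate_lv_mesh(params)
            mesh.label = sid
            meshes.append(mesh)
            contours[sid] = slice_contours(mesh)

            if gp["has_arch"]:
                g_ratio = np.clip(
                    rng.normal(gp["gothicity_mean"], gp["gothicity_sd"]), 0.3, 2.4
                )
                wav = np.clip(rng.normal(spec.arch_waviness, 0.02), 0.0, 0.3)
                centerlines[sid] = generate_arch_centerline(
                    float(g_ratio), float(wav), seed=int(rng.integers(0, 2**31 - 1)),
                    span=spec.arch_span,
                )
            else:
                g_ratio, wav = np.nan, np.nan

            age = float(np.clip(rng.normal(gp["age_mean"], gp["age_sd"]), 18, 80))
            bmi = float(np.clip(rng.normal(gp["bmi_mean"], gp["bmi_sd"]), 16, 45))
            sex = "M" if rng.random() < gp["male_p"] else "F"
            htn = bool(rng.random() < gp["htn_p"])
            ar = _sample_severity(rng, gp["ar_probs"])
            as_ = _sample_severity(rng, gp["as_probs"])

            row = {
                "subject_id": sid, "group": group, "age": age, "sex": sex,
                "bmi": bmi, "hypertension": int(htn),
                "ar_severity": ar, "as_severity": as_,
                "EF": float(rng.normal(*gp["ef"])),
                "EDV": float(max(rng.normal(*gp["edv"]), 30)),
                "ESV": float(max(rng.normal(*gp["esv"]), 10)),
                "SV": float(max(rng.normal(*gp["sv"]), 15)),
                "LV_mass": float(max(rng.normal(*gp["mass"]), 25)),
            }
            truth = {
                "subject_id": sid, "group": group,
                "size_factor": float(size), "height_factor": float(aspect),
                "sphericity_factor": float(1.0 + (1.0 - _WAIST_OFFSET) * waist),
                "true_sphericity": float(s_true), "apex_exponent": float(e),
                "length_mm": float(L), "equatorial_radius_mm": float(R),
                "gothic_height_ratio": float(g_ratio), "waviness": float(wav),
            }
            for name, sm in spec.strain_models.items():
                eps = rng.normal(0.0, sm["noise_sd"])
                row[name] = float(sm["intercept"] + sm["slope"] * s_true + eps)
                truth[f"{name}_residual"] = float(eps)
            subj_rows.append(row)
            truth_rows.append(truth)
            i += 1

    subjects = pd.DataFrame(subj_rows)
    ground_truth = pd.DataFrame(truth_rows)
    result = {
        "meshes": meshes,
        "contours": contours,
        "centerlines": centerlines,
        "subjects": subjects,
        "ground_truth": ground_truth,
        "spec": spec,
    }
    if out_dir is not None:
        _write_cohort(result, Path(out_dir))
    return result


def _write_cohort(cohort: dict, out: Path) -> None:
    import yaml

    (out / "meshes").mkdir(parents=True, exist_ok=True)
    (out / "contours").mkdir(exist_ok=True)
    (out / "centerlines").mkdir(exist_ok=True)
    for mesh in cohort["meshes"]:
        write_mesh(mesh, out / "meshes" / f"{mesh.label}.stl")
    for sid, pair in cohort["contours"].items():
        write_contours_csv(list(pair), out / "contours" / f"{sid}.csv")
    for sid, cl in cohort["centerlines"].items():
        write_centerline_csv(cl, out / "centerlines" / f"{sid}.csv")
    cohort["subjects"].to_csv(out / "subjects.csv", index=False)
    cohort["ground_truth"].to_csv(out / "ground_truth.csv", index=False)
    spec = cohort["spec"]

    def plain(obj):
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    (out / "spec.yaml").write_text(yaml.safe_dump(plain(asdict(spec)), sort_keys=False))


# ---------------------------------------------------------------------------
# re-segmentation emulation
# ---------------------------------------------------------------------------

def resegment_mesh(mesh: TriangleMesh, amplitude: float = 1.1, seed: int = 0,
                   offset_sd: float = 0.72) -> TriangleMesh:
    """Emulate an independent re-segmentation of the same anatomy.

    Displaces vertices along their normals by a random systematic offset
    (``offset_sd`` mm -- a second reader's consistent over/under-contouring,
    which is what actually moves the surface area) plus a smooth
    zero-mean low-frequency field of the given ``amplitude`` for local
    disagreement.  Defaults are calibrated so the median surface-area
    difference across a panel is a few percent (~4%).
    """
    rng = np.random.default_rng(seed)
    offset = rng.normal(0.0, offset_sd)
    v = mesh.vertices
    lo, hi = v.min(axis=0), v.max(axis=0)
    scale = np.maximum(hi - lo, 1e-9)
    t = (v - lo) / scale
    fieldv = np.zeros(len(v))
    for _ in range(3):
        k = rng.uniform(0.5, 1.5, size=3)
        ph = rng.uniform(0, 2 * np.pi, size=3)
        fieldv += rng.normal(0, 1.0) * np.cos(
            2 * np.pi * (t @ k) + ph.sum()
        )
    fieldv /= max(np.abs(fieldv).max(), 1e-9)
    from .remesh import _vertex_normals

    normals = _vertex_normals(mesh)
    disp = (offset + amplitude * fieldv)[:, None] * normals
    return TriangleMesh(v + disp, mesh.faces.copy(), mesh.label)
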