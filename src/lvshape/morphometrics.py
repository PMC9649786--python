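"""CMR-style morphometric indices.

Left-ventricular indices are measured on 2D long-axis contours the way
they are measured on cine views:

* **sphericity**  = short axis / long axis (B/A)
* **conicity**    = apical axis / short axis (E/B), the apical axis being
  the diameter of the best-fitting circle to the apical part of the
  contour

with the long axis running from the mitral-valve midpoint (C) to the
apex, the short axis being the perpendicular chord at the long-axis
midpoint, and the apical circle fit over contour points in the apical
third of the long axis.  Values from the two long-axis views (2ch/4ch)
are averaged.

Aortic-arch indices are measured on a 3D lumen centerline between the
sinotubular junction (STJ) and the mid-descending aorta:

* **gothicity**  = arch height / arch width (H/W)
* **tortuosity** = 1 - W/l

where W is the distance between the two landmark points, H the maximal
elevation (along the vertical axis) of the centerline above the W
segment, and l the centerline arc length between the landmarks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "LVContour",
    "LVAxes",
    "Centerline",
    "ArchIndices",
    "lv_axes",
    "sphericity",
    "conicity",
    "average_views",
    "arch_geometry",
    "fit_circle_2d",
    "read_contours_csv",
    "write_contours_csv",
    "read_centerline_csv",
    "write_centerline_csv",
]

APICAL_FRACTION = 1.0 / 3.0  # portion of the long axis used for the apex fit


@dataclass
class LVContour:
    """Closed 2D endocardial contour in a long-axis view (mm)."""

    points: np.ndarray  # (n, 2), ordered, closed implicitly
    mitral_a: int
    mitral_b: int
    view: str = "2ch"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        n = len(self.points)
        if n < 20:
            raise ValueError(f"contour needs >= 20 points, got {n}")
        if not (0 <= self.mitral_a < n and 0 <= self.mitral_b < n):
            raise ValueError("mitral landmark index out of range")
        if self.mitral_a == self.mitral_b:
            raise ValueError("mitral landmarks must be distinct")
        if not _polygon_is_simple(self.points):
            raise ValueError("contour polyline is self-intersecting")


@dataclass
class LVAxes:
    """The long-axis measurement set (symbols A, B, C, D, E)."""

    long_axis_A: float
    short_axis_B: float
    mitral_mid_C: np.ndarray
    apex_sphere_D: tuple[np.ndarray, float]  # (center, diameter)
    apical_axis_E: float

    def __post_init__(self) -> None:
        for name in ("long_axis_A", "short_axis_B", "apical_axis_E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Centerline:
    """Ordered 3D aortic centerline with STJ / mid-descending landmarks."""

    points: np.ndarray  # (n, 3)
    idx_stj: int
    idx_middesc: int
    up_axis: np.ndarray = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.up_axis is None:
            self.up_axis = np.array([0.0, 0.0, 1.0])
        self.up_axis = np.asarray(self.up_axis, dtype=np.float64).reshape(3)
        self.up_axis = self.up_axis / np.linalg.norm(self.up_axis)
        if not self.idx_stj < self.idx_middesc:
            raise ValueError("idx_stj must precede idx_middesc")
        if self.idx_middesc - self.idx_stj < 10:
            raise ValueError("need >= 10 centerline points between the landmarks")
        seg = np.diff(self.points[self.idx_stj : self.idx_middesc + 1], axis=0)
        if (np.linalg.norm(seg, axis=1) == 0).any():
            raise ValueError("consecutive centerline points must be distinct")


@dataclass
class ArchIndices:
    width_W: float
    height_H: float
    arch_length_l: float
    gothicity: float
    tortuosity: float


def _polygon_is_simple(points: np.ndarray) -> bool:
    from shapely.geometry import LinearRing

    try:
        return LinearRing(points).is_valid
    except Exception:
        return False


# ---------------------------------------------------------------------------
# LV indices
# ---------------------------------------------------------------------------

def fit_circle_2d(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares circle: algebraic (Kasa) fit refined by Gauss-Newton.

    Returns (center, radius) minimising the summed squared radial error.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("circle fit needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(pts))])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r = np.sqrt(max(sol[2] + cx**2 + cy**2, 1e-30))

    def resid(q):
        return np.hypot(x - q[0], y - q[1]) - q[2]

    out = least_squares(resid, x0=[cx, cy, r], method="lm")
    cx, cy, r = out.x
    return np.array([cx, cy]), float(abs(r))


def lv_axes(contour: LVContour, apical_fraction: float = APICAL_FRACTION) -> LVAxes:
    """Measure A, B, C, D, E on a long-axis contour.

    C is the midpoint of the mitral landmarks; the apex is the contour
    point farthest from C (ties broken by smallest index); B is the chord
    through the long-axis midpoint perpendicular to the C-apex direction;
    the apical circle is fit to contour points whose projection on the
    long axis falls in the apical ``apical_fraction``.
    """
    pts = contour.points
    C = 0.5 * (pts[contour.mitral_a] + pts[contour.mitral_b])
    d = np.linalg.norm(pts - C, axis=1)
    apex_idx = int(np.argmax(d))  # argmax returns the first (smallest index) tie
    apex = pts[apex_idx]
    A = float(d[apex_idx])
    u = (apex - C) / A
    mid = C + 0.5 * A * u

    B = _perpendicular_chord_length(pts, mid, u)
    if B is None:
        raise ValueError("invalid short-axis plane: perpendicular chord misses the contour")

    t = (pts - C) @ u
    apical = pts[t >= A * (1.0 - apical_fraction)]
    if len(apical) < 5:
        raise ValueError("apical third of the contour has fewer than 5 points")
    center, radius = fit_circle_2d(apical)
    return LVAxes(
        long_axis_A=A,
        short_axis_B=float(B),
        mitral_mid_C=C,
        apex_sphere_D=(center, 2.0 * radius),
        apical_axis_E=2.0 * radius,
    )


def _perpendicular_chord_length(pts: np.ndarray, mid: np.ndarray, u: np.ndarray):
    """Length of the contour chord through ``mid`` perpendicular to ``u``."""
    v = np.array([-u[1], u[0]])  # perpendicular direction
    # signed distance of each contour point to the chord line
    s = (pts - mid) @ u
    ts = []
    n = len(pts)
    for i in range(n):
        j = (i + 1) % n
        si, sj = s[i], s[j]
        if si == sj:
            continue
        if (si > 0) != (sj > 0) or si == 0.0:
            w = si / (si - sj)
            q = pts[i] + w * (pts[j] - pts[i])
            ts.append((q - mid) @ v)
    if len(ts) < 2:
        return None
    return max(ts) - min(ts)


def sphericity(axes: LVAxes) -> float:
    """Short-to-long axis ratio B/A (1.0 for a circle)."""
    return axes.short_axis_B / axes.long_axis_A * 1.0 if axes.long_axis_A > 0 else np.nan


def conicity(axes: LVAxes) -> float:
    """Apical-to-short axis ratio E/B (1.0 for a circle)."""
    if axes.short_axis_B <= 0:
        raise ValueError("short axis must be positive")
    return axes.apical_axis_E / axes.short_axis_B


def average_views(value_2ch: float | None, value_4ch: float | None) -> tuple[float, bool]:
    """Mean of the two view measurements.

    Returns ``(value, single_view)``; if one view is missing the other is
    returned with ``single_view=True``.
    """
    have2 = value_2ch is not None and np.isfinite(value_2ch)
    have4 = value_4ch is not None and np.isfinite(value_4ch)
    if have2 and have4:
        return 0.5 * (value_2ch + value_4ch), False
    if have2:
        return float(value_2ch), True
    if have4:
        return float(value_4ch), True
    raise ValueError("both views missing")


# ---------------------------------------------------------------------------
# arch indices
# ---------------------------------------------------------------------------

def arch_geometry(cl: Centerline) -> ArchIndices:
    """Width, height, arc length, gothicity and tortuosity of the arch."""
    p = cl.points
    p_stj = p[cl.idx_stj]
    p_mid = p[cl.idx_middesc]
    W = float(np.linalg.norm(p_mid - p_stj))
    if W <= 0:
        raise ValueError("landmark points coincide")

    arch = p[cl.idx_stj : cl.idx_middesc + 1]
    l = float(np.linalg.norm(np.diff(arch, axis=0), axis=1).sum())
    if l < W * (1 - 1e-9):
        raise ValueError("internal consistency error: arc length shorter than width")

    # elevation of each arch point above the W segment, along up_axis
    d_hat = (p_mid - p_stj) / W
    t = (arch - p_stj) @ d_hat
    base = p_stj[None, :] + t[:, None] * d_hat[None, :]
    h = (arch - base) @ cl.up_axis
    H = float(max(h.max(), 0.0))

    tort = 1.0 - W / l
    return ArchIndices(
        width_W=W,
        height_H=H,
        arch_length_l=l,
        gothicity=H / W,
        tortuosity=tort,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_contours_csv(contours: list[LVContour], path: str | Path) -> None:
    """Columns: view,row_type,point_index,x_mm,y_mm.

    ``row_type`` is "contour" for border points and "mitral" for the two
    landmark rows (whose point_index references a contour row).
    """
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.points):
            rows.append((c.view, "contour", i, x, y))
        for idx in (c.mitral_a, c.mitral_b):
            rows.append((c.view, "mitral", idx, c.points[idx, 0], c.points[idx, 1]))
    pd.DataFrame(rows, columns=["view", "row_type", "point_index", "x_mm", "y_mm"]).to_csv(
        path, index=False
    )


def read_contours_csv(path: str | Path) -> list[LVContour]:
    df = pd.read_csv(path)
    out = []
    for view, sub in df.groupby("view", sort=True):
        pts = (
            sub[sub.row_type == "contour"]
            .sort_values("point_index")[["x_mm", "y_mm"]]
            .to_numpy()
        )
        mitral = sub[sub.row_type == "mitral"].point_index.astype(int).tolist()
        if len(mitral) != 2:
            raise ValueError(f"view '{view}' must carry exactly 2 mitral landmarks")
        out.append(LVContour(pts, mitral[0], mitral[1], view=str(view)))
    return out


def write_centerline_csv(cl: Centerline, path: str | Path) -> None:
    """Points to CSV; landmarks and up_axis to a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(cl.points, columns=["x_mm", "y_mm", "z_mm"])
    df.insert(0, "point_index", np.arange(len(cl.points)))
    df.to_csv(path, index=False)
    sidecar = {
        "idx_stj": int(cl.idx_stj),
        "idx_middesc": int(cl.idx_middesc),
        "up_axis": [float(v) for v in cl.up_axis],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_centerline_csv(path: str | Path) -> Centerline:
    path = Path(path)
    df = pd.read_csv(path).sort_values("point_index")
    meta = json.loads(path.with_suffix(".json").read_text())
    return Centerline(
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        idx_stj=meta["idx_stj"],
        idx_middesc=meta["idx_middesc"],
        up_axis=np.asarray(meta["up_axis"]),
    )


def subject_morphometrics(
    contours: list[LVContour] | None,
    centerline: Centerline | None,
    subject_id: str = "",
) -> dict:
    """Per-subject morphometrics row (sphericity/conicity averaged over views)."""
    row: dict = {"subject_id": subject_id}
    if contours:
        sph, con, As, Bs, Es = [], [], [], [], []
        for c in contours:
            ax = lv_axes(c)
            sph.append(sphericity(ax))
            con.append(conicity(ax))
            As.append(ax.long_axis_A)
            Bs.append(ax.short_axis_B)
            Es.append(ax.apical_axis_E)
        row["sphericity"] = float(np.mean(sph))
        row["conicity"] = float(np.mean(con))
        row["A"], row["B"], row["E"] = map(lambda v: float(np.mean(v)), (As, Bs, Es))
        row["single_view"] = len(contours) == 1
    if centerline is not None:
        arch = arch_geometry(centerline)
        row.update(
            gothicity=arch.gothicity,
            tortuosity=arch.tortuosity,
            W=arch.width_W,
            H=arch.height_H,
            l=arch.arch_length_l,
        )
    return row
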