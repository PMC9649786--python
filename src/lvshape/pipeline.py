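"""End-to-end pipeline: preprocess -> atlas -> modes -> morphometrics -> stats.

A run consumes a cohort directory (as written by the synthetic generator,
or assembled from real exports with the same layout):

    meshes/*.stl|ply|obj      one LV surface per subject
    contours/<id>.csv         two long-axis contours per subject
    centerlines/<id>.csv+json aortic centerlines (optional per subject)
    subjects.csv              clinical/strain table

and writes every intermediate artifact plus a manifest (config, seed,
per-file checksums) into the run directory, so re-running with the same
config and seed reproduces every numeric output exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import modes as modes_mod
from . import morphometrics as morpho_mod
from . import stats as stats_mod
from .mesh import read_mesh, align_barycentre, surface_area
from .remesh import remesh_isotropic

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the CLI exit path."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    input_dir: str | None = None
    output_dir: str = "lvshape_run"
    lambda_diffeos: float = 35.0  # mm, deformation kernel width
    lambda_surface: float = 11.0  # mm, varifold kernel width
    remesh_target: float = 4.0  # mm
    do_remesh: bool = False
    sd_multiple: float = 2.7
    mode_rule: str = "cumulative54"  # or "fixed:<k>"
    metric: str = "kernel"
    alpha: float = 0.05
    seed: int = 0
    reg_weight: float = 1e-2
    max_iter: int = 50
    atlas_tol: float = 1e-5
    n_steps: int = 10
    reseg_fraction: float = 0.2
    reseg_amplitude: float = 1.1
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("lambda_diffeos", "lambda_surface", "remesh_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.mode_rule != "cumulative54" and not self.mode_rule.startswith("fixed:"):
            raise ValueError("mode_rule must be 'cumulative54' or 'fixed:<k>'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(input_dir: str | Path) -> dict:
    """Check readability and cross-referencing of a cohort directory.

    Returns ``{"errors": [...], "warnings": [...], "n_subjects": int}``;
    never raises for data problems (this is a reporting operation).
    """
    root = Path(input_dir)
    errors: list[str] = []
    warnings: list[str] = []
    mesh_ids: set[str] = set()

    mesh_dir = root / "meshes"
    if not mesh_dir.is_dir():
        errors.append("missing meshes/ directory")
    else:
        for p in sorted(mesh_dir.iterdir()):
            if p.suffix.lower() not in (".stl", ".ply", ".obj"):
                continue
            try:
                read_mesh(p)
                mesh_ids.add(p.stem)
            except Exception as e:
                errors.append(f"unreadable mesh {p.name}: {e}")

    table = root / "subjects.csv"
    table_ids: set[str] = set()
    if not table.exists():
        errors.append("missing subjects.csv")
    else:
        df = pd.read_csv(table)
        required = {"subject_id", "group"}
        missing = required - set(df.columns)
        if missing:
            errors.append(f"subjects.csv missing columns: {sorted(missing)}")
        else:
            table_ids = set(df.subject_id.astype(str))
    for sid in sorted(mesh_ids - table_ids):
        errors.append(f"subject '{sid}' has a mesh but no subjects.csv row")
    for sid in sorted(table_ids - mesh_ids):
        warnings.append(f"subject '{sid}' in subjects.csv has no mesh")

    for sid in sorted(table_ids):
        if not (root / "contours" / f"{sid}.csv").exists():
            warnings.append(f"subject '{sid}' has no contours (LV indices skipped)")
        cl = root / "centerlines" / f"{sid}.csv"
        if cl.exists() and not cl.with_suffix(".json").exists():
            errors.append(f"centerline for '{sid}' lacks its JSON landmark sidecar")
        elif not cl.exists():
            warnings.append(f"subject '{sid}' has no centerline (arch models skip it)")
    return {"errors": errors, "warnings": warnings, "n_subjects": len(table_ids)}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "warnings": []}

    if config.input_dir is None:
        raise PipelineError("inputs", "no input_dir configured (run 'simulate' first)")
    root = Path(config.input_dir)
    report = validate_inputs(root)
    if report["errors"]:
        raise PipelineError("validate", "; ".join(report["errors"]))
    manifest["warnings"] += report["warnings"]

    # ---- load + preprocess ----
    try:
        subjects = pd.read_csv(root / "subjects.csv")
        meshes = []
        for sid in subjects.subject_id.astype(str):
            for suf in (".stl", ".ply", ".obj"):
                p = root / "meshes" / f"{sid}{suf}"
                if p.exists():
                    meshes.append(read_mesh(p))
                    break
        if config.do_remesh:
            meshes = [remesh_isotropic(m, config.remesh_target) for m in meshes]
        meshes = align_barycentre(meshes)
        manifest["stages"]["preprocess"] = {
            "n_meshes": len(meshes),
            "remeshed": config.do_remesh,
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("preprocess", str(e)) from e

    # ---- atlas ----
    try:
        atl = atlas_mod.estimate_atlas(
            meshes,
            lambda_diffeos=config.lambda_diffeos,
            lambda_surface=config.lambda_surface,
            reg_weight=config.reg_weight,
            max_iter=config.max_iter,
            tol=config.atlas_tol,
            seed=config.seed,
            n_steps=config.n_steps,
        )
        atlas_mod.save_atlas(atl, out / "atlas")
        manifest["stages"]["atlas"] = {
            "final_loss": atl.loss_trace[-1],
            "converged": atl.converged,
            "max_residual_mm": max(r["max_mm"] for r in atl.residuals.values()),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("atlas", str(e)) from e

    # ---- modes ----
    try:
        basis = modes_mod.compute_modes(atl, metric=config.metric)
        if config.mode_rule.startswith("fixed:"):
            basis.n_retained = min(int(config.mode_rule.split(":")[1]), basis.n_modes)
        scores = modes_mod.subject_scores(atl, basis)
        modes_mod.save_modes(atl, basis, scores, out / "modes", config.sd_multiple)
        manifest["stages"]["modes"] = {
            "n_retained": basis.n_retained,
            "cumulative_pct_retained": float(basis.cumulative_pct[basis.n_retained - 1]),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("modes", str(e)) from e

    # ---- morphometrics ----
    try:
        rows = []
        for sid in subjects.subject_id.astype(str):
            cpath = root / "contours" / f"{sid}.csv"
            contours = morpho_mod.read_contours_csv(cpath) if cpath.exists() else None
            clpath = root / "centerlines" / f"{sid}.csv"
            cl = morpho_mod.read_centerline_csv(clpath) if clpath.exists() else None
            rows.append(morpho_mod.subject_morphometrics(contours, cl, sid))
        morpho = pd.DataFrame(rows)
        morpho.to_csv(out / "morphometrics.csv", index=False)
        manifest["stages"]["morphometrics"] = {"n_rows": len(morpho)}
    except Exception as e:  # noqa: BLE001
        raise PipelineError("morphometrics", str(e)) from e

    # ---- association statistics ----
    try:
        merged = subjects.copy()
        merged["subject_id"] = merged.subject_id.astype(str)
        merged = merged.merge(morpho, on="subject_id", how="left")
        score_df = scores.to_frame().iloc[:, : basis.n_retained + 1]
        suite = stats_mod.run_association_suite(merged, score_df, alpha=config.alpha)
        suite["results"].to_csv(out / "results.csv", index=False)
        suite["grouptests"].to_csv(out / "grouptests.csv", index=False)
        manifest["warnings"] += suite["warnings"]
        manifest["stages"]["stats"] = {
            "n_models": len(suite["results"]),
            "n_grouptests": len(suite["grouptests"]),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stats", str(e)) from e

    # ---- reproducibility panel (synthetic re-segmentation) ----
    if config.reseg_fraction > 0:
        try:
            from .synthetic import resegment_mesh

            rng = np.random.default_rng(config.seed + 1)
            n_panel = max(int(round(config.reseg_fraction * len(meshes))), 5)
            n_panel = min(n_panel, len(meshes))
            idx = rng.choice(len(meshes), size=n_panel, replace=False)
            a1, a2 = [], []
            for i in idx:
                a1.append(surface_area(meshes[i]))
                a2.append(
                    surface_area(
                        resegment_mesh(
                            meshes[i], config.reseg_amplitude,
                            seed=int(rng.integers(0, 2**31 - 1)),
                        )
                    )
                )
            rep = stats_mod.icc_reproducibility(a1, a2)
            (out / "reproducibility.json").write_text(
                json.dumps(
                    {
                        "n_panel": n_panel,
                        "median_pct_diff": rep.median_pct_diff,
                        "pct_diff_range": rep.pct_diff_range,
                        "icc": rep.icc,
                        "bias": rep.bias,
                        "loa": [rep.loa_low, rep.loa_high],
                    },
                    indent=2,
                )
            )
            manifest["stages"]["reproducibility"] = {"icc": rep.icc}
        except Exception as e:  # noqa: BLE001
            raise PipelineError("reproducibility", str(e)) from e

    checks = {}
    for p in sorted(out.rglob("*.csv")) + sorted(out.rglob("*.json")):
        if p.name == "manifest.json":
            continue
        checks[str(p.relative_to(out))] = _sha256(p)
    manifest["checksums"] = checks
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
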