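"""Shape-function association statistics and reproducibility metrics.

Group comparisons follow the usual normality-gated switch: Shapiro-Wilk
per group, one-way ANOVA if every group passes, otherwise Kruskal-Wallis
with Dunn's post hoc (Holm-adjusted).  Regressions are ordinary least
squares via statsmodels; aortic-valve disease severity enters the models
binarised (none or mild = 0, moderate or severe = 1).  Test-retest
reproducibility is summarised by the median percentage difference, the
two-way random-effects absolute-agreement single-measure ICC, and
Bland-Altman bias with 95% limits of agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "SubjectRecord",
    "RegressionResult",
    "GroupTestResult",
    "ReproducibilityResult",
    "binarize_severity",
    "group_compare",
    "simple_regression",
    "multiple_regression",
    "icc_reproducibility",
    "run_association_suite",
]

GROUPS = ("isolated_CoA", "CoA_BAV", "isolated_BAV", "control")
SEVERITY_LEVELS = ("none", "mild", "moderate", "severe")

STRAIN_COLUMNS = ("GLS", "GRS", "GCS", "apical_radial", "apical_circumferential")
VOLUME_COLUMNS = ("EF", "EDV", "ESV", "SV", "LV_mass")


@dataclass
class SubjectRecord:
    """One subject's covariates, strain values and shape measures."""

    subject_id: str
    group: str
    age: float = np.nan
    sex: str = ""
    bmi: float = np.nan
    hypertension: bool = False
    ar_severity: str = "none"
    as_severity: str = "none"
    strains: dict = field(default_factory=dict)
    volumes: dict = field(default_factory=dict)
    morphometrics: dict = field(default_factory=dict)
    mode_scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group '{self.group}'")
        for sev in (self.ar_severity, self.as_severity):
            if sev not in SEVERITY_LEVELS:
                raise ValueError(f"unknown severity '{sev}'")

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
            "bmi": self.bmi,
            "hypertension": int(self.hypertension),
            "ar_severity": self.ar_severity,
            "as_severity": self.as_severity,
        }
        row.update(self.strains)
        row.update(self.volumes)
        row.update(self.morphometrics)
        row.update(self.mode_scores)
        return row


@dataclass
class RegressionResult:
    terms: pd.DataFrame  # term, estimate, se, p
    r_squared: float
    n: int
    formula: str

    def p_of(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "p"])

    def coef_of(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "estimate"])


@dataclass
class GroupTestResult:
    test_name: str  # "ANOVA" or "Kruskal-Wallis"
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None  # pairwise Dunn p-values (KW only)
    alpha: float = 0.05


@dataclass
class ReproducibilityResult:
    median_pct_diff: float
    pct_diff_range: tuple[float, float]
    icc: float
    bias: float
    loa_low: float
    loa_high: float


def binarize_severity(values) -> np.ndarray:
    """none or mild -> 0; moderate or severe -> 1."""
    arr = np.asarray(values, dtype=object)
    out = np.empty(len(arr), dtype=float)
    for i, v in enumerate(arr):
        if v in ("none", "mild"):
            out[i] = 0.0
        elif v in ("moderate", "severe"):
            out[i] = 1.0
        else:
            raise ValueError(f"unknown severity level '{v}'")
    return out


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def _dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests with tie correction, Holm-adjusted."""
    labels = list(pd.unique(groups))
    N = len(values)
    ranks = sps.rankdata(values)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi, gj = labels[i], labels[j]
            ri = ranks[groups == gi]
            rj = ranks[groups == gj]
            se = np.sqrt(var_base * (1.0 / len(ri) + 1.0 / len(rj)))
            z = (ri.mean() - rj.mean()) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_1": gi, "group_2": gj, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    # Holm step-down adjustment
    order = np.argsort(df.p_raw.to_numpy())
    m = len(df)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * df.p_raw.iloc[idx])
        adj[idx] = min(running, 1.0)
    df["p_adj"] = adj
    return df


def group_compare(values, groups, alpha: float = 0.05) -> GroupTestResult:
    """ANOVA or Kruskal-Wallis depending on per-group normality.

    Shapiro-Wilk is run in each group at the same alpha; if all groups
    look normal, one-way ANOVA is used, otherwise Kruskal-Wallis with a
    Holm-adjusted Dunn post hoc.  Constant data in every group yields
    p = 1 by convention (no evidence of a difference).
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = []
    for g in labels:
        v = values[groups == g]
        if len(v) < 3:
            raise ValueError(f"group '{g}' has fewer than 3 values")
        samples.append(v)
    if all(np.ptp(v) == 0 for v in samples) and len(set(v[0] for v in samples)) == 1:
        return GroupTestResult("ANOVA", 0.0, 1.0, None, alpha)

    normal = True
    for v in samples:
        if np.ptp(v) == 0:
            normal = False
            break
        if sps.shapiro(v).pvalue < alpha:
            normal = False
            break
    if normal:
        stat, p = sps.f_oneway(*samples)
        return GroupTestResult("ANOVA", float(stat), float(p), None, alpha)
    stat, p = sps.kruskal(*samples)
    posthoc = _dunn_posthoc(values, groups)
    return GroupTestResult("Kruskal-Wallis", float(stat), float(p), posthoc, alpha)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def simple_regression(x, y, x_name: str = "x", y_name: str = "y") -> RegressionResult:
    """OLS of y on x (complete pairs only); R^2 equals squared Pearson r."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    terms = pd.DataFrame(
        {
            "term": ["intercept", x_name],
            "estimate": fit.params,
            "se": fit.bse,
            "p": fit.pvalues,
        }
    )
    return RegressionResult(terms, float(fit.rsquared), int(len(x)), f"{y_name} ~ {x_name}")


def multiple_regression(y, covariates: pd.DataFrame, y_name: str = "y") -> RegressionResult:
    """OLS of y on the named covariate columns (complete cases).

    Severity columns should be pre-binarised; sex/hypertension enter as
    0/1 indicators.  A rank-deficient design raises an error naming the
    collinear columns.
    """
    cov = covariates.copy()
    for col in cov.columns:
        if cov[col].dtype == object or cov[col].dtype == bool:
            cov[col] = _encode_binary(cov[col], col)
    y = np.asarray(y, dtype=np.float64)
    mask = np.isfinite(y) & np.isfinite(cov.to_numpy(dtype=np.float64)).all(axis=1)
    cov = cov.loc[mask]
    y = y[mask]
    if len(y) < len(cov.columns) + 3:
        raise ValueError(
            f"too few complete cases ({len(y)}) for {len(cov.columns)} covariates"
        )
    X = cov.to_numpy(dtype=np.float64)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        collinear = _find_collinear(cov)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(y, Xc).fit()
    names = ["intercept"] + list(cov.columns)
    terms = pd.DataFrame(
        {"term": names, "estimate": fit.params, "se": fit.bse, "p": fit.pvalues}
    )
    formula = f"{y_name} ~ " + " + ".join(cov.columns)
    return RegressionResult(terms, float(fit.rsquared), int(len(y)), formula)


def _encode_binary(col: pd.Series, name: str) -> pd.Series:
    vals = col.dropna().unique()
    mapping = {}
    for v in vals:
        if v in (True, 1, "1", "M", "male", "yes", "moderate", "severe"):
            mapping[v] = 1.0
        elif v in (False, 0, "0", "F", "female", "no", "none", "mild"):
            mapping[v] = 0.0
        else:
            raise ValueError(f"cannot encode value '{v}' in column '{name}' as 0/1")
    return col.map(mapping).astype(float)


def _find_collinear(cov: pd.DataFrame) -> list[str]:
    X = cov.to_numpy(dtype=np.float64)
    bad = []
    for i, name in enumerate(cov.columns):
        rest = np.delete(X, i, axis=1)
        full = np.linalg.matrix_rank(sm.add_constant(X, has_constant="add"))
        without = np.linalg.matrix_rank(sm.add_constant(rest, has_constant="add"))
        if full == without:
            bad.append(name)
    return bad


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------

def icc_reproducibility(measure_1, measure_2) -> ReproducibilityResult:
    """Test-retest agreement between two measurement passes.

    ICC(A,1): two-way random effects, absolute agreement, single
    measurement (via pingouin).  Bland-Altman bias is mean(m1 - m2) with
    limits bias +/- 1.96 SD of the differences; the percentage difference
    is 100 |m1 - m2| / mean(m1, m2) per case.
    """
    m1 = np.asarray(measure_1, dtype=np.float64)
    m2 = np.asarray(measure_2, dtype=np.float64)
    if m1.shape != m2.shape:
        raise ValueError("paired measurements must have equal length")
    ok = np.isfinite(m1) & np.isfinite(m2)
    m1, m2 = m1[ok], m2[ok]
    n = len(m1)
    if n < 5:
        raise ValueError("need at least 5 paired cases")
    if np.ptp(np.concatenate([m1, m2])) == 0 or (np.ptp(m1) == 0 and np.ptp(m2) == 0):
        raise ValueError("zero between-case variance")

    if np.array_equal(m1, m2):
        icc = 1.0
    else:
        import pingouin as pg

        df = pd.DataFrame(
            {
                "case": np.tile(np.arange(n), 2),
                "rater": np.repeat(["m1", "m2"], n),
                "value": np.concatenate([m1, m2]),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = pg.intraclass_corr(
                data=df, targets="case", raters="rater", ratings="value"
            )
        icc = float(table.set_index("Type").loc["ICC(A,1)", "ICC"])

    diff = m1 - m2
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    denom = 0.5 * (m1 + m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * np.abs(diff) / np.abs(denom)
    pct = pct[np.isfinite(pct)]
    return ReproducibilityResult(
        median_pct_diff=float(np.median(pct)) if len(pct) else 0.0,
        pct_diff_range=(float(pct.min()), float(pct.max())) if len(pct) else (0.0, 0.0),
        icc=min(icc, 1.0),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


# ---------------------------------------------------------------------------
# model battery
# ---------------------------------------------------------------------------

def run_association_suite(
    subjects: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> dict:
    """The full association battery on a subjects table.

    Runs, where the needed columns are present: bivariate regressions of
    each shape mode on sphericity/conicity; of each strain on each mode
    and on sphericity/conicity; the covariate-adjusted strain models
    (sphericity + AR + AS; sphericity + gothicity + tortuosity; M3 + age
    + hypertension; sphericity + BMI + sex); and group comparisons for
    every continuous variable.  Models whose columns are missing are
    skipped with a logged warning.  Returns ``{"results": DataFrame,
    "grouptests": DataFrame, "warnings": [...]}``.
    """
    df = subjects.copy()
    if scores is not None:
        score_cols = [c for c in scores.columns if c != "subject_id"]
        df = df.merge(scores, on="subject_id", how="left", suffixes=("", "_score"))
    else:
        score_cols = []
    mode_cols = [c for c in df.columns if c.startswith("M") and c[1:].isdigit()]

    for sev in ("ar_severity", "as_severity"):
        if sev in df.columns:
            df[sev.replace("_severity", "_bin")] = binarize_severity(df[sev])

    logs: list[str] = []
    rows: list[dict] = []

    def have(*cols) -> bool:
        missing = [c for c in cols if c not in df.columns or df[c].notna().sum() < 3]
        if missing:
            logs.append(f"skipped model (missing: {missing})")
            return False
        return True

    def add_simple(xcol: str, ycol: str) -> None:
        if not have(xcol, ycol):
            return
        try:
            res = simple_regression(df[xcol], df[ycol], x_name=xcol, y_name=ycol)
        except ValueError as e:
            logs.append(f"{ycol} ~ {xcol}: {e}")
            return
        t = res.terms.set_index("term").loc[xcol]
        rows.append(
            {
                "model": res.formula,
                "term": xcol,
                "estimate": t.estimate,
                "se": t.se,
                "p": t.p,
                "R2": res.r_squared,
                "n": res.n,
            }
        )

    def add_multiple(ycol: str, xcols: list[str]) -> None:
        if not have(ycol, *xcols):
            return
        try:
            res = multiple_regression(df[ycol], df[xcols], y_name=ycol)
        except ValueError as e:
            logs.append(f"{ycol} ~ {'+'.join(xcols)}: {e}")
            return
        for _, t in res.terms.iterrows():
            if t.term == "intercept":
                continue
            rows.append(
                {
                    "model": res.formula,
                    "term": t.term,
                    "estimate": t.estimate,
                    "se": t.se,
                    "p": t.p,
                    "R2": res.r_squared,
                    "n": res.n,
                }
            )

    # modes vs morphometric indices
    for m in mode_cols:
        for idx in ("sphericity", "conicity"):
            add_simple(m, idx)
    # strain vs modes and indices
    for strain in STRAIN_COLUMNS:
        for x in list(mode_cols) + ["sphericity", "conicity"]:
            add_simple(x, strain)
    # covariate-adjusted strain models
    for strain in STRAIN_COLUMNS:
        add_multiple(strain, ["sphericity", "ar_bin", "as_bin"])
        add_multiple(strain, ["sphericity", "gothicity", "tortuosity"])
        if "M3" in df.columns:
            add_multiple(strain, ["M3", "age", "hypertension"])
        add_multiple(strain, ["sphericity", "age", "hypertension"])
        add_multiple(strain, ["sphericity", "bmi", "sex"])
    # arch vs sphericity
    add_simple("tortuosity", "sphericity")

    results = pd.DataFrame(
        rows, columns=["model", "term", "estimate", "se", "p", "R2", "n"]
    )
    if fdr and len(results):
        from statsmodels.stats.multitest import multipletests

        results["p_fdr"] = multipletests(results.p.to_numpy(), method="fdr_bh")[1]

    # group comparisons for Table-2-style continuous variables
    grows = []
    if "group" in df.columns:
        candidates = (
            list(STRAIN_COLUMNS)
            + list(VOLUME_COLUMNS)
            + ["sphericity", "conicity", "gothicity", "tortuosity", "age", "bmi"]
            + mode_cols
        )
        for var in candidates:
            if var not in df.columns:
                continue
            sub = df[[var, "group"]].dropna()
            counts = sub.group.value_counts()
            usable = counts[counts >= 3].index
            if len(usable) < 2:
                logs.append(f"group test skipped for '{var}' (too few groups)")
                continue
            sub = sub[sub.group.isin(usable)]
            try:
                gt = group_compare(sub[var], sub.group, alpha=alpha)
            except ValueError as e:
                logs.append(f"group test for '{var}': {e}")
                continue
            grows.append(
                {
                    "variable": var,
                    "test": gt.test_name,
                    "statistic": gt.statistic,
                    "p": gt.p_value,
                    "significant": gt.p_value < alpha,
                }
            )
    grouptests = pd.DataFrame(
        grows, columns=["variable", "test", "statistic", "p", "significant"]
    )
    return {"results": results, "grouptests": grouptests, "warnings": logs, "alpha": alpha}
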