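"""Per-site vertex-wise mass-univariate linear models.

Each site fits, at every template vertex independently, an ordinary
least-squares model of a shape measure on a fixed 8-column design:

    [intercept, predictor, sex, age, age x sex, age^2, age^2 x sex, ICV]

where the predictor of interest is diagnosis (0/1), chlorpromazine dose
equivalents (mg/day, patients only), or SAPS total score (patients only).
Age is centred at the site mean before powers and interactions are formed —
this improves conditioning and leaves inference on the predictor of
interest unchanged.

The predictor's t statistic is converted to a Cohen's d with sampling
variance using standard meta-analytic conversions:

* two-group (diagnosis): ``d = t (n1+n2) / (sqrt(n1 n2) sqrt(df))`` with
  ``var_d = (n1+n2)/(n1 n2) + d^2 / (2 (n1+n2))``;
* continuous predictor: via the partial correlation ``r = t/sqrt(t^2+df)``,
  ``d = 2 r / sqrt(1-r^2)`` and, by the delta method,
  ``var_d = 4/(df+2) * (1/(1-r^2))^2``.

For continuous predictors the per-unit regression slope and its standard
error are always reported alongside d, since the standardized and per-unit
scales differ by orders of magnitude for dose-like predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mesh_io import SubjectRecord
from .shape_measures import VertexMeasureMap

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = (
    "intercept", "predictor", "sex", "age", "age_x_sex", "age2", "age2_x_sex", "icv",
)
N_DESIGN_COLUMNS = len(DESIGN_COLUMNS)

#: Minimum usable site: at least this many rows overall ...
MIN_SITE_ROWS = 10
#: ... and, for two-group (diagnosis) models, at least this many per group.
MIN_GROUP_SIZE = 5


@dataclass(frozen=True)
class ModelSpec:
    """One linear model of the analysis battery.

    ``predictor`` names the predictor of interest; ``outcomes`` lists the
    measure-map keys this model is fitted to (per-hemisphere and/or
    bilateral); ``cohort_filter`` restricts the sample.
    """

    model_id: str
    predictor: str  # "dx" | "cpz" | "saps_total"
    outcomes: tuple[str, ...]
    cohort_filter: str = "all"  # "all" | "patients_only"

    def __post_init__(self):
        if self.predictor in ("cpz", "saps_total") and self.cohort_filter != "patients_only":
            raise ValueError(f"{self.model_id}: continuous clinical predictors "
                             "require cohort_filter='patients_only'")


#: The model battery: diagnosis on each measure per hemisphere and on
#: interhemispheric means (m1, m2), diagnosis on the asymmetry indices
#: (m3, m4), and dose / positive-symptom effects in patients on the
#: interhemispheric means (m5, m6).
MODELS: dict[str, ModelSpec] = {
    "m1_dx_thickness": ModelSpec(
        "m1_dx_thickness", "dx",
        ("thickness_L", "thickness_R", "mean_thickness")),
    "m2_dx_logjac": ModelSpec(
        "m2_dx_logjac", "dx",
        ("log_jacobian_L", "log_jacobian_R", "mean_log_jacobian")),
    "m3_dx_asym_thickness": ModelSpec(
        "m3_dx_asym_thickness", "dx", ("asym_thickness",)),
    "m4_dx_asym_logjac": ModelSpec(
        "m4_dx_asym_logjac", "dx", ("asym_log_jacobian",)),
    "m5_cpz": ModelSpec(
        "m5_cpz", "cpz", ("mean_thickness", "mean_log_jacobian"),
        cohort_filter="patients_only"),
    "m6_saps": ModelSpec(
        "m6_saps", "saps_total", ("mean_thickness", "mean_log_jacobian"),
        cohort_filter="patients_only"),
}


class DesignError(ValueError):
    pass


def _predictor_value(record: SubjectRecord, predictor: str):
    if predictor == "dx":
        return float(record.dx)
    if predictor == "cpz":
        return None if record.cpz is None else float(record.cpz)
    if predictor == "saps_total":
        return None if record.saps_total is None else float(record.saps_total)
    raise DesignError(f"unknown predictor {predictor!r}")


def build_design_matrix(records: Sequence[SubjectRecord], spec: ModelSpec):
    """Build the 8-column design for one site.

    Returns ``(X, labels, used_records, info)`` where ``info`` carries the
    dropped-row count, group sizes, and usability flags. Rows with a missing
    required field are dropped (and counted); a site with fewer than
    :data:`MIN_SITE_ROWS` usable rows — or, for diagnosis models, fewer
    than :data:`MIN_GROUP_SIZE` in either group — is flagged unusable. A
    rank-deficient design is flagged and not fitted.
    """
    if spec.cohort_filter == "patients_only":
        records = [r for r in records if r.dx == 1]
    rows = []
    used = []
    n_dropped = 0
    for r in records:
        x = _predictor_value(r, spec.predictor)
        if x is None:
            n_dropped += 1
            continue
        rows.append((x, float(r.sex), float(r.age), float(r.icv)))
        used.append(r)
    if n_dropped:
        logger.info("dropped %d row(s) with missing %s", n_dropped, spec.predictor)

    info = {"n_dropped": n_dropped, "usable": True, "reason": "", "rank_ok": True}
    n = len(rows)
    if spec.predictor == "dx":
        n1 = sum(1 for r in used if r.dx == 1)
        n2 = n - n1
    else:
        n1, n2 = n, 0
    info["n1"], info["n2"] = n1, n2

    if n < MIN_SITE_ROWS:
        info.update(usable=False, reason=f"only {n} usable rows (< {MIN_SITE_ROWS})")
        return np.empty((0, N_DESIGN_COLUMNS)), list(DESIGN_COLUMNS), [], info
    if spec.predictor == "dx" and min(n1, n2) < MIN_GROUP_SIZE:
        info.update(usable=False,
                    reason=f"group sizes {n1}/{n2} below minimum {MIN_GROUP_SIZE}")
        return np.empty((0, N_DESIGN_COLUMNS)), list(DESIGN_COLUMNS), [], info

    arr = np.asarray(rows)
    x, sex, age, icv = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    age_c = age - age.mean()  # centre at the site mean before powers
    X = np.column_stack([
        np.ones(n), x, sex, age_c, age_c * sex, age_c ** 2, age_c ** 2 * sex, icv,
    ])
    if np.linalg.matrix_rank(X) < N_DESIGN_COLUMNS:
        info.update(usable=False, rank_ok=False, reason="rank-deficient design")
        return X, list(DESIGN_COLUMNS), used, info
    return X, list(DESIGN_COLUMNS), used, info


def effect_size_from_t(t, n1: int, n2: int, df: int):
    """Convert the predictor's t statistic to Cohen's d with variance.

    Two-group (``n2 > 0``) and continuous-predictor (``n2 == 0``)
    conversions as documented in the module docstring. ``t`` may be an
    array; returns ``(d, var_d)`` of the same shape.
    """
    t = np.asarray(t, dtype=np.float64)
    if df < 1:
        raise ValueError("df must be >= 1")
    if n2 > 0:
        ntot = n1 + n2
        d = t * ntot / (np.sqrt(n1 * n2) * np.sqrt(df))
        var_d = ntot / (n1 * n2) + d ** 2 / (2.0 * ntot)
    else:
        if n1 < 1:
            raise ValueError("n1 must be >= 1 for continuous predictors")
        r2 = t ** 2 / (t ** 2 + df)
        d = 2.0 * t / np.sqrt(df)  # = 2 r / sqrt(1 - r^2)
        var_d = 4.0 / (df + 2.0) * (1.0 / (1.0 - r2)) ** 2
    return d, var_d


@dataclass
class SiteVertexStats:
    """Vertex-wise fit results for one (site, model, structure, map)."""

    site_id: str
    model_id: str
    structure_id: str
    map_key: str  # e.g. "thickness_L", "asym_thickness"
    d: np.ndarray
    var_d: np.ndarray
    beta: np.ndarray
    se_beta: np.ndarray
    t: np.ndarray
    df: int
    n1: int
    n2: int
    rank_ok: bool = True
    usable: bool = True
    reason: str = ""
    n_dropped: int = 0

    @property
    def n_vertices(self) -> int:
        return len(self.d) if self.usable else 0

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "vertex_index": np.arange(len(self.d)),
            "d": self.d, "var_d": self.var_d,
            "beta": self.beta, "se_beta": self.se_beta, "t": self.t,
        })
        df["df"] = self.df
        df["n1"] = self.n1
        df["n2"] = self.n2
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, site_id: str, model_id: str,
                 structure_id: str, map_key: str) -> "SiteVertexStats":
        df = pd.read_csv(path, comment="#").sort_values("vertex_index")
        return cls(
            site_id=site_id, model_id=model_id, structure_id=structure_id,
            map_key=map_key,
            d=df["d"].to_numpy(), var_d=df["var_d"].to_numpy(),
            beta=df["beta"].to_numpy(), se_beta=df["se_beta"].to_numpy(),
            t=df["t"].to_numpy(), df=int(df["df"].iloc[0]),
            n1=int(df["n1"].iloc[0]), n2=int(df["n2"].iloc[0]),
        )


def fit_vertexwise(X: np.ndarray, Y: np.ndarray, spec: ModelSpec, *,
                   site_id: str = "", structure_id: str = "", map_key: str = "",
                   n1: int = 0, n2: int = 0, info: dict | None = None
                   ) -> SiteVertexStats:
    """OLS of every vertex column of ``Y`` (n_subjects x n_vertices) on ``X``.

    The predictor of interest is column 1 of the design. Returns the full
    per-vertex effect-size map for this site.
    """
    info = info or {}
    n, p = X.shape
    if Y.shape[0] != n:
        raise DesignError(
            f"design has {n} rows but measures have {Y.shape[0]} subjects")
    df_resid = n - p
    if df_resid < 1:
        raise DesignError("non-positive residual degrees of freedom")
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Y)  # (p, V)
    resid = Y - X @ B
    rss = np.einsum("nv,nv->v", resid, resid)
    sigma2 = rss / df_resid
    j = 1  # predictor-of-interest column
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[j, j], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[j] / se, 0.0)
    d, var_d = effect_size_from_t(t, n1, n2, df_resid)
    return SiteVertexStats(
        site_id=site_id, model_id=spec.model_id, structure_id=structure_id,
        map_key=map_key, d=d, var_d=var_d, beta=B[j], se_beta=se, t=t,
        df=df_resid, n1=n1, n2=n2,
        rank_ok=info.get("rank_ok", True), usable=True,
        n_dropped=info.get("n_dropped", 0),
    )


def t_pvalues(stats: SiteVertexStats) -> np.ndarray:
    """Two-sided p-values of the predictor's t statistic (Student t)."""
    from scipy import stats as sps

    return 2.0 * sps.t.sf(np.abs(stats.t), stats.df)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class VertexwiseGLM:
    """Mass-univariate site model for one structure map.

    Parameters
    ----------
    records : sequence of SubjectRecord
        Covariate rows for one site.
    maps : sequence of VertexMeasureMap
        One measure map per subject (any order; aligned by ``subject_id``).
    spec : ModelSpec
        Which predictor, cohort filter, and outcome family to fit.

    ``fit()`` returns a :class:`VertexwiseGLMResults`.
    """

    def __init__(self, records: Sequence[SubjectRecord],
                 maps: Sequence[VertexMeasureMap], spec: ModelSpec,
                 site_id: str | None = None):
        self.spec = spec
        self.records = list(records)
        self.maps = {m.subject_id: m for m in maps}
        if len(self.maps) != len(maps):
            raise DesignError("duplicate subject_id among measure maps")
        sites = {r.site_id for r in self.records}
        if site_id is None:
            if len(sites) != 1:
                raise DesignError("records span multiple sites; pass site_id")
            site_id = next(iter(sites))
        self.site_id = site_id
        kinds = {m.measure_kind for m in maps}
        if len(kinds) > 1:
            raise DesignError(f"maps mix measure kinds: {sorted(kinds)}")

    def fit(self) -> "VertexwiseGLMResults":
        X, labels, used, info = build_design_matrix(self.records, self.spec)
        first = next(iter(self.maps.values()))
        if not info["usable"]:
            empty = np.empty(0)
            stats = SiteVertexStats(
                site_id=self.site_id, model_id=self.spec.model_id,
                structure_id=first.structure_id, map_key=first.measure_kind,
                d=empty, var_d=empty, beta=empty, se_beta=empty, t=empty,
                df=0, n1=info["n1"], n2=info["n2"],
                rank_ok=info["rank_ok"], usable=False, reason=info["reason"],
                n_dropped=info["n_dropped"])
            return VertexwiseGLMResults(self, stats, labels)
        missing = [r.subject_id for r in used if r.subject_id not in self.maps]
        if missing:
            raise DesignError(f"no measure map for subject(s): {missing[:5]}")
        Y = np.stack([self.maps[r.subject_id].values for r in used], axis=0)
        stats = fit_vertexwise(
            X, Y, self.spec, site_id=self.site_id,
            structure_id=first.structure_id, map_key=first.measure_kind,
            n1=info["n1"], n2=info["n2"], info=info)
        return VertexwiseGLMResults(self, stats, labels)


class VertexwiseGLMResults:
    """Results wrapper around :class:`SiteVertexStats`."""

    def __init__(self, model: VertexwiseGLM, stats: SiteVertexStats,
                 design_labels: list[str]):
        self.model = model
        self.stats = stats
        self.design_labels = design_labels

    @property
    def pvalues(self) -> np.ndarray:
        return t_pvalues(self.stats)

    def summary(self) -> pd.DataFrame:
        """Per-vertex table of effect sizes and test statistics."""
        s = self.stats
        return pd.DataFrame({
            "vertex_index": np.arange(len(s.d)),
            "d": s.d, "var_d": s.var_d, "beta": s.beta,
            "se_beta": s.se_beta, "t": s.t,
            "p": t_pvalues(s) if s.usable and len(s.d) else np.empty(0),
        })

    def __repr__(self) -> str:
        s = self.stats
        status = "ok" if s.usable else f"unusable ({s.reason})"
        return (f"<VertexwiseGLMResults site={s.site_id} model={s.model_id} "
                f"map={s.map_key} vertices={s.n_vertices} df={s.df} {status}>")
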