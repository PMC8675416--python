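"""Inverse-variance random-effects meta-analysis of vertex-wise effect sizes.

Each vertex is pooled independently across sites ("mass univariate"
meta-analysis). The random-effects model treats the site effect sizes
``d_i`` as draws from ``N(mu, var_i + tau^2)`` where ``tau^2`` is the
between-site heterogeneity variance. Pooling uses weights
``w_i = 1/(var_i + tau^2)``:

    pooled_d = sum(w_i d_i) / sum(w_i),   se = 1/sqrt(sum(w_i)),
    z = pooled_d / se,                     p = 2 (1 - Phi(|z|)).

``tau^2`` is estimated by restricted maximum likelihood (REML, the default,
via the standard fixed-point iteration) or by the DerSimonian–Laird moment
estimator. Heterogeneity is additionally summarised by Cochran's Q and I².

With ``tau^2 = 0`` the result reduces exactly to the fixed-effect
inverse-variance answer; a vertex with a single contributing site carries
that site's estimate flagged ``k = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .site_glm import SiteVertexStats

REML_TOL = 1e-10
REML_MAX_ITER = 100


class MetaError(ValueError):
    pass


def _dl_tau2(d: np.ndarray, var: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """DerSimonian–Laird moment estimator, vectorized over columns.

    ``d``/``var`` are (k, V); ``mask`` marks valid entries. Columns with
    fewer than 2 valid sites get tau^2 = 0.
    """
    w = np.where(mask, 1.0 / var, 0.0)
    k = mask.sum(axis=0)
    sw = w.sum(axis=0)
    sw2 = (w ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(sw > 0, (w * np.where(mask, d, 0.0)).sum(axis=0) / sw, 0.0)
    Q = (w * np.where(mask, (d - mu) ** 2, 0.0)).sum(axis=0)
    denom = sw - np.where(sw > 0, sw2 / sw, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau2 = np.where((k >= 2) & (denom > 0),
                        np.maximum(0.0, (Q - (k - 1)) / denom), 0.0)
    return tau2


def _reml_tau2(d: np.ndarray, var: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """REML estimate via the standard fixed-point iteration, vectorized.

    Iterates tau^2 <- max(0, sum w^2 ((d-mu)^2 - var) / sum w^2 + 1/sum w)
    with w = 1/(var + tau^2), starting from the DL estimate, until
    |change| < 1e-10 or 100 iterations.
    """
    tau2 = _dl_tau2(d, var, mask)
    k = mask.sum(axis=0)
    active = k >= 2
    d0 = np.where(mask, d, 0.0)
    for _ in range(REML_MAX_ITER):
        w = np.where(mask, 1.0 / (var + tau2[None, :]), 0.0)
        sw = w.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = np.where(sw > 0, (w * d0).sum(axis=0) / sw, 0.0)
        resid2 = np.where(mask, (d - mu) ** 2 - var, 0.0)
        sw2 = (w ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            new = np.maximum(
                0.0, ((w ** 2) * resid2).sum(axis=0) / np.where(sw2 > 0, sw2, 1.0)
                + np.where(sw > 0, 1.0 / sw, 0.0))
        new = np.where(active, new, 0.0)
        delta = np.abs(new - tau2)
        tau2 = new
        if delta.max(initial=0.0) < REML_TOL:
            break
    return tau2


def estimate_tau2(d_list, var_list, method: str = "REML"):
    """Between-site heterogeneity variance for a single meta-analysis.

    ``d_list`` and ``var_list`` are the per-site effect sizes and their
    sampling variances. With fewer than two sites the estimate is 0 (the
    heterogeneity is unidentifiable and flagged downstream).
    """
    d = np.asarray(d_list, dtype=np.float64)[:, None]
    var = np.asarray(var_list, dtype=np.float64)[:, None]
    mask = np.isfinite(d) & np.isfinite(var) & (var > 0)
    method = method.upper()
    if method == "DL":
        return float(_dl_tau2(d, var, mask)[0])
    if method == "REML":
        return float(_reml_tau2(d, var, mask)[0])
    raise MetaError(f"unknown tau^2 method {method!r}")


@dataclass
class MetaVertexResult:
    """Pooled vertex-wise estimates for one (model, structure, map)."""

    model_id: str
    structure_id: str
    map_key: str
    pooled_d: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    tau2: np.ndarray
    Q: np.ndarray
    I2: np.ndarray
    k: np.ndarray
    method: str = "REML"

    @property
    def n_vertices(self) -> int:
        return len(self.pooled_d)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "vertex_index": np.arange(self.n_vertices),
            "pooled_d": self.pooled_d, "se": self.se, "z": self.z,
            "p": self.p, "tau2": self.tau2, "Q": self.Q, "I2": self.I2,
            "k": self.k,
        }).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, model_id: str, structure_id: str,
                 map_key: str, method: str = "REML") -> "MetaVertexResult":
        df = pd.read_csv(path, comment="#").sort_values("vertex_index")
        return cls(model_id=model_id, structure_id=structure_id,
                   map_key=map_key, method=method,
                   pooled_d=df["pooled_d"].to_numpy(), se=df["se"].to_numpy(),
                   z=df["z"].to_numpy(), p=df["p"].to_numpy(),
                   tau2=df["tau2"].to_numpy(), Q=df["Q"].to_numpy(),
                   I2=df["I2"].to_numpy(), k=df["k"].to_numpy(dtype=np.int64))


def pool_effects(stats_list: Sequence[SiteVertexStats], method: str = "REML",
                 knapp_hartung: bool = False) -> MetaVertexResult:
    """Pool per-site vertex-wise effect sizes into one meta-analytic map.

    Unusable sites are skipped; every usable site must cover the same
    template (equal vertex counts). Per vertex, sites with non-finite d or
    variance are excluded from that vertex's pool.
    """
    usable = [s for s in stats_list if s.usable and s.n_vertices > 0]
    if not usable:
        raise MetaError("no usable site results to pool")
    n_vertices = {s.n_vertices for s in usable}
    if len(n_vertices) != 1:
        raise MetaError(f"sites disagree on vertex count: {sorted(n_vertices)}")
    ref = usable[0]
    # deterministic site order regardless of input order
    usable = sorted(usable, key=lambda s: s.site_id)
    d = np.stack([s.d for s in usable], axis=0)
    var = np.stack([s.var_d for s in usable], axis=0)
    mask = np.isfinite(d) & np.isfinite(var) & (var > 0)
    k = mask.sum(axis=0)
    if np.any(k == 0):
        import logging

        logging.getLogger(__name__).warning(
            "%d vertex/vertices with no usable site", int((k == 0).sum()))

    method_u = method.upper()
    if method_u == "DL":
        tau2 = _dl_tau2(d, var, mask)
    elif method_u == "REML":
        tau2 = _reml_tau2(d, var, mask)
    else:
        raise MetaError(f"unknown tau^2 method {method!r}")

    d0 = np.where(mask, d, 0.0)
    w = np.where(mask, 1.0 / (var + tau2[None, :]), 0.0)
    sw = w.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.where(sw > 0, (w * d0).sum(axis=0) / sw, np.nan)
        se = np.where(sw > 0, 1.0 / np.sqrt(sw), np.nan)

    # fixed-effect Q / I^2 heterogeneity summary
    wf = np.where(mask, 1.0 / var, 0.0)
    swf = wf.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_f = np.where(swf > 0, (wf * d0).sum(axis=0) / swf, 0.0)
    Q = (wf * np.where(mask, (d - mu_f) ** 2, 0.0)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        I2 = np.where((k >= 2) & (Q > 0),
                      np.maximum(0.0, (Q - (k - 1)) / np.where(Q > 0, Q, 1.0)) * 100.0,
                      0.0)

    if knapp_hartung:
        # Knapp–Hartung: scale se by sqrt(q) and use a t reference with k-1 df
        resid2 = np.where(mask, (d - pooled) ** 2, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            qscale = np.where(k >= 2, (w * resid2).sum(axis=0)
                              / (np.maximum(k - 1, 1) * np.where(sw > 0, sw, 1.0)),
                              np.nan)
        se_kh = np.sqrt(np.where(k >= 2, qscale, se ** 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se_kh > 0, pooled / se_kh, 0.0)
        p = 2.0 * sps.t.sf(np.abs(z), np.maximum(k - 1, 1))
        p = np.where(k >= 2, p, 2.0 * sps.norm.sf(np.abs(pooled / se)))
        se_out = se_kh
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, pooled / se, 0.0)
        p = 2.0 * sps.norm.sf(np.abs(z))
        se_out = se

    return MetaVertexResult(
        model_id=ref.model_id, structure_id=ref.structure_id,
        map_key=ref.map_key, pooled_d=pooled, se=se_out, z=z, p=p,
        tau2=tau2, Q=Q, I2=I2, k=k.astype(np.int64), method=method_u)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class RandomEffectsMeta:
    """Random-effects meta-analysis model over per-site vertex statistics.

    ``fit()`` returns a :class:`MetaResults` wrapping the pooled per-vertex
    estimates with a ``summary()`` table.
    """

    def __init__(self, stats_list: Sequence[SiteVertexStats],
                 method: str = "REML", knapp_hartung: bool = False):
        self.stats_list = list(stats_list)
        self.method = method
        self.knapp_hartung = knapp_hartung

    def fit(self) -> "MetaResults":
        result = pool_effects(self.stats_list, method=self.method,
                              knapp_hartung=self.knapp_hartung)
        return MetaResults(self, result)


class MetaResults:
    def __init__(self, model: RandomEffectsMeta, result: MetaVertexResult):
        self.model = model
        self.result = result

    @property
    def pooled_d(self) -> np.ndarray:
        return self.result.pooled_d

    @property
    def pvalues(self) -> np.ndarray:
        return self.result.p

    def conf_int(self, alpha: float = 0.05):
        zq = sps.norm.ppf(1.0 - alpha / 2.0)
        r = self.result
        return np.column_stack([r.pooled_d - zq * r.se, r.pooled_d + zq * r.se])

    def summary(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame({
            "vertex_index": np.arange(r.n_vertices),
            "pooled_d": r.pooled_d, "se": r.se, "z": r.z, "p": r.p,
            "tau2": r.tau2, "Q": r.Q, "I2": r.I2, "k": r.k,
        })

    def __repr__(self) -> str:
        r = self.result
        return (f"<MetaResults model={r.model_id} map={r.map_key} "
                f"vertices={r.n_vertices} sites<= {int(r.k.max(initial=0))} "
                f"method={r.method}>")
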