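"""Searchlight false-discovery-rate correction on atlas meshes.

Multiple-comparison correction across *all* structures, vertices, and
measures of one linear model is performed with a regionally adaptive
("searchlight") FDR procedure:

Stage 1 (local step-up). Vertex ``v`` is a candidate at working level
``q*`` if its p-value is at or below the Benjamini–Hochberg step-up
threshold computed over the p-values inside its searchlight neighbourhood
``N(v)`` — the same-structure vertices within the searchlight radius of
``v`` (vertices of different structures are at infinite distance, so
neighbourhoods never cross structure boundaries).

Stage 2 (global calibration). The working level ``q*`` is calibrated so
that a plug-in estimate of the global FDR over the whole family,

    FDR_hat(q*) = m0_hat * tbar(q*) / max(1, R(q*)),

stays at or below the requested level ``q``; here ``R`` is the total
number of rejections, ``tbar`` the rejection-weighted mean of the local
step-up thresholds, and ``m0_hat`` the estimated number of true nulls.
``m0_hat = m`` by default (conservative; with global neighbourhoods the
procedure then reduces *exactly* to Benjamini–Hochberg on the family), or
the Storey estimator at lambda = 0.5 when ``m0_method="storey"``.
Calibration scans a fixed grid of candidate levels (always including
``q``) and refines the best bracket by bisection; all ties are resolved by
vertex order, so the output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import json

import numpy as np
import pandas as pd

_GRID = None


class FDRError(ValueError):
    pass


def bh_threshold(pvals: Sequence[float], q: float) -> float:
    """Benjamini–Hochberg step-up rejection threshold.

    Returns the largest ``p_(i)`` (ascending order) with
    ``p_(i) <= i q / m``, or 0.0 if none qualifies. Rejections are exactly
    the p-values at or below the returned threshold.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        raise FDRError("empty p-value list")
    if not (0.0 < q < 1.0):
        raise FDRError(f"q must be in (0, 1), got {q}")
    s = np.sort(p, kind="stable")
    m = s.size
    crit = (np.arange(1, m + 1) / m) * q
    ok = np.flatnonzero(s <= crit)
    return float(s[ok[-1]]) if ok.size else 0.0


@dataclass
class SignificanceMask:
    """Thresholded vertex-wise significance for one model family."""

    model_id: str
    keys: list
    p: dict
    significant: dict
    local_threshold: dict
    q: float
    q_star: float
    m0: float
    radius: float
    m0_method: str = "total"

    def n_rejections(self, key=None) -> int:
        if key is not None:
            return int(self.significant[key].sum())
        return int(sum(s.sum() for s in self.significant.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.keys:
            structure, measure = key if isinstance(key, tuple) else (str(key), "")
            rows.append(pd.DataFrame({
                "structure": str(structure),
                "measure": str(measure),
                "vertex_index": np.arange(len(self.p[key])),
                "p": self.p[key],
                "significant": self.significant[key],
                "local_threshold": self.local_threshold[key],
            }))
        return pd.concat(rows, ignore_index=True)

    def save(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        if json_path is not None:
            summary = {
                "model_id": self.model_id,
                "q": self.q, "q_star": self.q_star, "m0": self.m0,
                "m0_method": self.m0_method, "radius": self.radius,
                "rejections": {
                    "/".join(map(str, key)) if isinstance(key, tuple) else str(key):
                        self.n_rejections(key)
                    for key in self.keys
                },
            }
            with open(json_path, "w", encoding="utf-8") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)


def _pad_neighborhoods(p_maps, neighborhoods, keys):
    """Flatten the family into global indices with padded neighbour arrays."""
    offsets = {}
    total = 0
    for key in keys:
        offsets[key] = total
        total += len(p_maps[key])
    p_all = np.concatenate([np.asarray(p_maps[key], dtype=np.float64)
                            for key in keys])
    if np.any(~np.isfinite(p_all)) or p_all.min(initial=0.0) < 0 or \
            p_all.max(initial=0.0) > 1:
        raise FDRError("p-values must be finite and in [0, 1]")
    sizes = []
    for key in keys:
        nbs = neighborhoods[key]
        if len(nbs) != len(p_maps[key]):
            raise FDRError(f"{key}: neighbourhood list does not match p map")
        sizes.extend(len(nb) for nb in nbs)
    max_k = max(sizes)
    m = total
    nb_idx = np.zeros((m, max_k), dtype=np.int64)
    K = np.zeros(m, dtype=np.int64)
    row = 0
    for key in keys:
        off = offsets[key]
        for nb in neighborhoods[key]:
            nb = np.asarray(nb, dtype=np.int64)
            K[row] = nb.size
            nb_idx[row, :nb.size] = nb + off
            row += 1
    return p_all, nb_idx, K, offsets


def _candidate_criticals(p_all, nb_idx, K):
    """Per-vertex smallest working level at which the vertex is a candidate,
    plus sorted (level, threshold) step functions for the local thresholds.

    For vertex ``v`` with sorted neighbourhood p-values ``s_1..s_k``, the
    local BH threshold at level ``q*`` is ``max{s_i : s_i <= i q*/k}``; the
    vertex is a candidate iff some ``i`` has ``s_i >= p_v`` and
    ``s_i k / i <= q*``. The smallest such level is
    ``c(v) = min_{i: s_i >= p_v} s_i k / i``.
    """
    m, max_k = nb_idx.shape
    s = p_all[nb_idx]
    pad = np.arange(max_k)[None, :] >= K[:, None]
    s[pad] = np.inf
    s = np.sort(s, axis=1, kind="stable")
    i = np.arange(1, max_k + 1)[None, :].astype(np.float64)
    with np.errstate(invalid="ignore"):
        r = s * (K[:, None] / i)
    r[pad] = np.inf
    ge = s >= p_all[:, None]
    c = np.where(ge, r, np.inf).min(axis=1)
    # step function of the local threshold: sort (r, s) by r, prefix-max s
    order = np.argsort(r, axis=1, kind="stable")
    r_sorted = np.take_along_axis(r, order, axis=1)
    s_by_r = np.take_along_axis(np.where(np.isinf(r), -np.inf, s), order, axis=1)
    prefmax = np.maximum.accumulate(s_by_r, axis=1)
    return c, r_sorted, prefmax


def _estimate(qs, c, r_sorted, prefmax, m0, q):
    """Plug-in global FDR estimate at working level ``qs``.

    Returns (feasible, n_rejections).
    """
    rej = np.flatnonzero(c <= qs)
    R = rej.size
    if R == 0:
        return True, 0
    cnt = (r_sorted[rej] <= qs).sum(axis=1)
    T = prefmax[rej, cnt - 1]  # cnt >= 1 whenever c <= qs
    est = m0 * T.mean() / R
    return bool(est <= q), R


def searchlight_fdr(p_maps: Mapping[Hashable, np.ndarray],
                    neighborhoods: Mapping[Hashable, Sequence[np.ndarray]],
                    q: float = 0.05,
                    m0_method: str = "total",
                    model_id: str = "",
                    radius: float = float("nan"),
                    n_grid: int = 129,
                    n_bisect: int = 50) -> SignificanceMask:
    """Two-stage searchlight FDR over one model's whole family.

    ``p_maps`` maps family keys — typically ``(structure, measure)`` or
    ``(structure_hemisphere, measure)`` — to vertex p-value arrays;
    ``neighborhoods`` maps the same keys to per-vertex arrays of
    same-structure neighbour indices (always containing the vertex itself).
    """
    if not (0.0 < q < 1.0):
        raise FDRError(f"q must be in (0, 1), got {q}")
    keys = sorted(p_maps, key=str)
    if not keys:
        raise FDRError("empty family")
    p_all, nb_idx, K, offsets = _pad_neighborhoods(p_maps, neighborhoods, keys)
    m = p_all.size
    if m0_method == "total":
        m0 = float(m)
    elif m0_method == "storey":
        lam = 0.5
        m0 = min(float(m), (float((p_all > lam).sum()) + 1.0) / (1.0 - lam))
    else:
        raise FDRError(f"unknown m0_method {m0_method!r}")

    c, r_sorted, prefmax = _candidate_criticals(p_all, nb_idx, K)

    # calibration: coarse grid (always containing q), then bisection of the
    # bracket around the best feasible grid point
    grid = np.unique(np.concatenate([
        np.geomspace(1e-10, 1.0, n_grid), [q]]))
    feasible_mask = np.array(
        [_estimate(g, c, r_sorted, prefmax, m0, q)[0] for g in grid])
    if feasible_mask.any():
        best = float(grid[np.flatnonzero(feasible_mask)[-1]])
    else:
        best = 0.0
    above = grid[(grid > best) & ~feasible_mask]
    hi = float(above.min()) if above.size else 1.0
    lo = best
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        ok, _R = _estimate(mid, c, r_sorted, prefmax, m0, q)
        if ok:
            lo = mid
            best = max(best, mid)
        else:
            hi = mid
    q_star = best

    rejected = c <= q_star
    # local thresholds at the calibrated level
    thr = np.zeros(m)
    cnt = (r_sorted <= q_star).sum(axis=1)
    has = cnt > 0
    thr[has] = np.maximum(prefmax[has, cnt[has] - 1], 0.0)

    p_dict, sig_dict, thr_dict = {}, {}, {}
    for key in keys:
        off = offsets[key]
        n = len(p_maps[key])
        p_dict[key] = p_all[off:off + n]
        sig_dict[key] = rejected[off:off + n].copy()
        thr_dict[key] = thr[off:off + n].copy()
    return SignificanceMask(
        model_id=model_id, keys=keys, p=p_dict, significant=sig_dict,
        local_threshold=thr_dict, q=q, q_star=q_star, m0=m0, radius=radius,
        m0_method=m0_method)
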