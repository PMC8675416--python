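"""Post-meta-analysis summaries: measure concordance, overall effect sizes,
and the direction of asymmetry differences.

Concordance asks whether the two shape measures (thickness and
log-Jacobian) flag the same vertices in the same direction. A vertex is
*concordant* when it is significant for both measures and the pooled
effect sizes share a sign; the reported proportion uses the union of the
two significant sets as denominator ("of all flagged vertices, how many
agree"), stated in the output metadata.

Overall effects summarise a structure by averaging pooled Cohen's d over
the significant vertices of the interhemispheric-mean model — separately
for vertices with positive and with negative effects. A side with no
significant vertices is reported as undefined (NaN), never as 0.

Asymmetry direction labels significant vertices of the asymmetry models:
positive pooled d (patients' |L − R| larger than controls') means
*exaggerated* asymmetry, negative means *diminished*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .meta_analysis import MetaVertexResult
from .searchlight_fdr import SignificanceMask


class SummaryError(ValueError):
    pass


@dataclass
class ConcordanceSummary:
    structure_id: str
    n_sig_thickness: int
    n_sig_logjac: int
    n_concordant: int
    proportion_concordant: float  # denominator: union of significant sets
    mean_pos_d_thickness: float  # NaN when undefined
    mean_neg_d_thickness: float
    mean_pos_d_logjac: float
    mean_neg_d_logjac: float


def overall_effects(meta: MetaVertexResult, significant: np.ndarray
                    ) -> tuple[float, float]:
    """Mean pooled d over significant vertices, split by sign.

    Returns ``(mean_pos_d, mean_neg_d)``; an absent side is NaN.
    """
    significant = np.asarray(significant, dtype=bool)
    if len(significant) != meta.n_vertices:
        raise SummaryError("mask length does not match meta result")
    d = meta.pooled_d[significant]
    pos = d[d > 0]
    neg = d[d < 0]
    mean_pos = float(pos.mean()) if pos.size else float("nan")
    mean_neg = float(neg.mean()) if neg.size else float("nan")
    return mean_pos, mean_neg


def concordance(mask: SignificanceMask,
                meta: Mapping, thickness_measure: str = "mean_thickness",
                logjac_measure: str = "mean_log_jacobian"
                ) -> list[ConcordanceSummary]:
    """Per-structure concordance of the two measures on one family mask.

    ``meta`` maps the mask's family keys ``(structure, measure)`` to their
    :class:`MetaVertexResult`. Both measures must be present for every
    structure in the mask.
    """
    structures = sorted({key[0] for key in mask.keys})
    out = []
    for structure in structures:
        kt = (structure, thickness_measure)
        kj = (structure, logjac_measure)
        if kt not in mask.significant or kj not in mask.significant:
            raise SummaryError(f"{structure}: family lacks one of the measures")
        sig_t = np.asarray(mask.significant[kt], dtype=bool)
        sig_j = np.asarray(mask.significant[kj], dtype=bool)
        mt, mj = meta[kt], meta[kj]
        if mt.n_vertices != len(sig_t) or mj.n_vertices != len(sig_j):
            raise SummaryError(f"{structure}: atlas mismatch between mask and meta")
        both = sig_t & sig_j
        same_sign = np.sign(mt.pooled_d) == np.sign(mj.pooled_d)
        conc = both & same_sign
        union = sig_t | sig_j
        n_union = int(union.sum())
        prop = float(conc.sum() / n_union) if n_union else float("nan")
        pos_t, neg_t = overall_effects(mt, sig_t)
        pos_j, neg_j = overall_effects(mj, sig_j)
        out.append(ConcordanceSummary(
            structure_id=structure,
            n_sig_thickness=int(sig_t.sum()),
            n_sig_logjac=int(sig_j.sum()),
            n_concordant=int(conc.sum()),
            proportion_concordant=prop,
            mean_pos_d_thickness=pos_t, mean_neg_d_thickness=neg_t,
            mean_pos_d_logjac=pos_j, mean_neg_d_logjac=neg_j,
        ))
    return out


def concordance_frame(summaries: list[ConcordanceSummary]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in summaries])
    df.attrs["denominator"] = "union of significant sets"
    return df


def asymmetry_direction(meta_asym: MetaVertexResult,
                        significant: np.ndarray) -> np.ndarray:
    """Label significant asymmetry-model vertices.

    Returns an object array with "exaggerated" (pooled d > 0: patients'
    |L − R| larger), "diminished" (pooled d < 0), or "" for non-significant
    vertices.
    """
    if not meta_asym.map_key.startswith("asym_"):
        raise SummaryError(
            f"asymmetry_direction needs an asym_* result, got {meta_asym.map_key!r}")
    significant = np.asarray(significant, dtype=bool)
    if len(significant) != meta_asym.n_vertices:
        raise SummaryError("mask length does not match meta result")
    labels = np.full(meta_asym.n_vertices, "", dtype=object)
    labels[significant & (meta_asym.pooled_d > 0)] = "exaggerated"
    labels[significant & (meta_asym.pooled_d < 0)] = "diminished"
    return labels
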