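"""Two-phase analysis pipeline: per-site statistics, then meta-analysis.

The pipeline mirrors a federated consortium workflow: the *site phase*
turns one site's corresponded meshes and covariates into vertex-wise
effect-size maps (shape measures → GLM → per-site CSVs) that can be
exchanged as flat files, and the *meta phase* pools the site CSVs into
meta-analytic maps, applies the searchlight FDR globally per model family,
and writes summary tables. Both phases are deterministic: re-running with
identical inputs and config produces byte-identical outputs, and every
output carries the config hash, seed, and package version in a leading
comment line.

FDR families group the maps that are corrected together for each linear
model: the diagnosis models on the per-hemisphere measures form one family
(all structure-sides × both measures), the diagnosis models on
interhemispheric means another, the asymmetry models a third, and the
dose / symptom models one family each.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mesh_io import (
    AtlasTemplate,
    SubjectRecord,
    read_covariates,
    read_mesh,
    vertex_neighborhoods,
)
from .meta_analysis import MetaVertexResult, pool_effects
from .searchlight_fdr import SignificanceMask, searchlight_fdr
from .shape_measures import subject_measures
from .site_glm import MODELS, ModelSpec, SiteVertexStats, VertexwiseGLM, t_pvalues
from .summaries import asymmetry_direction, concordance, concordance_frame

logger = logging.getLogger(__name__)

#: FDR family → list of (model_id, map_key). Correction is applied globally
#: across all structures and both measures within each family.
FAMILIES: dict[str, list[tuple[str, str]]] = {
    "diagnosis": [("m1_dx_thickness", "thickness_L"),
                  ("m1_dx_thickness", "thickness_R"),
                  ("m2_dx_logjac", "log_jacobian_L"),
                  ("m2_dx_logjac", "log_jacobian_R")],
    "diagnosis_mean": [("m1_dx_thickness", "mean_thickness"),
                       ("m2_dx_logjac", "mean_log_jacobian")],
    "asymmetry": [("m3_dx_asym_thickness", "asym_thickness"),
                  ("m4_dx_asym_logjac", "asym_log_jacobian")],
    "cpz": [("m5_cpz", "mean_thickness"), ("m5_cpz", "mean_log_jacobian")],
    "saps": [("m6_saps", "mean_thickness"), ("m6_saps", "mean_log_jacobian")],
}


@dataclass
class RunConfig:
    """Paths and options of one pipeline run."""

    atlas_dir: str = "atlas"
    meshes_dir: str = "meshes"
    covariates: str = "covariates.csv"
    out_dir: str = "results"
    models: tuple[str, ...] = tuple(MODELS)
    q: float = 0.05
    radius: float = 10.0  # searchlight radius, mm in template space
    tau2_method: str = "REML"
    m0_method: str = "total"
    knapp_hartung: bool = False
    n_bands: int = 30
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    def provenance(self) -> str:
        return (f"# config_hash={self.config_hash()} seed={self.seed} "
                f"version={__version__}")


def _write_frame(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(config.provenance() + "\n")
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def _stats_frame(stats: SiteVertexStats) -> pd.DataFrame:
    df = pd.DataFrame({
        "vertex_index": np.arange(len(stats.d)),
        "d": stats.d, "var_d": stats.var_d, "beta": stats.beta,
        "se_beta": stats.se_beta, "t": stats.t,
    })
    df["df"] = stats.df
    df["n1"] = stats.n1
    df["n2"] = stats.n2
    return df


# ---------------------------------------------------------------------------
# In-memory analysis (used by the file pipeline, tests, and the CLI alike)
# ---------------------------------------------------------------------------


def compute_site_measures(atlas: AtlasTemplate,
                          records: Sequence[SubjectRecord],
                          meshes: dict, n_bands: int = 30):
    """All measure maps for one site.

    ``meshes[subject_id][(structure, hemi)]`` are the subject meshes.
    Returns ``maps[(structure, map_key)] = list of VertexMeasureMap`` (one
    per subject, in record order) and the list of excluded subject ids.
    """
    maps: dict[tuple[str, str], list] = {}
    excluded: list[str] = []
    for record in records:
        subj = meshes.get(record.subject_id)
        if subj is None:
            excluded.append(record.subject_id)
            continue
        for structure in atlas.structures:
            pair = {h: subj[(structure, h)] for h in ("L", "R")}
            measures = subject_measures(pair, atlas, structure, n_bands=n_bands)
            for map_key, m in measures.items():
                maps.setdefault((structure, map_key), []).append(m)
    return maps, excluded


def fit_site_models(records: Sequence[SubjectRecord], maps: dict,
                    model_ids: Sequence[str], site_id: str
                    ) -> dict[tuple[str, str, str], SiteVertexStats]:
    """Fit every requested model at one site.

    Returns ``stats[(model_id, structure, map_key)]``.
    """
    out: dict[tuple[str, str, str], SiteVertexStats] = {}
    subject_ids = {r.subject_id for r in records}
    for model_id in model_ids:
        spec = MODELS[model_id]
        for (structure, map_key), site_maps in maps.items():
            if map_key not in spec.outcomes:
                continue
            usable_maps = [m for m in site_maps if m.subject_id in subject_ids]
            glm = VertexwiseGLM(records, usable_maps, spec, site_id=site_id)
            res = glm.fit()
            res.stats.structure_id = structure
            res.stats.map_key = map_key
            out[(model_id, structure, map_key)] = res.stats
            if not res.stats.usable:
                logger.info("site %s unusable for %s/%s/%s: %s", site_id,
                            model_id, structure, map_key, res.stats.reason)
    return out


@dataclass
class AnalysisResult:
    """Everything the meta phase produces, in memory."""

    meta: dict  # (model_id, structure, map_key) -> MetaVertexResult
    masks: dict  # family -> SignificanceMask
    concordance: pd.DataFrame | None
    asym_labels: dict  # (structure, map_key) -> label array
    report: dict


def run_meta_analysis(site_stats: Sequence[dict], atlas: AtlasTemplate,
                      config: RunConfig) -> AnalysisResult:
    """Pool per-site stats, threshold with searchlight FDR, and summarise.

    ``site_stats`` is one dict per site, keyed ``(model_id, structure,
    map_key)``.
    """
    # --- pool each map across sites -------------------------------------
    keys = sorted({k for s in site_stats for k in s})
    meta: dict = {}
    report: dict = {"pooling": {}, "q": config.q, "radius": config.radius,
                    "tau2_method": config.tau2_method,
                    "config_hash": config.config_hash()}
    for key in keys:
        stats_list = [s[key] for s in site_stats if key in s]
        usable = [s for s in stats_list if s.usable]
        if not usable:
            report["pooling"]["/".join(key)] = "no usable site"
            continue
        dropped = [s.site_id for s in stats_list if not s.usable]
        if dropped:
            report["pooling"]["/".join(key)] = (
                f"pooled {len(usable)} site(s); excluded "
                + ", ".join(f"{s.site_id} ({s.reason})"
                            for s in stats_list if not s.usable))
        meta[key] = pool_effects(usable, method=config.tau2_method,
                                 knapp_hartung=config.knapp_hartung)

    # --- searchlight FDR per family -------------------------------------
    neighborhoods = vertex_neighborhoods(atlas, config.radius)
    masks: dict[str, SignificanceMask] = {}
    for family, members in FAMILIES.items():
        p_maps, nb = {}, {}
        for model_id, map_key in members:
            if model_id not in config.models:
                continue
            for structure in atlas.structures:
                key = (model_id, structure, map_key)
                if key not in meta:
                    continue
                if map_key.endswith("_L") or map_key.endswith("_R"):
                    hemi = map_key[-1]
                    region = f"{structure}_{hemi}"
                    nb_key = (structure, hemi)
                else:
                    region = structure
                    nb_key = (structure, "L")  # bilateral maps live on L coords
                fam_key = (region, map_key)
                p_maps[fam_key] = meta[key].p
                nb[fam_key] = neighborhoods[nb_key]
        if not p_maps:
            continue
        masks[family] = searchlight_fdr(
            p_maps, nb, q=config.q, m0_method=config.m0_method,
            model_id=family, radius=config.radius)
        report.setdefault("rejections", {})[family] = masks[family].n_rejections()

    # --- summaries -------------------------------------------------------
    conc_df = None
    both_measures = all(model_id in config.models
                        for model_id, _ in FAMILIES["diagnosis_mean"])
    if "diagnosis_mean" in masks and both_measures:
        mask = masks["diagnosis_mean"]
        meta_by_fam = {}
        for (model_id, map_key) in FAMILIES["diagnosis_mean"]:
            for structure in atlas.structures:
                key = (model_id, structure, map_key)
                if key in meta:
                    meta_by_fam[(structure, map_key)] = meta[key]
        if meta_by_fam:
            conc_df = concordance_frame(concordance(mask, meta_by_fam))

    asym_labels: dict = {}
    if "asymmetry" in masks:
        mask = masks["asymmetry"]
        for (model_id, map_key) in FAMILIES["asymmetry"]:
            for structure in atlas.structures:
                key = (model_id, structure, map_key)
                if key in meta:
                    sig = mask.significant.get((structure, map_key))
                    if sig is not None:
                        asym_labels[(structure, map_key)] = asymmetry_direction(
                            meta[key], sig)

    return AnalysisResult(meta=meta, masks=masks, concordance=conc_df,
                          asym_labels=asym_labels, report=report)


def analyze_dataset(dataset, config: RunConfig) -> AnalysisResult:
    """End-to-end in-memory analysis of a (simulated) multi-site dataset."""
    site_stats = []
    for site_id in dataset.site_ids:
        records = dataset.site_records(site_id)
        maps, _ = compute_site_measures(dataset.atlas, records,
                                        dataset.meshes, n_bands=config.n_bands)
        site_stats.append(fit_site_models(records, maps, config.models,
                                          site_id))
    return run_meta_analysis(site_stats, dataset.atlas, config)


# ---------------------------------------------------------------------------
# File-based phases
# ---------------------------------------------------------------------------


def _load_site_inputs(config: RunConfig, site_id: str):
    records = read_covariates(config.covariates)  # fails fast on bad columns
    records = [r for r in records if r.site_id == site_id]
    if not records:
        raise ValueError(f"no covariate rows for site {site_id!r}")
    atlas = AtlasTemplate.load(config.atlas_dir)
    meshdir = Path(config.meshes_dir) / site_id
    meshes: dict[str, dict] = {}
    for record in records:
        subj: dict = {}
        complete = True
        for structure in atlas.structures:
            for hemi in ("L", "R"):
                p = meshdir / f"{record.subject_id}_{structure}_{hemi}.ply"
                if not p.exists():
                    complete = False
                    break
                subj[(structure, hemi)] = read_mesh(
                    p, structure_id=structure, hemisphere=hemi,
                    subject_id=record.subject_id)
            if not complete:
                break
        if complete:
            meshes[record.subject_id] = subj
    return atlas, records, meshes


def run_site(config: RunConfig, site_id: str,
             write_measures: bool = False) -> Path:
    """Site phase: measures → GLM → per-site CSVs. Idempotent.

    Writes ``<out_dir>/sites/<site_id>/`` with one stats CSV per (model,
    structure, map) plus a site manifest (exclusions, atlas checksum,
    provenance).
    """
    atlas, records, meshes = _load_site_inputs(config, site_id)
    out = Path(config.out_dir) / "sites" / site_id
    out.mkdir(parents=True, exist_ok=True)

    maps, excluded = compute_site_measures(atlas, records, meshes,
                                           n_bands=config.n_bands)
    if excluded:
        logger.warning("site %s: %d subject(s) missing meshes, skipped",
                       site_id, len(excluded))
    used_records = [r for r in records if r.subject_id not in excluded]

    if write_measures:
        mdir = out / "measures"
        mdir.mkdir(exist_ok=True)
        for (structure, map_key), site_maps in sorted(maps.items()):
            for m in site_maps:
                m.to_csv(mdir / f"{m.subject_id}_{structure}_{map_key}.csv")

    stats = fit_site_models(used_records, maps, config.models, site_id)
    manifest = {
        "site_id": site_id,
        "atlas_checksum": atlas.checksum(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_records": len(records),
        "excluded_subjects": sorted(excluded),
        "unusable": {},
    }
    for (model_id, structure, map_key), s in sorted(stats.items()):
        name = f"{model_id}__{structure}__{map_key}.csv"
        if s.usable:
            _write_frame(_stats_frame(s), out / name, config)
        else:
            manifest["unusable"]["/".join((model_id, structure, map_key))] = s.reason
    with open(out / "site_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _load_site_stats(site_dir: Path) -> tuple[dict, dict]:
    with open(site_dir / "site_manifest.json", "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    stats: dict = {}
    for p in sorted(site_dir.glob("*__*__*.csv")):
        model_id, structure, map_key = p.stem.split("__")
        stats[(model_id, structure, map_key)] = SiteVertexStats.from_csv(
            p, site_id=manifest["site_id"], model_id=model_id,
            structure_id=structure, map_key=map_key)
    return stats, manifest


def run_meta(config: RunConfig, site_dirs: Sequence[str | Path]) -> Path:
    """Meta phase: pool site CSVs, threshold, summarise, write reports."""
    if not site_dirs:
        raise ValueError("need at least one site result directory")
    atlas = AtlasTemplate.load(config.atlas_dir)
    all_stats, checksums = [], set()
    unusable_notes: dict[str, list[str]] = {}
    for d in site_dirs:
        stats, manifest = _load_site_stats(Path(d))
        all_stats.append(stats)
        checksums.add(manifest["atlas_checksum"])
        for key, reason in manifest.get("unusable", {}).items():
            unusable_notes.setdefault(key, []).append(
                f"{manifest['site_id']} ({reason})")
    if len(checksums) > 1:
        raise ValueError("template checksum mismatch across sites — "
                         "vertex correspondences are not aligned")
    if atlas.checksum() not in checksums:
        raise ValueError("template checksum mismatch: site results were not "
                         "computed on the configured atlas")

    result = run_meta_analysis(all_stats, atlas, config)
    for key, notes in unusable_notes.items():
        entry = result.report["pooling"].get(key, "")
        result.report["pooling"][key] = (entry + "; " if entry else "") + \
            "excluded " + ", ".join(notes)
    out = Path(config.out_dir) / "meta"
    out.mkdir(parents=True, exist_ok=True)

    for (model_id, structure, map_key), m in sorted(result.meta.items()):
        df = pd.DataFrame({
            "vertex_index": np.arange(m.n_vertices),
            "pooled_d": m.pooled_d, "se": m.se, "z": m.z, "p": m.p,
            "tau2": m.tau2, "Q": m.Q, "I2": m.I2, "k": m.k,
        })
        _write_frame(df, out / f"meta__{model_id}__{structure}__{map_key}.csv",
                     config)
    for family, mask in sorted(result.masks.items()):
        frame = mask.to_frame()
        _write_frame(frame, out / f"mask__{family}.csv", config)
        mask.save(out / f"mask__{family}.csv.tmp", out / f"mask__{family}.json")
        (out / f"mask__{family}.csv.tmp").unlink()
    if result.concordance is not None:
        _write_frame(result.concordance, out / "concordance.csv", config)
    if result.asym_labels:
        rows = []
        for (structure, map_key), labels in sorted(result.asym_labels.items()):
            rows.append(pd.DataFrame({
                "structure": structure, "measure": map_key,
                "vertex_index": np.arange(len(labels)), "direction": labels,
            }))
        _write_frame(pd.concat(rows, ignore_index=True),
                     out / "asymmetry_direction.csv", config)
    report = dict(result.report)
    report.update(config_hash=config.config_hash(), seed=config.seed,
                  version=__version__, n_sites=len(site_dirs))
    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return out


def run_all(config: RunConfig) -> Path:
    """Site phase for every site in the covariate table, then the meta phase."""
    records = read_covariates(config.covariates)
    site_ids = sorted({r.site_id for r in records})
    site_dirs = [run_site(config, site_id) for site_id in site_ids]
    return run_meta(config, site_dirs)
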