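"""End-to-end orchestration: config validation, occurrence import, and the
simulate -> covariates -> ensemble -> suitability -> connectivity chain.

A single root seed deterministically spawns one sub-seed per stochastic
stage (landscape, presence sampling, pseudo-absences, splits, permutation
importance), so any stage can be re-run in isolation and the whole run is
reproducible checksum-for-checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import connectivity as conn
from . import covariates as cov
from . import sdm
from . import suitability as suit_ops
from . import synthetic as syn
from .rasters import write_ascii_grid, write_landcover

__version__ = "0.1.0"

log = logging.getLogger("corridorscape")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Configuration schema (versioned; unknown keys rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LandscapeSection(_Strict):
    width_cells: int = 64
    height_cells: int = 64
    cell_size_m: float = Field(100.0, gt=0)
    patch_scale_cells: float = Field(3.0, gt=0)
    river_count: int = Field(1, ge=0)
    raster_path: str | None = None  # load instead of simulate when set


class OccurrenceSection(_Strict):
    source: Literal["synthetic", "csv", "xlsx"] = "synthetic"
    path: str | None = None
    # Defaults are the per-area presence counts of the original field survey.
    n_presence: dict[str, int] = Field(
        default_factory=lambda: {syn.TICINO: 96, syn.APENNINE: 71})


class CVSection(_Strict):
    train_fraction: float = Field(0.75, gt=0, lt=1)
    n_reps: int = Field(3, ge=1)


class CovariateSection(_Strict):
    buffer_radius_m: float = Field(100.0, gt=0)
    collinearity_threshold: float = Field(0.60, gt=0, le=1)


class ResistanceSection(_Strict):
    r_max: float = Field(100.0, gt=1)


class SourceSection(_Strict):
    grid_size_m: float = Field(1000.0, gt=0)
    suitability_threshold: float = 0.5
    rarefy_stratum: str | None = "north_massif"
    rarefy_dist_m: float = Field(5000.0, gt=0)


class ScenarioSection(_Strict):
    name: str
    threshold_km: float = Field(gt=0)


class GBMSection(_Strict):
    n_stages: int = Field(500, ge=1)
    learning_rate: float = Field(0.05, gt=0)
    max_depth: int = Field(3, ge=1)


class MaxentSection(_Strict):
    features: Literal["l", "lq"] = "lq"
    l1_penalty: float | None = None


class RunConfig(_Strict):
    schema_version: int = 1
    seed: int
    output_dir: str
    landscape: LandscapeSection = LandscapeSection()
    occurrences: OccurrenceSection = OccurrenceSection()
    pseudo_absences: dict[str, int] = Field(
        default_factory=lambda: {syn.TICINO: 300, syn.APENNINE: 500})
    models: list[str] = Field(default_factory=lambda: list(sdm.MODEL_KINDS))
    cv: CVSection = CVSection()
    covariates: CovariateSection = CovariateSection()
    resistance: ResistanceSection = ResistanceSection()
    sources: SourceSection = SourceSection()
    scenarios: list[ScenarioSection] = Field(default_factory=lambda: [
        ScenarioSection(name="low", threshold_km=100.0),
        ScenarioSection(name="high", threshold_km=850.0)])
    gbm: GBMSection = GBMSection()
    maxent: MaxentSection = MaxentSection()


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` listing every missing mandatory key, unknown
    key, or out-of-range value (with the offending key named).
    """
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except OSError as exc:
        raise ConfigError(f"cannot read config: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            key = ".".join(str(p) for p in err["loc"]) or "<root>"
            if err["type"] == "missing":
                msgs.append(f"missing mandatory key: {key}")
            else:
                msgs.append(f"{key}: {err['msg']}")
        raise ConfigError("; ".join(msgs)) from exc
    for model in cfg.models:
        if model not in sdm.MODEL_KINDS:
            raise ConfigError(f"models: unknown model kind {model!r}")
    if cfg.occurrences.source != "synthetic" and not cfg.occurrences.path:
        raise ConfigError("occurrences.path is required unless source is "
                          "'synthetic'")
    return cfg


def demo_config(seed: int = 0, output_dir: str = "out",
                n_presence: int | None = None, **overrides) -> RunConfig:
    """The 64x64 synthetic demonstration configuration."""
    cfg = RunConfig(seed=seed, output_dir=output_dir, **overrides)
    if n_presence is not None:
        cfg.occurrences.n_presence = {syn.TICINO: n_presence,
                                      syn.APENNINE: n_presence}
    return cfg


# ---------------------------------------------------------------------------
# Occurrence import
# ---------------------------------------------------------------------------

_XLSX_COLMAP = {
    "x": "x", "longitude": "x", "east": "x", "x_coord": "x",
    "y": "y", "latitude": "y", "north": "y", "y_coord": "y",
    "area": "study_area", "study_area": "study_area",
    "label": "label", "presence": "label", "type": "label",
}


def _normalise_label(value, row: int) -> str:
    if isinstance(value, str):
        v = value.strip().lower().replace("-", "_").replace(" ", "_")
        if v in (syn.PRESENCE, syn.PSEUDO_ABSENCE):
            return v
    if value in (1, 1.0, True):
        return syn.PRESENCE
    if value in (0, 0.0, False):
        return syn.PSEUDO_ABSENCE
    raise ValueError(f"row {row}: unknown occurrence label {value!r}")


def import_occurrences(path: str | Path,
                       fmt: str | None = None) -> syn.OccurrenceSet:
    """Read an occurrence table from CSV (columns x, y, study_area, label) or
    from a supplementary-data-style XLSX sheet whose headers are sniffed
    (coordinate, area and presence-flag columns must be recognisable; the
    importer fails loudly rather than guessing)."""
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown occurrence format {fmt!r}")
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower().replace(" ", "_")
        if key in _XLSX_COLMAP:
            rename[col] = _XLSX_COLMAP[key]
    df = df.rename(columns=rename)
    missing = {"x", "y", "study_area", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: could not identify columns "
                         f"{sorted(missing)} (found {list(df.columns)})")
    if df[["x", "y"]].isna().any().any():
        bad = int(df[["x", "y"]].isna().any(axis=1).idxmax())
        raise ValueError(f"row {bad}: missing coordinates")
    df["label"] = [_normalise_label(v, i) for i, v in enumerate(df["label"])]
    occ = syn.OccurrenceSet(df[["x", "y", "study_area", "label"]])
    for area, counts in occ.counts().iterrows():
        log.info("imported %s: %s", area, counts.to_dict())
    return occ


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: dict[str, int]
    checksums: dict[str, str] = dc_field(default_factory=dict)
    eval_records: list[dict] = dc_field(default_factory=list)
    summary: dict[str, float] = dc_field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         sort_keys=True))


def _spawn_seeds(root_seed: int) -> dict[str, int]:
    names = ("landscape", "presence", "pseudo_absence", "splits",
             "importance")
    children = np.random.SeedSequence(root_seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, stop_after: str = "connect") -> RunManifest:
    """Execute the full analysis chain and write artifacts + manifest.

    ``stop_after`` in {"simulate", "fit", "project", "connect"} truncates the
    chain after that stage (used by the per-stage CLI subcommands).
    """
    order = ["simulate", "fit", "project", "connect"]
    if stop_after not in order:
        raise ConfigError(f"unknown stage {stop_after!r}")
    last = order.index(stop_after)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed)
    canon = json.dumps(config.model_dump(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(canon.encode()).hexdigest(),
        version=__version__, seeds=seeds)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        p = outdir / name
        writer(p)
        written.append(p)
        return p

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        ls = config.landscape
        lcfg = syn.LandscapeConfig(
            width_cells=ls.width_cells, height_cells=ls.height_cells,
            cell_size_m=ls.cell_size_m,
            patch_scale_cells=ls.patch_scale_cells,
            river_count=ls.river_count, seed=seeds["landscape"])
        if ls.raster_path:
            from .rasters import read_landcover
            landcover = read_landcover(ls.raster_path)
        else:
            landcover = syn.generate_landscape(lcfg)
        s_masks = syn.stratum_masks(lcfg)
        a_masks = syn.subarea_masks(lcfg)
        vs_base = syn.VirtualSpeciesConfig(
            buffer_radius_m=config.covariates.buffer_radius_m)
        if config.occurrences.source == "synthetic":
            parts = []
            for i, (area, n) in enumerate(
                    sorted(config.occurrences.n_presence.items())):
                vs = syn.VirtualSpeciesConfig(
                    beta0=vs_base.beta0, betas=vs_base.betas,
                    buffer_radius_m=vs_base.buffer_radius_m, n_presence=n,
                    seed=seeds["presence"] + i)
                parts.append(syn.sample_virtual_occurrences(
                    landcover, vs, a_masks[area], area_name=area))
            occurrences = syn.OccurrenceSet.concat(parts)
        else:
            occurrences = import_occurrences(config.occurrences.path,
                                             config.occurrences.source)
        pa_parts = []
        for i, (area, n) in enumerate(sorted(config.pseudo_absences.items())):
            pa_parts.append(syn.generate_pseudo_absences(
                a_masks[area], n, seeds["pseudo_absence"] + i,
                landcover.geometry, area_name=area))
        occurrences = syn.OccurrenceSet.concat([occurrences] + pa_parts)
        log.info("simulate: %d occurrence records", len(occurrences))
        emit("landcover.asc", lambda p: write_landcover(landcover, p))
        emit("occurrences.csv", occurrences.to_csv)
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    if last < 1:
        return _finish(manifest, written, outdir)

    # --- fit ----------------------------------------------------------
    stage = "fit"
    areas = sorted(config.occurrences.n_presence)
    ensembles: dict[str, sdm.EnsembleModel] = {}
    try:
        eval_rows = []
        for area in areas:
            classes = cov.area_classes(area, lcfg.exclusive_classes)
            sel = occurrences.records["study_area"] == area
            occ_area = syn.OccurrenceSet(occurrences.records[sel])
            table = cov.build_covariate_table(
                landcover, occ_area, config.covariates.buffer_radius_m,
                classes)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = cov.collinearity_screen(
                    table, config.covariates.collinearity_threshold)
            if report.zero_variance:
                log.info("fit %s: dropping zero-variance covariates %s",
                         area, report.zero_variance)
                table = table.drop(columns=report.zero_variance)
            for _, row in report.flagged.iterrows():
                log.info("collinearity %s: %s ~ %s r=%.3f", area,
                         row["class_a"], row["class_b"], row["pearson_r"])
            emit(f"collinearity_{area}.csv", report.to_csv)
            emit(f"covariates_{area}.csv",
                 lambda p, t=table: t.to_csv(p, index=False))
            ens = sdm.build_ensemble(
                table, kinds=tuple(config.models),
                train_fraction=config.cv.train_fraction,
                n_reps=config.cv.n_reps, seed=seeds["splits"],
                gbm_params=config.gbm.model_dump(),
                maxent_params=config.maxent.model_dump())
            ensembles[area] = ens
            for rec in ens.eval_records:
                log.debug("eval %s %s rep %d: auc=%.3f tss=%.3f", area,
                          rec.kind, rec.replicate, rec.auc, rec.tss)
                eval_rows.append({"study_area": area, "model": rec.kind,
                                  "replicate": rec.replicate,
                                  "auc": rec.auc, "tss": rec.tss})
            # ensemble CV metric: members refitted per split, weighted by
            # their own test AUC, scored on the held-out rows
            for rep in range(config.cv.n_reps):
                recs = [r for r in ens.eval_records if r.replicate == rep]
                test = recs[0].test_ids
                w = np.array([r.auc for r in recs])
                if w.sum() > 0:
                    w = w / w.sum()
                    scores = sum(
                        wi * m.predict(table.iloc[test])
                        for wi, m in zip(w, ens.members))
                    y = table.iloc[test]["label"]
                    eval_rows.append({
                        "study_area": area, "model": "ensemble",
                        "replicate": rep,
                        "auc": sdm.evaluate_auc(scores, y),
                        "tss": sdm.evaluate_tss(scores, y)})
            imp_frames = []
            for member in ens.members:
                imp = sdm.variable_importance(member, table,
                                              seed=seeds["importance"])
                imp["model"] = member.kind
                imp_frames.append(imp)
            imp = sdm.variable_importance(ens, table,
                                          seed=seeds["importance"])
            imp["model"] = "ensemble"
            imp_frames.append(imp)
            emit(f"importance_{area}.csv",
                 lambda p, f=imp_frames: pd.concat(f, ignore_index=True)
                 .to_csv(p, index=False))
        evals = pd.DataFrame(eval_rows)
        manifest.eval_records = eval_rows
        emit("evaluation.csv", lambda p: evals.to_csv(p, index=False))
        for area in areas:
            mean_auc = evals[(evals["study_area"] == area)
                             & (evals["model"] == "ensemble")]["auc"].mean()
            manifest.summary[f"ensemble_auc_{area}"] = float(mean_auc)
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    if last < 2:
        return _finish(manifest, written, outdir)

    # --- project -------------------------------------------------------
    stage = "project"
    try:
        excl_by_area = {a: [c for c, owner in lcfg.exclusive_classes.items()
                            if owner != a] for a in areas}
        maps = {}
        for area in areas:
            m = suit_ops.project(ensembles[area], landcover,
                                 config.covariates.buffer_radius_m,
                                 provenance=area)
            m = suit_ops.mask_exclusive_covers(m, landcover,
                                               excl_by_area[area])
            maps[area] = m
            emit(f"suitability_{area}.asc",
                 lambda p, mm=m: write_ascii_grid(p, mm.grid, mm.geometry))
            manifest.summary[f"suitable_fraction_{area}_pct"] = \
                suit_ops.suitable_fraction(suit_ops.normalize(m))
        merged = maps[areas[0]]
        for area in areas[1:]:
            merged = suit_ops.merge_max(merged, maps[area])
        integrated = suit_ops.normalize(merged)
        emit("suitability_integrated.asc",
             lambda p: write_ascii_grid(p, integrated.grid,
                                        integrated.geometry))
        manifest.summary["suitable_fraction_integrated_pct"] = \
            suit_ops.suitable_fraction(integrated)
        log.info("project: %.2f%% of the landscape above 0.5",
                 manifest.summary["suitable_fraction_integrated_pct"])
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    if last < 3:
        return _finish(manifest, written, outdir)

    # --- connect -------------------------------------------------------
    stage = "connect"
    try:
        res = conn.suitability_to_resistance(
            integrated, conn.ResistanceParams(r_max=config.resistance.r_max))
        emit("resistance.asc",
             lambda p: write_ascii_grid(p, res.grid, res.geometry))
        sources = conn.select_sources(
            integrated, grid_size_m=config.sources.grid_size_m,
            threshold=config.sources.suitability_threshold,
            strata_masks=s_masks,
            rarefy_stratum=config.sources.rarefy_stratum,
            rarefy_dist_m=config.sources.rarefy_dist_m)
        log.info("connect: %d source locations", len(sources))
        manifest.summary["n_sources"] = float(len(sources))
        emit("sources.csv", sources.to_csv)
        emit("sources_unicor.xy", sources.to_unicor_xy)
        for sc in config.scenarios:
            scenario = conn.DispersalScenario(sc.name, sc.threshold_km)
            density, skipped = conn.factorial_lcp(res, sources, scenario)
            kernel = conn.resistant_kernel(res, sources, scenario)
            log.info("connect[%s]: %d pairs skipped", sc.name, len(skipped))
            emit(f"density_lcp_{sc.name}.asc",
                 lambda p, d=density: write_ascii_grid(p, d.grid, d.geometry))
            emit(f"kernel_{sc.name}.asc",
                 lambda p, k=kernel: write_ascii_grid(p, k.grid, k.geometry))
            emit(f"skipped_pairs_{sc.name}.csv",
                 lambda p, s=skipped: s.to_csv(p, index=False))
            manifest.summary[f"movement_extent_{sc.name}_pct"] = \
                conn.connectivity_extent(density)
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    return _finish(manifest, written, outdir)


def _finish(manifest: RunManifest, written: list[Path],
            outdir: Path) -> RunManifest:
    for p in written:
        manifest.checksums[p.name] = _sha256(p)
        side = p.with_suffix(p.suffix + ".classes.json")
        if side.exists():
            manifest.checksums[side.name] = _sha256(side)
    manifest.to_json(outdir / "manifest.json")
    return manifest
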