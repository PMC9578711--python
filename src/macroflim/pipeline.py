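"""Configuration-driven orchestration of the full analysis.

Stages (synthetic mode): simulate -> fit (full FoV) -> phasor ->
segment/per-cell features -> classify (full-FoV OOB model + per-donor
single-cell models) [-> flux if a flux table is supplied]. Stage outputs
are materialised to disk between stages (TIFF/CSV/JSON) so partial
reruns and audits are possible; the run is end-to-end deterministic
given the configured seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classification import (
    RFSearchGrid,
    build_feature_table,
    run_donor_models,
    train_rf_oob_grid,
    umap_embed,
)
from .core import AcquisitionParams
from .decay_fitting import FitOptions, fit_field
from .errors import ConfigError
from .flux_metrics import FluxSeries, compute_flux_rates
from .io import field_stem, load_field, save_field
from .phasor import chord_fraction, phasor_transform
from .decay_fitting import DecayHistogram, photon_mask
from .segmentation import SegmentationOptions, aggregate_cell_features, segment_cells
from .synthetic_data import CohortConfig, iter_cohort

logger = logging.getLogger(__name__)

_COHORT_KEYS = {
    "n_donors",
    "phenotypes",
    "treatments",
    "fields_per_condition",
    "cells_per_field",
    "cell_radius",
    "photons_per_cell",
    "background_c",
    "fad_background",
    "image_size",
    "n_bins",
}
_FIT_KEYS = {"min_photons", "method", "fix_background"}
_SEG_KEYS = {"sigma", "method", "threshold", "min_area", "clear_border", "watershed"}
_GRID_KEYS = {"ntree_candidates", "mtry_candidates", "max_terminal_nodes"}
_CLASSIFY_KEYS = {"treatment", "umap", "donor_models", "train_fraction"}
_TOP_KEYS = {
    "mode",
    "seed",
    "out_dir",
    "cohort",
    "fit",
    "segmentation",
    "grid",
    "classify",
    "feature_csv",
    "fields_dir",
    "flux_csv",
    "flux_schedule",
}


@dataclass(frozen=True)
class PipelineConfig:
    mode: str
    seed: int
    out_dir: str
    cohort: CohortConfig | None
    fit: FitOptions
    segmentation: SegmentationOptions
    grid: RFSearchGrid
    classify: dict
    feature_csv: str | None = None
    fields_dir: str | None = None
    flux_csv: str | None = None
    flux_schedule: tuple | None = None
    raw: dict = field(default_factory=dict)


def _check_keys(section: dict, allowed: set, where: str):
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def validate_config(document) -> PipelineConfig:
    """Type-check and default a config document (dict, or YAML/JSON path).

    Exactly one input mode must be active and a seed is mandatory for
    every stochastic stage; unknown keys are rejected by name.
    """
    if isinstance(document, (str, Path)):
        document = yaml.safe_load(Path(document).read_text())
    if not isinstance(document, dict):
        raise ConfigError("config document must be a mapping")
    _check_keys(document, _TOP_KEYS, "top level")

    mode = document.get("mode", "synthetic")
    if mode not in ("synthetic", "feature_csv", "field_tiffs"):
        raise ConfigError(f"unknown mode {mode!r}")
    mode_inputs = [
        m
        for m, key in (
            ("feature_csv", "feature_csv"),
            ("field_tiffs", "fields_dir"),
        )
        if document.get(key)
    ]
    if mode == "synthetic" and mode_inputs:
        raise ConfigError(
            f"mode 'synthetic' conflicts with input keys for {mode_inputs}"
        )
    if mode == "feature_csv" and ("fields_dir" in document or not document.get("feature_csv")):
        raise ConfigError("feature_csv mode requires feature_csv and no fields_dir")
    if mode == "field_tiffs" and ("feature_csv" in document or not document.get("fields_dir")):
        raise ConfigError("field_tiffs mode requires fields_dir and no feature_csv")

    if "seed" not in document:
        raise ConfigError(
            "missing seed: the simulate and classify stages are stochastic"
        )
    seed = int(document["seed"])

    cohort_doc = dict(document.get("cohort", {}))
    _check_keys(cohort_doc, _COHORT_KEYS, "cohort")
    cohort = None
    if mode == "synthetic":
        acq_kwargs = {}
        if "image_size" in cohort_doc:
            acq_kwargs["image_size"] = int(cohort_doc.pop("image_size"))
        if "n_bins" in cohort_doc:
            acq_kwargs["n_bins"] = int(cohort_doc.pop("n_bins"))
        if "phenotypes" in cohort_doc:
            cohort_doc["phenotypes"] = tuple(cohort_doc["phenotypes"])
        if "treatments" in cohort_doc:
            cohort_doc["treatments"] = tuple(cohort_doc["treatments"])
        acq = AcquisitionParams(image_size=acq_kwargs.get("image_size", 128),
                                n_bins=acq_kwargs.get("n_bins", 256))
        cohort = CohortConfig(seed=seed, acq=acq, **cohort_doc)

    fit_doc = dict(document.get("fit", {}))
    _check_keys(fit_doc, _FIT_KEYS, "fit")
    seg_doc = dict(document.get("segmentation", {}))
    _check_keys(seg_doc, _SEG_KEYS, "segmentation")
    grid_doc = dict(document.get("grid", {}))
    _check_keys(grid_doc, _GRID_KEYS, "grid")
    if "ntree_candidates" in grid_doc:
        grid_doc["ntree_candidates"] = tuple(grid_doc["ntree_candidates"])
    if grid_doc.get("mtry_candidates") is not None:
        grid_doc["mtry_candidates"] = tuple(grid_doc["mtry_candidates"])
    classify_doc = dict(document.get("classify", {}))
    _check_keys(classify_doc, _CLASSIFY_KEYS, "classify")
    classify = dict(
        treatment="FCCP", umap=False, donor_models=True, train_fraction=0.75
    )
    classify.update(classify_doc)

    return PipelineConfig(
        mode=mode,
        seed=seed,
        out_dir=str(document.get("out_dir", "macroflim_run")),
        cohort=cohort,
        fit=FitOptions(**fit_doc),
        segmentation=SegmentationOptions(**seg_doc),
        grid=RFSearchGrid(**grid_doc),
        classify=classify,
        feature_csv=document.get("feature_csv"),
        fields_dir=document.get("fields_dir"),
        flux_csv=document.get("flux_csv"),
        flux_schedule=tuple(document["flux_schedule"]) if "flux_schedule" in document else None,
        raw=dict(document),
    )


@dataclass
class RunReport:
    counts: dict
    failures: dict
    reports: dict
    manifest: dict
    config_echo: dict
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(
            dict(
                counts=self.counts,
                failures=self.failures,
                reports=self.reports,
                manifest=self.manifest,
                config=self.config_echo,
                version=self.version,
            ),
            indent=1,
            default=str,
        )


def _field_rows(stack, cfg: PipelineConfig):
    """Full-FoV fit row and per-cell feature rows for one field."""
    cond = stack.condition
    fov = fit_field(stack, mode="full_fov", options=cfg.fit)
    fov.insert(0, "donor", cond.donor)
    fov.insert(1, "phenotype", cond.phenotype)
    fov.insert(2, "treatment", cond.treatment)
    fov.insert(3, "field_id", cond.field)
    fov = fov.rename(columns={"unit_id": "cell_id"})
    fov["cell_id"] = -1  # full-FoV marker

    lm = segment_cells(stack.nadh_histograms.sum(axis=2), cfg.segmentation)
    cells = aggregate_cell_features(lm, stack, fit_options=cfg.fit)

    mask = photon_mask(stack.nadh_histograms.sum(axis=2), method="otsu")
    agg = stack.nadh_histograms[mask].sum(axis=0)
    point = phasor_transform(
        DecayHistogram(agg, stack.acq.bin_width_ns), stack.acq
    )
    phasor_row = dict(
        donor=cond.donor,
        phenotype=cond.phenotype,
        treatment=cond.treatment,
        field_id=cond.field,
        g=point.g,
        s=point.s,
        chord_fraction=chord_fraction(point, stack.acq),
    )
    return fov, cells, phasor_row, lm


def default_stages(config: PipelineConfig) -> tuple:
    if config.mode == "synthetic":
        stages = ("simulate", "features", "classify")
    elif config.mode == "field_tiffs":
        stages = ("features", "classify")
    else:
        stages = ("classify",)
    if config.flux_csv:
        stages = stages + ("flux",)
    return stages


def run_pipeline(config: PipelineConfig, stages=None) -> RunReport:
    """Execute the configured stages in order and write all artefacts.

    stages defaults to everything the input mode supports; a subset (in
    pipeline order) reruns from the materialised intermediate files of a
    previous run in the same output directory.
    """
    t_start = time.time()
    stages = tuple(stages) if stages is not None else default_stages(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, failures, reports, manifest = {}, {}, {}, {}
    field_dir = out / "fields"
    fov_features = cell_features = None

    if "simulate" in stages:
        if config.mode != "synthetic":
            raise ConfigError("simulate stage requires synthetic mode")
        n_fields = 0
        for stack in iter_cohort(config.cohort):
            manifest[field_stem(stack.condition)] = save_field(stack, field_dir)
            n_fields += 1
        counts["fields_simulated"] = n_fields
        logger.info("simulate: wrote %d fields to %s", n_fields, field_dir)

    if "features" in stages:
        src_dir = field_dir if config.mode == "synthetic" else Path(config.fields_dir)
        sidecars = sorted(src_dir.glob("*.json"))
        fov_rows, cell_rows, phasor_rows = [], [], []
        for p in sidecars:
            stack = load_field(p)
            fov, cells, phasor_row, _ = _field_rows(stack, config)
            fov_rows.append(fov)
            cell_rows.append(cells)
            phasor_rows.append(phasor_row)
            logger.info(
                "field %s: %d cells, %d good fits",
                field_stem(stack.condition),
                len(cells),
                int(cells["good"].sum()) if len(cells) else 0,
            )
        fov_features = pd.concat(fov_rows, ignore_index=True)
        cell_features = (
            pd.concat(cell_rows, ignore_index=True) if cell_rows else pd.DataFrame()
        )
        phasors = pd.DataFrame(phasor_rows)
        fov_features.to_csv(out / "fullfov_features.csv", index=False)
        cell_features.to_csv(out / "cell_features.csv", index=False)
        phasors.to_csv(out / "phasors.csv", index=False)
        counts["fields"] = len(sidecars)
        counts["cells_segmented"] = int(len(cell_features))
        failures["cell_fit_failures"] = (
            int((~cell_features["good"].astype(bool)).sum())
            if len(cell_features)
            else 0
        )
        manifest["fullfov_features"] = str(out / "fullfov_features.csv")
        manifest["cell_features"] = str(out / "cell_features.csv")
        manifest["phasors"] = str(out / "phasors.csv")

    if "classify" in stages:
        if fov_features is None:
            source = (
                config.feature_csv
                if config.mode == "feature_csv"
                else out / "fullfov_features.csv"
            )
            fov_features = pd.read_csv(source)
            cell_path = out / "cell_features.csv"
            if config.mode != "feature_csv" and cell_path.exists():
                cell_features = pd.read_csv(cell_path)
            else:
                cell_features = pd.DataFrame()
        treatment = config.classify["treatment"]
        X, y, predictors, _ = build_feature_table(fov_features, treatment=treatment)
        _, fov_report = train_rf_oob_grid(
            X, y, config.grid, seed=config.seed, predictor_names=predictors
        )
        reports["full_fov"] = fov_report.to_dict()
        counts["fullfov_rows"] = int(len(y))

        if config.classify.get("umap"):
            coords = umap_embed(X, seed=config.seed)
            pd.DataFrame(
                dict(umap1=coords[:, 0], umap2=coords[:, 1], phenotype=y)
            ).to_csv(out / "umap_fullfov.csv", index=False)
            manifest["umap"] = str(out / "umap_fullfov.csv")

        if config.classify.get("donor_models") and len(cell_features):
            donor_reports = run_donor_models(
                cell_features,
                config.grid,
                seed=config.seed,
                train_fraction=config.classify["train_fraction"],
                treatment=treatment,
            )
            reports["donors"] = {d: r.to_dict() for d, r in donor_reports.items()}
            counts["donor_models"] = len(donor_reports)

    if "flux" in stages and config.flux_csv:
        flux_df = pd.read_csv(config.flux_csv)
        if config.flux_schedule is None:
            raise ConfigError("flux_csv requires flux_schedule")
        rate_rows = []
        for (group, rep), sub in flux_df.groupby(["group", "replicate"]):
            series = FluxSeries(
                times=sub["time_min"].to_numpy(),
                ecar=sub["ecar"].to_numpy(),
                ocr=sub["ocr"].to_numpy(),
                schedule=config.flux_schedule,
                replicate=int(rep),
                group=str(group),
            )
            rates = compute_flux_rates(series)
            rate_rows.append(
                dict(
                    group=group,
                    replicate=rep,
                    basal_glycolysis=rates.basal_glycolysis,
                    max_glycolysis=rates.max_glycolysis,
                    basal_respiration=rates.basal_respiration,
                    max_respiration=rates.max_respiration,
                )
            )
        pd.DataFrame(rate_rows).to_csv(out / "flux_rates.csv", index=False)
        manifest["flux_rates"] = str(out / "flux_rates.csv")
        counts["flux_replicates"] = len(rate_rows)

    report = RunReport(
        counts=counts,
        failures=failures,
        reports=reports,
        manifest=manifest,
        config_echo=config.raw,
    )
    (out / "run_report.json").write_text(report.to_json())
    logger.info("pipeline finished in %.1f s", time.time() - t_start)
    return report
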