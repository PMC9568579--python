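"""End-to-end pipeline orchestration.

One reproducible run: simulate (or ingest) a cohort -> extract robust
features from the original, eroded and dilated segmentations -> robustness
filter -> correlation clustering + representative selection -> CV profile
-> heterogeneity indexes -> subsampling simulation -> recovery curve ->
cohort statistics.  Every intermediate lands as CSV in the run directory
together with a JSON manifest (config, seed, package versions) and a log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .feature_selection import cluster_features, select_representatives
from .heterogeneity import META_COLUMNS, cohort_indexes, cv_profile
from .io import read_feature_table, write_feature_table
from .radiomics import extract_features
from .robustness import perturb_mask, robustness_filter
from .sampling import (
    min_lesions_for_recovery,
    recovery_curve,
    simulate_strategy,
    standard_strategies,
)
from .stats import cv_stats_report
from .synthetic import PatientCase, generate_cohort, preset_spec

logger = logging.getLogger("radhet")

#: Interpretability order used when picking one feature per cluster
#: (volume before advanced texture indices).
DEFAULT_PREFERENCE = (
    "shape_VoxelVolume",
    "shape_Sphericity",
    "shape_Maximum2DDiameterSlice",
    "firstorder_90Percentile",
)


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their standard defaults."""

    out_dir: str = "radhet_run"
    preset: str = "M-oligo"          # synthetic cohort preset, or use features_csv
    features_csv: str | None = None  # pre-extracted feature table (skips imaging)
    heterogeneity_level: float = 0.5
    target_spacing_mm: float = 1.0
    bin_width: float = 10.0
    perturb_radius_mm: float = 1.0
    ccc_threshold: float = 0.8
    n_clusters: int = 8
    n_sim: int = 500
    k_min: int = 2
    k_max: int = 15
    recovery_threshold_pct: float = 75.0
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config from a YAML key-value file mirroring these fields."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not 0.0 < self.ccc_threshold <= 1.0:
            raise ConfigurationError("ccc_threshold must be in (0, 1]")
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be positive")
        if self.n_sim < 2:
            raise ConfigurationError("n_sim must be >= 2")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ConfigurationError("need 2 <= k_min <= k_max")
        if not 0.0 <= self.recovery_threshold_pct <= 100.0:
            raise ConfigurationError("recovery threshold is a percentage")
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")


def extract_cohort_tables(patients: list[PatientCase], features="robust8",
                          bin_width: float = 10.0, perturb_radius_mm: float = 1.0,
                          target_mm: float = 1.0):
    """Feature tables for the original, eroded and dilated segmentations.

    Lesions whose mask vanishes under erosion are dropped from the eroded
    table only (the robustness filter excludes them pairwise).  Returns
    ``(orig, eroded, dilated, n_vanished)``.
    """
    rows_o, rows_e, rows_d = [], [], []
    n_vanished = 0
    for patient in patients:
        for lesion in patient.lesions:
            meta = {"patient_id": lesion.patient_id,
                    "lesion_id": lesion.lesion_id,
                    "site_label": lesion.site_label}
            already_iso = all(abs(s - target_mm) < 1e-12 for s in lesion.spacing)
            fv = extract_features(lesion.image, lesion.mask, lesion.spacing,
                                  features=features, bin_width=bin_width,
                                  resample=not already_iso, target_mm=target_mm)
            rows_o.append({**meta, **fv.values})
            for mode, rows in (("erode", rows_e), ("dilate", rows_d)):
                pm, vanished = perturb_mask(lesion.mask, perturb_radius_mm,
                                            mode, lesion.spacing)
                if vanished:
                    n_vanished += 1
                    continue
                fv_p = extract_features(lesion.image, pm, lesion.spacing,
                                        features=features, bin_width=bin_width,
                                        resample=not already_iso,
                                        target_mm=target_mm)
                rows.append({**meta, **fv_p.values})
    return (pd.DataFrame(rows_o), pd.DataFrame(rows_e), pd.DataFrame(rows_d),
            n_vanished)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory.

    Any stage error aborts with the stage name in the exception message;
    partial outputs written so far are left in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    timings: dict[str, float] = {}

    def tick(name):
        nonlocal stage
        timings[stage] = round(time.perf_counter() - tick.t0, 3)
        stage = name
        tick.t0 = time.perf_counter()
        logger.info("stage: %s", name)

    tick.t0 = time.perf_counter()
    try:
        tick("cohort")
        if config.features_csv:
            orig = read_feature_table(config.features_csv)
            eroded = dilated = None
            n_vanished = 0
        else:
            spec = preset_spec(config.preset, seed=config.seed,
                               heterogeneity_level=config.heterogeneity_level)
            patients = generate_cohort(spec)
            logger.info("generated %d patients, %d lesions", len(patients),
                        sum(len(p.lesions) for p in patients))
            tick("extract")
            orig, eroded, dilated, n_vanished = extract_cohort_tables(
                patients, bin_width=config.bin_width,
                perturb_radius_mm=config.perturb_radius_mm,
                target_mm=config.target_spacing_mm)
            logger.info("vanished under erosion: %d", n_vanished)
        write_feature_table(orig, out / "features.csv")

        tick("robustness")
        if eroded is not None:
            write_feature_table(eroded, out / "features_eroded.csv")
            write_feature_table(dilated, out / "features_dilated.csv")
            report = robustness_filter(orig, eroded, dilated,
                                       threshold=config.ccc_threshold)
            report.table.to_csv(out / "robustness.csv", index=False)
            kept = report.kept_features
            logger.info("kept %d/%d features", len(kept),
                        len(report.table))
        else:
            kept = [c for c in orig.columns if c not in META_COLUMNS]
        if not kept:
            raise ConfigurationError("no feature survived the robustness filter")
        kept_table = orig[META_COLUMNS + kept]

        tick("selection")
        k_eff = min(config.n_clusters, len(kept))
        clustering = cluster_features(kept_table, k=k_eff)
        selected = select_representatives(clustering, DEFAULT_PREFERENCE)
        (out / "selected_features.txt").write_text("\n".join(selected) + "\n")
        selected_table = orig[META_COLUMNS + selected]

        tick("cv_profile")
        profile = cv_profile(selected_table, group_by="patient")
        profile.per_feature.rename_axis("patient_id").to_csv(out / "cv_profile.csv")
        profile.pooled.rename("mean_cv_pct").rename_axis("patient_id") \
            .to_csv(out / "cv_pooled.csv")

        tick("indexes")
        cohort, per_patient = cohort_indexes(selected_table)
        idx_out = per_patient.rename_axis("patient_id").copy()
        idx_out.to_csv(out / "indexes.csv")

        tick("sampling")
        rng = np.random.default_rng(config.seed)
        sim_rows = []
        for strat in standard_strategies():
            res = simulate_strategy(selected_table, strat, n_sim=config.n_sim,
                                    rng=rng)
            sim_rows.append({"strategy": strat.label, **res.summary()})
        pd.DataFrame(sim_rows).to_csv(out / "sampling_recovery.csv", index=False)

        tick("recovery_curve")
        curve = recovery_curve(selected_table,
                               k_range=range(config.k_min, config.k_max + 1),
                               n_sim=config.n_sim, rng=rng)
        curve.as_frame().to_csv(out / "recovery_curve.csv", index=False)
        k_needed = min_lesions_for_recovery(curve, config.recovery_threshold_pct)

        tick("stats")
        stats = cv_stats_report(profile.per_feature, alpha=config.alpha)
        stats.table.to_csv(out / "stats.csv", index=False)

        tick("manifest")
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "n_vanished_under_erosion": n_vanished,
            "selected_features": selected,
            "cohort_mtd": cohort.mtd,
            "cohort_ath": cohort.ath,
            "min_lesions_for_recovery": k_needed,
            "alpha_corrected": stats.alpha_corrected,
            "stage_timings_s": timings,
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
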