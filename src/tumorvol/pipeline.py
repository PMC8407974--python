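"""End-to-end pipeline: simulate/load masks -> measure -> estimate -> evaluate.

Outputs, under the configured directory:

* ``cases.csv`` — one row per analyzable case (morphometry + six estimates);
* ``agreement_full.csv`` / ``agreement_full.json`` — per-method agreement
  statistics on the whole cohort;
* ``agreement_subset_<t>.csv`` — the same restricted to cases below each
  small-volume threshold (mL);
* ``diameter_groups.csv`` — volume distribution per 1-cm maximum-diameter bin;
* ``ellipsoidity_correlations.csv`` — ellipsoidity-vs-APVD Spearman r per method;
* ``manifest.json`` — config echo, seed, versions, case counts, exclusions.

Identical config + seed produce byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .agreement import (
    diameter_volume_analysis,
    ellipsoidity_error_correlation,
    evaluate_method,
    subset_evaluate,
)
from .errors import ConfigError, MaskError, NoValidCasesError, StatisticsError, TumorvolError
from .estimators import METHOD_NAMES, estimate_volumes
from .mask_io import load_mask, write_table
from .morphometry import morphometry
from .records import CohortRecord, records_to_frame
from .synthetic import CohortConfig, measure_cohort, sample_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_CSV_FLOAT = "%.6g"


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``masks_dir`` (measure real masks) or ``n_simulate``
    (generate a synthetic cohort) must be set.
    """

    out_dir: str
    masks_dir: str | None = None
    n_simulate: int | None = None
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    subset_thresholds: tuple[float, ...] = (10.0, 20.0)
    apvd_thresholds: tuple[float, ...] = (10.0, 20.0, 30.0)
    mvee_tolerance: float = 1e-6
    slice_filter: bool = False  # apply the min-slice filter to measured masks too

    def validate(self) -> None:
        if (self.masks_dir is None) == (self.n_simulate is None):
            raise ConfigError("exactly one of 'masks_dir' or 'n_simulate' must be set")
        for name in ("subset_thresholds", "apvd_thresholds"):
            vals = getattr(self, name)
            if any(t <= 0 for t in vals):
                raise ConfigError(f"{name}: thresholds must be strictly positive, got {vals}")
            if list(vals) != sorted(vals):
                raise ConfigError(f"{name}: thresholds must be sorted ascending, got {vals}")
        if self.mvee_tolerance <= 0:
            raise ConfigError(f"mvee_tolerance: must be positive, got {self.mvee_tolerance}")
        if self.n_simulate is not None and self.n_simulate < 4:
            raise ConfigError("n_simulate: agreement analysis needs at least 4 cases")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cohort_raw = raw.pop("cohort", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("subset_thresholds", "apvd_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if cohort_raw is not None:
            for key in ("spacing", "volume_iqr_ml", "axis_ratio_range",
                        "n_lobes_range", "lobe_scale_range"):
                if key in cohort_raw:
                    cohort_raw[key] = tuple(cohort_raw[key])
            raw["cohort"] = CohortConfig(**cohort_raw)
        return cls(**raw)


@dataclass(frozen=True)
class PipelineResult:
    out_dir: Path
    records: list[CohortRecord]
    exclusions: list[dict]
    manifest: dict


def _collect_records(config: PipelineConfig) -> tuple[list[CohortRecord], list[dict]]:
    exclusions: list[dict] = []
    if config.n_simulate is not None:
        cohort = sample_cohort(config.n_simulate, config.cohort, seed=config.seed)
        return measure_cohort(cohort, mvee_tolerance=config.mvee_tolerance), exclusions
    masks_dir = Path(config.masks_dir)  # type: ignore[arg-type]
    paths = sorted(
        p for p in masks_dir.iterdir() if p.name.endswith((".nii", ".nii.gz"))
    )
    records = []
    for path in paths:
        try:
            mask = load_mask(path)
            if config.slice_filter:
                n_slices = int(mask.voxels.any(axis=(1, 2)).sum())
                if n_slices < config.cohort.min_slices:
                    raise MaskError(
                        f"only {n_slices} tumor-bearing slices "
                        f"(< {config.cohort.min_slices})"
                    )
            m = morphometry(mask, mvee_tolerance=config.mvee_tolerance)
            est = estimate_volumes(m.a, m.b, m.s, m.h)
            records.append(CohortRecord(case_id=mask.case_id, morphometry=m, estimates=est))
        except TumorvolError as exc:
            log.warning("excluding %s: %s", path.name, exc)
            exclusions.append({"file": path.name, "reason": str(exc)})
    return records, exclusions


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full volumetry evaluation and write all reports."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, exclusions = _collect_records(config)
    if not records:
        raise NoValidCasesError("no valid cases to analyze")
    write_table(records, out / "cases.csv")
    frame = records_to_frame(records)

    # per-method agreement, full cohort and small-volume subsets
    full_rows = []
    for m in METHOD_NAMES:
        try:
            full_rows.append(evaluate_method(frame, m, config.apvd_thresholds).as_row())
        except StatisticsError as exc:
            log.warning("full-cohort agreement for %s unavailable: %s", m, exc)
    pd.DataFrame(full_rows).to_csv(out / "agreement_full.csv", index=False,
                                   float_format=_CSV_FLOAT)
    with open(out / "agreement_full.json", "w") as fh:
        json.dump(full_rows, fh, indent=2)
    for t in config.subset_thresholds:
        rows = []
        for m in METHOD_NAMES:
            try:
                rows.append(subset_evaluate(frame, m, t, config.apvd_thresholds).as_row())
            except StatisticsError as exc:
                log.warning("subset <%g mL, method %s: %s", t, m, exc)
        if rows:
            pd.DataFrame(rows).to_csv(
                out / f"agreement_subset_{t:g}.csv", index=False, float_format=_CSV_FLOAT
            )

    groups, diam_rs = diameter_volume_analysis(frame)
    groups.to_csv(out / "diameter_groups.csv", index=False, float_format=_CSV_FLOAT)

    ell_rows = []
    for m in METHOD_NAMES:
        try:
            rs, lo, hi = ellipsoidity_error_correlation(frame, m)
            ell_rows.append({"method": m, "rs": rs, "rs_ci_low": lo, "rs_ci_high": hi})
        except StatisticsError as exc:
            log.warning("ellipsoidity correlation for %s unavailable: %s", m, exc)
            ell_rows.append({"method": m, "rs": float("nan"),
                             "rs_ci_low": float("nan"), "rs_ci_high": float("nan")})
    pd.DataFrame(ell_rows).to_csv(out / "ellipsoidity_correlations.csv", index=False,
                                  float_format=_CSV_FLOAT)

    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "versions": {
            "tumorvol": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "n_input": len(records) + len(exclusions),
        "n_cases": len(records),
        "exclusions": exclusions,
        "diameter_volume_rs": diam_rs[0],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(out_dir=out, records=records, exclusions=exclusions,
                          manifest=manifest)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=list))
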