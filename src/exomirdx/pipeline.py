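"""End-to-end orchestration: simulate/load → preprocess → stats →
thresholds → scoring → ROC → report.

All tunable constants default to the study's printed values: censor ceiling
35 cycles, sentinel 36, detection limit 40 cycles, target volume 750 µL,
detectability cutoff 80%, CI level 99%, CA19-9 cutoff 37 U/mL, call cutoff
"at least one hit". A report is written as plain CSV/JSON tables; the
logged censoring counts, dropped samples, and filtered miRNAs are the audit
trail for the narrative numbers (e.g. how many candidates were excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, UndefinedMetricError
from . import group_stats, preprocess, roc as roc_mod, scoring
from .preprocess import DeltaCqMatrix
from .scoring import ConfusionMetrics, ThresholdSet
from .simulate import DEFAULT_PANEL, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

THRESHOLD_MODES = ("control_upper", "pdac_lower", "combined")


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the study's constants."""

    raw_cq_csv: str | None = None
    metadata_csv: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    panel: list[str] = field(default_factory=lambda: list(DEFAULT_PANEL))
    threshold_mode: Literal["control_upper", "pdac_lower", "combined"] = "combined"
    call_cutoff: int = 1
    ttest_variant: Literal["student", "welch"] = "student"
    ci_level: float = 0.99
    max_nondetect_fraction: float = 0.80
    censor_ceiling: float = 35.0
    censor_sentinel: float = 36.0
    target_volume_ul: float = 750.0
    ca199_cutoff: float = 37.0
    roc_method: Literal["bootstrap", "delong"] = "bootstrap"
    roc_n_boot: int = 2000
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and not isinstance(d["cohort"], CohortConfig):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All pipeline outputs plus provenance, ready to serialize."""

    raw_cq: pd.DataFrame
    metadata: pd.DataFrame
    delta_matrix: DeltaCqMatrix
    summaries: pd.DataFrame
    tests: pd.DataFrame
    stage_tests: pd.DataFrame
    demographics: pd.DataFrame
    thresholds: ThresholdSet
    hit_matrices: dict[str, pd.DataFrame]
    confusion: dict[str, ConfusionMetrics | None]
    roc_results: dict[str, roc_mod.RocResult | None]
    provenance: dict


def _package_version() -> str:
    try:
        return _pkg_version("exomirdx")
    except PackageNotFoundError:
        return "unknown"


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in fixed order; idempotent for fixed config+seed."""
    # 1. inputs
    if config.raw_cq_csv and config.metadata_csv:
        logger.info("loading raw Cq table from %s", config.raw_cq_csv)
        raw = pd.read_csv(config.raw_cq_csv)
        metadata = pd.read_csv(config.metadata_csv).fillna({"stage": "", "stage_bucket": ""})
    else:
        cohort = CohortConfig.from_dict({**config.cohort.to_dict(), "seed": config.seed})
        logger.info("simulating cohort (seed=%d)", config.seed)
        raw, metadata = generate_cohort(cohort)

    # 2. preprocessing
    matrix = preprocess.preprocess_cohort(
        raw,
        max_nondetect_fraction=config.max_nondetect_fraction,
        ceiling=config.censor_ceiling,
        sentinel=config.censor_sentinel,
        target_volume=config.target_volume_ul,
    )

    meta = metadata.set_index("sample_id").loc[matrix.samples]
    truth = (meta["group"] == "pdac").to_numpy()
    has_both_groups = truth.any() and not truth.all()

    # 3. group statistics
    summaries = group_stats.group_summaries(matrix, metadata, config.ci_level)
    if has_both_groups:
        tests = group_stats.differential_tests(matrix, metadata, config.ttest_variant)
        stage_tests = group_stats.stage_stratified_tests(
            matrix, metadata, config.ttest_variant
        )
    else:
        logger.warning("single-group input: differential tests skipped")
        tests = pd.DataFrame()
        stage_tests = pd.DataFrame()
    demo_rows = []
    for var in ("sex", "ethnicity", "age"):
        try:
            r = group_stats.chi_squared_demographics(metadata, var)
            demo_rows.append(
                {"variable": var, "test": "chi2", "statistic": r.statistic,
                 "p_value": r.p_value, "df": r.df}
            )
        except UndefinedMetricError as exc:
            logger.warning("demographics test on %r skipped: %s", var, exc)
    if has_both_groups:
        r = group_stats.age_ttest(metadata, config.ttest_variant)
        demo_rows.append(
            {"variable": "age", "test": "t", "statistic": r.statistic,
             "p_value": r.p_value, "df": r.df}
        )
    demographics = pd.DataFrame(demo_rows)

    # 4. thresholds (derived on the same cohort they are applied to)
    if not has_both_groups:
        raise ConfigurationError(
            "threshold derivation requires both control and PDAC samples"
        )
    ctrl_slice = matrix.values.loc[meta.index[meta["group"] == "control"]]
    pdac_slice = matrix.values.loc[meta.index[meta["group"] == "pdac"]]
    thresholds = scoring.derive_thresholds(
        ctrl_slice, pdac_slice, config.panel, config.threshold_mode, config.ci_level
    )

    # 5./6. scoring, confusion, and ROC per threshold mode
    ca199 = meta["ca199_u_ml"] if "ca199_u_ml" in meta.columns else None
    hit_matrices: dict[str, pd.DataFrame] = {}
    confusion: dict[str, ConfusionMetrics | None] = {}
    roc_results: dict[str, roc_mod.RocResult | None] = {}
    for i, mode in enumerate(THRESHOLD_MODES):
        ts = thresholds.with_mode(mode)
        hm = scoring.score_matrix(
            matrix.values, ts, config.call_cutoff, ca199, config.ca199_cutoff
        )
        hit_matrices[mode] = hm
        try:
            confusion[mode] = scoring.confusion_metrics(hm["call"], truth)
        except UndefinedMetricError as exc:
            logger.warning("confusion metrics undefined in mode %s: %s", mode, exc)
            confusion[mode] = None
        try:
            roc_results[mode] = roc_mod.analyze_scores(
                hm["total_score"], truth,
                method=config.roc_method, level=config.ci_level,
                n_boot=config.roc_n_boot,
                seed=(config.seed * 7 + i) % (2**31),
            )
        except UndefinedMetricError as exc:
            logger.warning("ROC undefined in mode %s: %s", mode, exc)
            roc_results[mode] = None
    if ca199 is not None:
        try:
            confusion["ca199"] = scoring.confusion_metrics(
                hit_matrices["combined"]["ca199_call"], truth
            )
        except UndefinedMetricError:
            confusion["ca199"] = None

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "exomirdx": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_samples": len(matrix.samples),
        "dropped_samples": matrix.dropped_samples,
        "retained_mirnas": matrix.retained_mirnas,
    }
    return RunReport(
        raw_cq=raw, metadata=metadata, delta_matrix=matrix,
        summaries=summaries, tests=tests, stage_tests=stage_tests,
        demographics=demographics, thresholds=thresholds,
        hit_matrices=hit_matrices, confusion=confusion,
        roc_results=roc_results, provenance=provenance,
    )


def export_hit_heatmap_table(
    hit_matrix: pd.DataFrame, panel: Sequence[str]
) -> pd.DataFrame:
    """Long-format per-sample × per-miRNA hit table for heatmap plotting."""
    panel = list(panel)
    if not panel:
        raise ConfigurationError("panel is empty")
    missing = [m for m in panel if m not in hit_matrix.columns]
    if missing:
        raise ConfigurationError(f"hit matrix lacks panel columns: {missing}")
    rows = []
    for sid, row in hit_matrix.iterrows():
        for mid in panel:
            rows.append(
                {
                    "sample_id": sid,
                    "mirna_id": mid,
                    "hit_count": int(row[mid]),
                    "call": bool(row["call"]),
                    "ca199_u_ml": row.get("ca199_u_ml", np.nan),
                    "ca199_call": row.get("ca199_call", None),
                }
            )
    return pd.DataFrame(rows)


def write_report(report: RunReport, outdir: str | Path) -> Path:
    """Serialize a run to CSV/JSON files under ``outdir``; returns the dir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.raw_cq.to_csv(out / "raw_cq.csv", index=False)
    report.metadata.to_csv(out / "metadata.csv", index=False)
    report.delta_matrix.values.to_csv(out / "delta_cq.csv")
    report.summaries.to_csv(out / "group_summaries.csv", index=False)
    report.tests.to_csv(out / "differential_tests.csv", index=False)
    report.stage_tests.to_csv(out / "stage_tests.csv", index=False)
    report.demographics.to_csv(out / "demographics_tests.csv", index=False)
    report.thresholds.save(out / "thresholds.json")
    for mode, hm in report.hit_matrices.items():
        hm.to_csv(out / f"hit_matrix_{mode}.csv")
    heat = export_hit_heatmap_table(
        report.hit_matrices["combined"], report.thresholds.panel
    )
    heat.to_csv(out / "hit_heatmap_long.csv", index=False)
    summary = {
        "provenance": report.provenance,
        "confusion": {
            k: (v.to_dict() if v is not None else None)
            for k, v in report.confusion.items()
        },
        "roc": {
            k: (
                {
                    "auc": v.auc,
                    "auc_ci99": list(v.auc_ci99),
                    "p_value_vs_chance": v.p_value_vs_chance,
                    "method": v.method,
                }
                if v is not None
                else None
            )
            for k, v in report.roc_results.items()
        },
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, default=str))
    for mode, res in report.roc_results.items():
        if res is not None:
            pd.DataFrame(res.points, columns=["fpr", "tpr"]).to_csv(
                out / f"roc_points_{mode}.csv", index=False
            )
    logger.info("report written to %s", out)
    return out
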