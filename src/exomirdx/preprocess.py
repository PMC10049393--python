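"""Raw Cq → ΔCq preprocessing.

Fixed order of operations per measurement: censor → volume-normalize →
replicate-average → per-sample reference → ΔCq. Censoring maps any Cq above
35 cycles, and any non-detect (no amplification within 40 cycles), to the
sentinel value 36; the sentinel encodes "absent" and is therefore never
volume-adjusted. Volume normalization rescales endogenous measurements to a
common 750 µL plasma input: Cq_norm = Cq_raw − log2(750 / volume). The
exogenous spike-in reference is added at fixed mass regardless of plasma
volume, so by default it is exempt from the volume step.

The detectability filter drops any candidate miRNA that is non-detected
(all replicates failed) in strictly more than ``max_nondetect_fraction``
of samples — the "not detectable in over 80% of the samples" exclusion —
and operates on raw detection flags, before censoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MissingDataError
from .simulate import ENDOGENOUS_REF_ID, MAX_CYCLES, REFERENCE_IDS, SPIKE_IN_ID

logger = logging.getLogger(__name__)

CENSOR_CEILING = 35.0
CENSOR_SENTINEL = 36.0
TARGET_VOLUME_UL = 750.0
MAX_NONDETECT_FRACTION = 0.80


def censor_cq(
    cq, ceiling: float = CENSOR_CEILING, sentinel: float = CENSOR_SENTINEL
):
    """Censor a Cq value (scalar or array); NaN encodes a non-detect.

    Detected values at or below ``ceiling`` pass through; values above it
    and non-detects become ``sentinel``. Idempotent as long as
    ``sentinel > ceiling`` (the default 36 > 35). Negative Cq is invalid.
    """
    arr = np.asarray(cq, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise InvalidParameterError("Cq values must be non-negative")
    out = np.where(np.isnan(arr) | (arr > ceiling), sentinel, arr)
    return float(out) if np.isscalar(cq) or arr.ndim == 0 else out


def normalize_volume(
    cq_raw, volume, target_volume: float = TARGET_VOLUME_UL
):
    """Adjust Cq to a common plasma input: ``cq_raw − log2(target/volume)``.

    Halving the input volume leaves half the template, i.e. one cycle more;
    normalization removes that offset.
    """
    vol = np.asarray(volume, dtype=float)
    if np.any(vol <= 0):
        raise InvalidParameterError("volume must be positive")
    out = np.asarray(cq_raw, dtype=float) - np.log2(target_volume / vol)
    return float(out) if out.ndim == 0 else out


def average_replicates(
    cqs: Sequence[float],
    volumes: Sequence[float] | None = None,
    ceiling: float = CENSOR_CEILING,
    sentinel: float = CENSOR_SENTINEL,
    target_volume: float = TARGET_VOLUME_UL,
) -> float:
    """Censored, volume-normalized arithmetic mean of technical replicates.

    ``cqs`` may contain NaN non-detects. If ``volumes`` is given, detected
    in-range replicates are volume-normalized before averaging; censored
    sentinels are never adjusted.
    """
    cqs = np.asarray(list(cqs), dtype=float)
    if cqs.size == 0:
        raise MissingDataError("no replicate measurements to average")
    detected = ~np.isnan(cqs) & (cqs <= ceiling)
    vals = censor_cq(cqs, ceiling=ceiling, sentinel=sentinel)
    if volumes is not None:
        vols = np.asarray(list(volumes), dtype=float)
        vals = np.where(
            detected, normalize_volume(vals, np.where(detected, vols, 1.0), target_volume), vals
        )
    return float(np.mean(vals))


def reference_value(cel_cq: float, mir16_cq: float) -> float:
    """Per-sample normalization reference: mean of the spike-in and the
    endogenous control Cq. Either missing → the sample cannot be normalized."""
    if cel_cq is None or mir16_cq is None or math.isnan(cel_cq) or math.isnan(mir16_cq):
        raise MissingDataError("reference miRNA not detected for sample")
    return (float(cel_cq) + float(mir16_cq)) / 2.0


def delta_cq(target_cq, reference):
    """ΔCq = target − reference; higher ΔCq = lower relative abundance."""
    out = np.asarray(target_cq, dtype=float) - np.asarray(reference, dtype=float)
    return float(out) if out.ndim == 0 else out


def detectability_filter(
    raw: pd.DataFrame,
    max_nondetect_fraction: float = MAX_NONDETECT_FRACTION,
    candidate_ids: Iterable[str] | None = None,
    max_cycles: float = MAX_CYCLES,
) -> list[str]:
    """Return candidate miRNA ids retained after the non-detection filter.

    A miRNA counts as non-detected in a sample when no replicate amplified
    within ``max_cycles``. It is excluded iff its non-detected-sample
    fraction is strictly greater than ``max_nondetect_fraction`` ("over
    80%" → exactly 80% is retained). Order of first appearance is kept.
    """
    if raw["sample_id"].nunique() < 1:
        raise MissingDataError("raw table contains no samples")
    if candidate_ids is None:
        candidate_ids = [
            m for m in pd.unique(raw["mirna_id"]) if m not in REFERENCE_IDS
        ]
    else:
        candidate_ids = list(candidate_ids)
    sub = raw[raw["mirna_id"].isin(candidate_ids)].copy()
    sub["detected"] = sub["cq"].notna() & (sub["cq"] <= max_cycles)
    det_by_sample = sub.groupby(["mirna_id", "sample_id"], sort=False)["detected"].any()
    nondetect_frac = 1.0 - det_by_sample.groupby("mirna_id", sort=False).mean()
    retained = [
        m for m in candidate_ids if nondetect_frac.get(m, 1.0) <= max_nondetect_fraction
    ]
    dropped = sorted(set(candidate_ids) - set(retained))
    if dropped:
        logger.info(
            "detectability filter excluded %d of %d candidate miRNAs: %s",
            len(dropped), len(candidate_ids), ", ".join(dropped),
        )
    return retained


@dataclass
class DeltaCqMatrix:
    """Samples × retained-miRNAs ΔCq matrix plus normalization provenance."""

    values: pd.DataFrame  # index = sample_id, columns = retained miRNA ids
    reference_used: pd.Series  # per-sample reference Cq
    retained_mirnas: list[str]
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)


def preprocess_cohort(
    raw: pd.DataFrame,
    max_nondetect_fraction: float = MAX_NONDETECT_FRACTION,
    ceiling: float = CENSOR_CEILING,
    sentinel: float = CENSOR_SENTINEL,
    target_volume: float = TARGET_VOLUME_UL,
    volume_adjust_spike_in: bool = False,
    max_cycles: float = MAX_CYCLES,
) -> DeltaCqMatrix:
    """Run the full preprocessing chain on a long-format raw Cq table.

    Columns required: ``sample_id, mirna_id, replicate, cq, volume_ul``
    (``cq`` empty/NaN = non-detect). Reference assays are averaged raw
    (volume-normalized for the endogenous control; the spike-in only when
    ``volume_adjust_spike_in``); a sample whose reference assays are
    entirely non-detected is dropped with a warning. Candidate miRNAs pass
    the detectability filter, then censor → volume-normalize → replicate
    mean → ΔCq against the per-sample reference.
    """
    required = {"sample_id", "mirna_id", "replicate", "cq", "volume_ul"}
    missing = required - set(raw.columns)
    if missing:
        raise InvalidParameterError(f"raw table missing columns: {sorted(missing)}")

    sample_order = list(pd.unique(raw["sample_id"]))
    retained = detectability_filter(
        raw, max_nondetect_fraction=max_nondetect_fraction, max_cycles=max_cycles
    )

    # --- references -----------------------------------------------------
    refs = raw[raw["mirna_id"].isin(REFERENCE_IDS)].copy()
    detected = refs["cq"].notna() & (refs["cq"] <= max_cycles)
    adjust = detected & (
        (refs["mirna_id"] == ENDOGENOUS_REF_ID) | volume_adjust_spike_in
    )
    refs["cq_norm"] = np.where(
        adjust,
        refs["cq"] - np.log2(target_volume / refs["volume_ul"]),
        np.where(detected, refs["cq"], np.nan),
    )
    ref_means = refs.groupby(["sample_id", "mirna_id"], sort=False)["cq_norm"].mean()
    ref_wide = ref_means.unstack("mirna_id").reindex(sample_order)
    for rid in REFERENCE_IDS:
        if rid not in ref_wide.columns:
            ref_wide[rid] = np.nan
    ref_ok = ref_wide[list(REFERENCE_IDS)].notna().all(axis=1)
    dropped = [s for s in sample_order if not ref_ok.get(s, False)]
    for s in dropped:
        logger.warning("sample %s dropped: reference miRNA not detected", s)
    kept_samples = [s for s in sample_order if s not in dropped]
    reference_used = ref_wide.loc[kept_samples, list(REFERENCE_IDS)].mean(axis=1)
    reference_used.name = "reference_cq"

    # --- candidate targets ----------------------------------------------
    targets = raw[raw["mirna_id"].isin(retained)].copy()
    t_detected = targets["cq"].notna() & (targets["cq"] <= ceiling)
    censored = np.where(
        targets["cq"].isna() | (targets["cq"] > ceiling), sentinel, targets["cq"]
    )
    n_censored = int((~t_detected).sum())
    if n_censored:
        logger.info(
            "censored %d of %d candidate measurements to Cq=%g",
            n_censored, len(targets), sentinel,
        )
    targets["cq_proc"] = np.where(
        t_detected,
        censored - np.log2(target_volume / targets["volume_ul"]),
        censored,
    )
    avg = (
        targets.groupby(["sample_id", "mirna_id"], sort=False)["cq_proc"]
        .mean()
        .unstack("mirna_id")
        .reindex(index=kept_samples, columns=retained)
    )
    values = avg.sub(reference_used, axis=0)
    values.index.name = "sample_id"
    return DeltaCqMatrix(
        values=values,
        reference_used=reference_used,
        retained_mirnas=retained,
        dropped_samples=dropped,
    )
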