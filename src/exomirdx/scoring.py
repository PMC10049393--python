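"""Dual-threshold panel scoring and confusion metrics.

For each panel miRNA two ΔCq cutoffs are derived from the cohort itself:
the upper limit of the control group's 99% CI of the mean
(``control_upper``) and the lower limit of the PDAC group's 99% CI
(``pdac_lower``). A sample scores one hit per cutoff its ΔCq strictly
exceeds — up to 2 hits per miRNA in combined mode, so a four-miRNA panel
scores 0–8 — and is called positive when its total reaches the call
cutoff (default: at least one hit). No ordering between the two cutoffs
is assumed: for some markers the PDAC lower limit sits above the control
upper limit.

The CA19-9 serum-antigen comparator uses the established clinical rule:
positive iff CA19-9 > 37 U/mL (strict).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidParameterError, UndefinedMetricError
from .group_stats import ci99_mean
from .simulate import DEFAULT_PANEL

ThresholdMode = Literal["control_upper", "pdac_lower", "combined"]

CA199_CUTOFF_U_ML = 37.0


@dataclass
class ThresholdSet:
    """Per-miRNA cutoff pair plus the scoring mode they are applied in."""

    panel: list[str]
    control_upper: dict[str, float]
    pdac_lower: dict[str, float]
    mode: ThresholdMode = "combined"

    def __post_init__(self) -> None:
        for mid in self.panel:
            if mid not in self.control_upper or mid not in self.pdac_lower:
                raise ConfigurationError(f"missing thresholds for panel miRNA {mid}")
        if self.mode not in ("control_upper", "pdac_lower", "combined"):
            raise ConfigurationError(f"unknown threshold mode: {self.mode}")

    @property
    def max_score(self) -> int:
        return (2 if self.mode == "combined" else 1) * len(self.panel)

    def with_mode(self, mode: ThresholdMode) -> "ThresholdSet":
        return ThresholdSet(
            list(self.panel), dict(self.control_upper), dict(self.pdac_lower), mode
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdSet":
        return cls(**json.loads(Path(path).read_text()))


def derive_thresholds(
    control_values: pd.DataFrame,
    pdac_values: pd.DataFrame,
    panel: Sequence[str] = DEFAULT_PANEL,
    mode: ThresholdMode = "combined",
    level: float = 0.99,
) -> ThresholdSet:
    """Derive the per-miRNA cutoff pair from group ΔCq slices.

    ``control_values`` / ``pdac_values`` are samples × miRNA frames (e.g.
    group slices of a ΔCq matrix). ``control_upper`` is the high end of the
    control CI of the mean; ``pdac_lower`` the low end of the PDAC CI.
    """
    panel = list(panel)
    if not panel:
        raise ConfigurationError("panel is empty")
    for mid in panel:
        if mid not in control_values.columns or mid not in pdac_values.columns:
            raise ConfigurationError(f"panel miRNA {mid} absent from ΔCq matrix")
    control_upper = {}
    pdac_lower = {}
    for mid in panel:
        control_upper[mid] = ci99_mean(control_values[mid], level)[1]
        pdac_lower[mid] = ci99_mean(pdac_values[mid], level)[0]
    return ThresholdSet(panel, control_upper, pdac_lower, mode)


def score_sample(
    delta_cqs: Mapping[str, float], thresholds: ThresholdSet
) -> tuple[dict[str, int], int]:
    """Hit counts for one sample: strict '>' against each active cutoff.

    Returns ``(hits_per_mirna, total_score)``; per-miRNA hits are 0–2 in
    combined mode, 0–1 in the single-threshold modes.
    """
    hits: dict[str, int] = {}
    for mid in thresholds.panel:
        if mid not in delta_cqs:
            raise ConfigurationError(f"sample lacks ΔCq for panel miRNA {mid}")
        v = float(delta_cqs[mid])
        h = 0
        if thresholds.mode in ("control_upper", "combined"):
            h += int(v > thresholds.control_upper[mid])
        if thresholds.mode in ("pdac_lower", "combined"):
            h += int(v > thresholds.pdac_lower[mid])
        hits[mid] = h
    return hits, sum(hits.values())


def call_sample(total_score: int, call_cutoff: int = 1) -> bool:
    """Binary panel call: positive iff ``total_score >= call_cutoff``."""
    if total_score < 0:
        raise InvalidParameterError("total_score must be >= 0")
    return total_score >= call_cutoff


def ca199_call(value: float, cutoff: float = CA199_CUTOFF_U_ML) -> bool:
    """CA19-9 comparator call: positive iff value strictly exceeds 37 U/mL."""
    if value < 0:
        raise InvalidParameterError("CA19-9 concentration must be >= 0")
    return float(value) > cutoff


def score_matrix(
    values: pd.DataFrame,
    thresholds: ThresholdSet,
    call_cutoff: int = 1,
    ca199: pd.Series | None = None,
    ca199_cutoff: float = CA199_CUTOFF_U_ML,
) -> pd.DataFrame:
    """Score every sample of a ΔCq matrix.

    Returns a frame indexed by sample with one integer hit column per panel
    miRNA, ``total_score``, ``call``, and — when CA19-9 values are supplied —
    ``ca199_u_ml`` and ``ca199_call``.
    """
    rows = []
    for sid, row in values.iterrows():
        hits, total = score_sample(row.to_dict(), thresholds)
        rec = {"sample_id": sid, **hits, "total_score": total}
        rec["call"] = call_sample(total, call_cutoff)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("sample_id")
    if ca199 is not None:
        out["ca199_u_ml"] = ca199.reindex(out.index)
        out["ca199_call"] = [ca199_call(v, ca199_cutoff) for v in out["ca199_u_ml"]]
    return out


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)  # percent
    specificity: float = field(init=False)  # percent

    def __post_init__(self) -> None:
        self.sensitivity = 100.0 * self.tp / (self.tp + self.fn)
        self.specificity = 100.0 * self.tn / (self.tn + self.fp)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
        }


def confusion_metrics(
    calls: Sequence[bool], truth: Sequence[bool]
) -> ConfusionMetrics:
    """Sensitivity/specificity (percent) and raw counts.

    ``truth`` marks disease-positive samples. Both classes must be present;
    otherwise one of the two rates is undefined.
    """
    calls = np.asarray(list(calls), dtype=bool)
    truth = np.asarray(list(truth), dtype=bool)
    if calls.shape != truth.shape:
        raise InvalidParameterError("calls and truth must have equal length")
    if truth.all() or not truth.any():
        raise UndefinedMetricError("both classes must be present")
    tp = int((calls & truth).sum())
    fn = int((~calls & truth).sum())
    tn = int((~calls & ~truth).sum())
    fp = int((calls & ~truth).sum())
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
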