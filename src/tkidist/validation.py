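"""Agreement statistics between predicted and observed tissue-to-blood
ratios: prediction errors, Pearson correlation, fold accuracy and a
Bland-Altman export.

The prediction error is normalized by the mean of the pair,
``PE = (PRED - OBS) / ((PRED + OBS)/2) * 100`` — antisymmetric in its
arguments and bounded in (-200, 200) for positive inputs.  Fold accuracy
counts predictions whose ratio to the observation lies in the closed
interval ``[1/fold, fold]`` (ties count as within).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .params import ObservedTBR

__all__ = [
    "INTERVAL_METHODS",
    "ValidationRecord",
    "ValidationReport",
    "ZeroVarianceError",
    "bland_altman_table",
    "fold_accuracy",
    "make_records",
    "pearson_r",
    "prediction_error",
    "summarize",
]

#: Selectable methods for the dispersion band of the PEs.  The source
#: imaging comparison labels its band a "CI95% of the data"; numerically it
#: is the mean +/- 1 SD band, hence the "sd" default.
INTERVAL_METHODS = ("sd", "percentile", "normal")


class ZeroVarianceError(ValueError):
    """Correlation is undefined: one margin has zero variance."""


def prediction_error(predicted: float, observed: float) -> float:
    """Signed percentage error normalized by the mean of the pair."""
    if predicted <= 0 or observed <= 0:
        raise ValueError(
            f"prediction error needs positive inputs, got ({predicted}, {observed})"
        )
    return (predicted - observed) / ((predicted + observed) / 2.0) * 100.0


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation via the standardized-sum formula
    ``r = 1/(n-1) * sum(((x - xbar)/s_x) * ((y - ybar)/s_y))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("zero variance in one margin; r undefined")
    return float(np.sum((x - x.mean()) / sx * (y - y.mean()) / sy) / (x.size - 1))


@dataclass(frozen=True)
class ValidationRecord:
    """One predicted-vs-observed pair with its error metrics."""

    compound: str
    tissue: str
    predicted: float
    observed: float
    pe_percent: float
    within_3fold: bool


def make_records(
    predicted: Mapping[tuple[str, str], float],
    observed: Sequence[ObservedTBR],
    *,
    fold: float = 3.0,
) -> list[ValidationRecord]:
    """Pair predictions with the observed fixture; unavailable observations
    are dropped (the erlotinib brain cell), so 17 of the 18 grid cells
    yield records under the default fixture."""
    records = []
    for obs in observed:
        if not obs.available:
            continue
        key = (obs.compound, obs.tissue)
        if key not in predicted:
            continue
        pred = predicted[key]
        ratio = pred / obs.mean
        records.append(
            ValidationRecord(
                compound=obs.compound,
                tissue=obs.tissue,
                predicted=pred,
                observed=obs.mean,
                pe_percent=prediction_error(pred, obs.mean),
                within_3fold=(1.0 / fold) <= ratio <= fold,
            )
        )
    return records


def fold_accuracy(
    records: Sequence[ValidationRecord], fold: float = 3.0
) -> dict[str, float]:
    """Percentage of available pairs per compound whose predicted/observed
    ratio lies within ``[1/fold, fold]`` (closed interval)."""
    if fold <= 1.0:
        raise ValueError(f"fold must exceed 1, got {fold}")
    result: dict[str, float] = {}
    compounds = sorted({r.compound for r in records})
    for compound in compounds:
        subset = [r for r in records if r.compound == compound]
        hits = sum(1 for r in subset if (1.0 / fold) <= r.predicted / r.observed <= fold)
        result[compound] = 100.0 * hits / len(subset)
    return result


@dataclass(frozen=True)
class ValidationReport:
    """Summary of predicted-vs-observed agreement.

    ``pe_interval`` is the dispersion band of the PEs under
    ``interval_method`` ("sd": mean +/- SD; "percentile": empirical
    2.5/97.5; "normal": mean +/- 1.96 SD).  ``pearson_r`` is None when the
    correlation is undefined (zero variance in a margin).
    """

    records: tuple[ValidationRecord, ...]
    mean_pe: float
    pe_range: tuple[float, float]
    pe_interval: tuple[float, float]
    interval_method: str
    pearson_r: float | None
    r_squared: float | None
    p_value: float | None
    fold_accuracy_by_compound: dict[str, float]

    @property
    def n(self) -> int:
        return len(self.records)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_pe": self.mean_pe,
            "pe_range": list(self.pe_range),
            "pe_interval": list(self.pe_interval),
            "interval_method": self.interval_method,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "fold_accuracy_by_compound": self.fold_accuracy_by_compound,
            "records": [vars(r).copy() for r in self.records],
        }


def summarize(
    records: Sequence[ValidationRecord], *, interval_method: str = "sd"
) -> ValidationReport:
    """Aggregate per-pair errors into a validation report.

    The correlation significance uses the t statistic for a Pearson
    correlation with ``n - 2`` degrees of freedom.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to summarize")
    if interval_method not in INTERVAL_METHODS:
        raise ValueError(
            f"unknown interval method {interval_method!r}; expected {INTERVAL_METHODS}"
        )
    pes = np.array([r.pe_percent for r in records])
    mean_pe = float(pes.mean())
    sd_pe = float(pes.std(ddof=1))
    if interval_method == "sd":
        interval = (mean_pe - sd_pe, mean_pe + sd_pe)
    elif interval_method == "percentile":
        lo, hi = np.percentile(pes, [2.5, 97.5])
        interval = (float(lo), float(hi))
    else:
        interval = (mean_pe - 1.96 * sd_pe, mean_pe + 1.96 * sd_pe)

    x = [r.predicted for r in records]
    y = [r.observed for r in records]
    try:
        r = pearson_r(x, y)
        n = len(records)
        if abs(r) < 1.0:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p_value = float(2.0 * _sstats.t.sf(abs(t), df=n - 2))
        else:
            p_value = 0.0
        r_squared = r * r
    except ZeroVarianceError:
        r = r_squared = p_value = None

    return ValidationReport(
        records=tuple(records),
        mean_pe=mean_pe,
        pe_range=(float(pes.min()), float(pes.max())),
        pe_interval=interval,
        interval_method=interval_method,
        pearson_r=r,
        r_squared=r_squared,
        p_value=p_value,
        fold_accuracy_by_compound=fold_accuracy(records),
    )


def bland_altman_table(
    records: Sequence[ValidationRecord], fold: float = 3.0
) -> pd.DataFrame:
    """Bland-Altman-style table: pair mean vs PE with constant agreement
    bounds at the PE equivalent of the fold criterion
    (``+-200*(fold-1)/(fold+1)``, i.e. +-100 for 3-fold)."""
    bound = 200.0 * (fold - 1.0) / (fold + 1.0)
    rows = [
        {
            "compound": r.compound,
            "tissue": r.tissue,
            "pair_mean": (r.predicted + r.observed) / 2.0,
            "pe_percent": r.pe_percent,
            "lower_bound": -bound,
            "upper_bound": bound,
        }
        for r in records
    ]
    columns = ["compound", "tissue", "pair_mean", "pe_percent", "lower_bound", "upper_bound"]
    return pd.DataFrame(rows, columns=columns)
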