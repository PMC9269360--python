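"""Pheophytin-proportion threshold calibration against satellite stages.

A field sample's bloom stage is read from its pheophytin proportion
p = Pheo / (Chl + Pheo): a growing bloom is pigment-fresh (low p), a mature
or senescent bloom accumulates degraded pigment (high p). The calibration
scans every integer percentage threshold T in 0..100, classifies each
matched station-year as EB when p < T/100 (PB otherwise, equality going to
PB), tabulates the 2x2 field-vs-satellite error matrix, and selects the T
with maximum overall accuracy; ties are broken toward balanced EB/PB
omission errors, then toward the smallest T.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Stage

__all__ = [
    "pheophytin_proportion",
    "classify_field_stage",
    "build_error_matrix",
    "accuracy_metrics",
    "scan_thresholds",
    "ErrorMatrix",
    "AccuracyMetrics",
    "ThresholdScan",
    "UndefinedProportionError",
    "EmptyCalibrationError",
]


class UndefinedProportionError(ValueError):
    """Both pigments zero: the proportion is undefined."""


class EmptyCalibrationError(ValueError):
    """No station-years with both a satellite label and a field sample."""


def pheophytin_proportion(chl: float, pheo: float) -> float:
    """Pheo / (Chl + Pheo), dimensionless in [0, 1]."""
    if chl < 0 or pheo < 0:
        raise ValueError("pigment concentrations must be >= 0")
    total = chl + pheo
    if total == 0:
        raise UndefinedProportionError("chl + pheo = 0: proportion undefined")
    return pheo / total


def classify_field_stage(p: float, threshold_pct: int) -> Stage:
    """EB iff p < threshold_pct/100, else PB (equality assigned to PB)."""
    if not 0 <= threshold_pct <= 100:
        raise ValueError("threshold must lie in [0, 100]")
    return Stage.EB if p < threshold_pct / 100.0 else Stage.PB


@dataclass
class AccuracyMetrics:
    overall_accuracy: float
    producer_accuracy: dict = field(default_factory=dict)  # per satellite class
    user_accuracy: dict = field(default_factory=dict)      # per field class
    omission: dict = field(default_factory=dict)           # 100 - producer
    commission: dict = field(default_factory=dict)         # 100 - user
    consistent: int = 0
    inconsistent: int = 0

    def bias(self) -> float:
        """|omission(EB) - omission(PB)|; inf when either is undefined."""
        om_eb, om_pb = self.omission.get("EB"), self.omission.get("PB")
        if om_eb is None or om_pb is None:
            return float("inf")
        return abs(om_eb - om_pb)


@dataclass
class ErrorMatrix:
    """2x2 field-vs-satellite count table, satellite classes as reference.

    ``counts[i][j]`` is the number of station-years with field class i and
    satellite class j, i/j in (EB, PB) order, mirroring the published table
    orientation (field rows, satellite columns).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("error matrix must be 2x2 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(["EB", "PB"], name="field"),
                            columns=pd.Index(["EB", "PB"], name="satellite"))


_CLASSES = ("EB", "PB")


def build_error_matrix(field_labels, satellite_labels) -> ErrorMatrix:
    """Tabulate matched field/satellite EB-PB labels (satellite = reference)."""
    field_labels = [str(l) for l in field_labels]
    satellite_labels = [str(l) for l in satellite_labels]
    if len(field_labels) != len(satellite_labels):
        raise ValueError("label lists must have equal length")
    if not field_labels:
        raise ValueError("cannot tabulate an empty label list")
    bad = set(field_labels) | set(satellite_labels) - set(_CLASSES)
    if not set(field_labels) <= set(_CLASSES) or not set(satellite_labels) <= set(_CLASSES):
        raise ValueError(f"labels must be EB or PB, got {sorted(bad)}")
    counts = np.zeros((2, 2), dtype=int)
    for f, s in zip(field_labels, satellite_labels):
        counts[_CLASSES.index(f), _CLASSES.index(s)] += 1
    return ErrorMatrix(counts)


def accuracy_metrics(m: ErrorMatrix) -> AccuracyMetrics:
    """Overall, producer (reference-column) and user (row) accuracies with
    their omission/commission complements, in percent.

    A class with an empty reference column (or empty predicted row) has its
    producer (user) metric reported as None; the others are still computed.
    """
    if m.total == 0:
        raise ValueError("empty error matrix")
    diag = np.diag(m.counts)
    consistent = int(diag.sum())
    out = AccuracyMetrics(
        overall_accuracy=100.0 * consistent / m.total,
        consistent=consistent,
        inconsistent=m.total - consistent,
    )
    col_tot = m.counts.sum(axis=0)
    row_tot = m.counts.sum(axis=1)
    for k, cls in enumerate(_CLASSES):
        if col_tot[k] > 0:
            pa = 100.0 * m.counts[k, k] / col_tot[k]
            out.producer_accuracy[cls] = pa
            out.omission[cls] = 100.0 - pa
        else:
            out.producer_accuracy[cls] = None
            out.omission[cls] = None
        if row_tot[k] > 0:
            ua = 100.0 * m.counts[k, k] / row_tot[k]
            out.user_accuracy[cls] = ua
            out.commission[cls] = 100.0 - ua
        else:
            out.user_accuracy[cls] = None
            out.commission[cls] = None
    return out


@dataclass
class ThresholdScan:
    table: pd.DataFrame  # one row per threshold with accuracy metrics
    selected: int

    def metrics_at(self, threshold_pct: int) -> pd.Series:
        return self.table.set_index("threshold_pct").loc[threshold_pct]


def scan_thresholds(
    proportions,
    satellite_labels,
    threshold_range: tuple[int, int] = (0, 100),
) -> ThresholdScan:
    """Exhaustive integer-threshold scan of the field classifier.

    For each T in ``threshold_range`` (inclusive), classify every matched
    proportion (EB iff p < T/100), build the error matrix against the
    satellite labels and record the accuracy metrics. The selected threshold
    maximizes overall accuracy, with ties broken by (i) smaller
    |omission(EB) - omission(PB)| and (ii) smaller T.
    """
    proportions = np.asarray(list(proportions), dtype=float)
    satellite_labels = [str(l) for l in satellite_labels]
    if proportions.size == 0:
        raise EmptyCalibrationError("no matched proportion/satellite-label pairs")
    if proportions.size != len(satellite_labels):
        raise ValueError("proportions and labels must have equal length")
    lo, hi = threshold_range
    rows = []
    best: tuple[float, float, int] | None = None  # (-acc, bias, T)
    for t in range(lo, hi + 1):
        field = [classify_field_stage(p, t) for p in proportions]
        met = accuracy_metrics(build_error_matrix(field, satellite_labels))
        rows.append({
            "threshold_pct": t,
            "overall_accuracy": met.overall_accuracy,
            "omission_EB": met.omission["EB"],
            "commission_EB": met.commission["EB"],
            "omission_PB": met.omission["PB"],
            "commission_PB": met.commission["PB"],
        })
        key = (-met.overall_accuracy, met.bias(), t)
        if best is None or key < best:
            best = key
    assert best is not None
    return ThresholdScan(table=pd.DataFrame(rows), selected=best[2])
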