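"""Tabular observation data-sets: CSV I/O, bounding filter, normalization, splits.

The observation schema is one row per droplet-generation experiment: the
eight design parameters, the observed regime label, droplet diameter (μm)
and generation rate (Hz), plus an optional polydispersity column.

The regression models are trained only inside a bounded performance window
(diameter 25–250 μm, rate 5–500 Hz, endpoints inclusive) where the data
density supports them; :func:`bound_filter` applies that window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .physics import (
    DRIPPING,
    FEATURE_NAMES,
    JETTING,
    DesignPoint,
    Performance,
)

__all__ = [
    "ObservationRecord",
    "DatasetSummary",
    "NormalizationStats",
    "SchemaError",
    "DIAMETER_RANGE_UM",
    "RATE_RANGE_HZ",
    "CSV_COLUMNS",
    "read_dataset",
    "write_dataset",
    "records_to_frame",
    "bound_filter",
    "split_train_test",
    "normalize_features",
    "summarize",
]

#: Bounded performance window used for regression training (inclusive).
DIAMETER_RANGE_UM = (25.0, 250.0)
RATE_RANGE_HZ = (5.0, 500.0)

CSV_COLUMNS = list(FEATURE_NAMES) + ["regime", "diameter_um", "rate_hz"]
OPTIONAL_COLUMNS = ["polydispersity"]


class SchemaError(ValueError):
    """The CSV header or a cell does not conform to the documented schema."""


@dataclass(frozen=True)
class ObservationRecord:
    """One experimental observation: a design point and its outcome."""

    design: DesignPoint
    outcome: Performance

    def to_row(self) -> dict:
        row = dict(zip(FEATURE_NAMES, self.design.to_vector()))
        row["regime"] = self.outcome.regime
        row["diameter_um"] = self.outcome.diameter_um
        row["rate_hz"] = self.outcome.rate_hz
        if self.outcome.polydispersity is not None:
            row["polydispersity"] = self.outcome.polydispersity
        return row


@dataclass(frozen=True)
class DatasetSummary:
    n_total: int
    n_dripping: int
    n_jetting: int
    diameter_range_um: tuple[float, float]
    rate_range_hz: tuple[float, float]


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature min–max statistics; travel with any saved predictor."""

    feature_names: tuple[str, ...]
    minima: np.ndarray
    maxima: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        width = self.maxima - self.minima
        out = np.empty_like(x)
        nonconst = width > 0
        out[..., nonconst] = (x[..., nonconst] - self.minima[nonconst]) / width[nonconst]
        out[..., ~nonconst] = 0.5  # constant feature: centre of the unit interval
        return out

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        width = self.maxima - self.minima
        out = np.empty_like(z)
        nonconst = width > 0
        out[..., nonconst] = z[..., nonconst] * width[nonconst] + self.minima[nonconst]
        out[..., ~nonconst] = self.minima[~nonconst]
        return out


def _record_from_row(row: pd.Series, index: int) -> ObservationRecord:
    try:
        design = DesignPoint.from_vector([float(row[c]) for c in FEATURE_NAMES])
        outcome = Performance(
            regime=str(row["regime"]).strip().lower(),
            diameter_um=float(row["diameter_um"]),
            rate_hz=float(row["rate_hz"]),
            polydispersity=(float(row["polydispersity"])
                            if "polydispersity" in row.index
                            and pd.notna(row.get("polydispersity")) else None),
        )
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"row {index}: {exc}") from exc
    return ObservationRecord(design=design, outcome=outcome)


def read_dataset(path) -> list[ObservationRecord]:
    """Read a CSV observation data-set into records.

    Raises :class:`SchemaError` naming the missing column or offending row
    if the file does not follow the documented schema. Extra columns are
    ignored with a warning.
    """
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in frame.columns
             if c not in CSV_COLUMNS and c not in OPTIONAL_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unrecognized column(s): {', '.join(extra)}")
    records = []
    for i, row in frame.iterrows():
        records.append(_record_from_row(row, index=int(i) + 2))  # +2: header + 1-based
    return records


def records_to_frame(records: list[ObservationRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([r.to_row() for r in records])
    cols = CSV_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in frame.columns]
    return frame[cols]


def write_dataset(records: list[ObservationRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def bound_filter(
    records: list[ObservationRecord],
    diameter_range_um: tuple[float, float] = DIAMETER_RANGE_UM,
    rate_range_hz: tuple[float, float] = RATE_RANGE_HZ,
) -> list[ObservationRecord]:
    """Keep records whose diameter AND rate lie inside the inclusive window."""
    dlo, dhi = diameter_range_um
    flo, fhi = rate_range_hz
    if dlo > dhi or flo > fhi:
        raise ValueError("ranges must be ordered (lo ≤ hi)")
    return [
        r for r in records
        if dlo <= r.outcome.diameter_um <= dhi and flo <= r.outcome.rate_hz <= fhi
    ]


def split_train_test(
    records: list[ObservationRecord], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[ObservationRecord], list[ObservationRecord]]:
    """Disjoint, exhaustive, seed-reproducible train/test partition.

    Membership depends only on the seed and the multiset of records, not on
    their input order (records are sorted by their row values before the
    shuffle is applied).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if len(records) < 5:
        raise ValueError("need at least 5 records to split")
    order = sorted(range(len(records)),
                   key=lambda i: tuple(records[i].to_row().items()))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    shuffled = [records[order[j]] for j in perm]
    n_test = int(round(len(records) * test_fraction))
    n_test = min(max(n_test, 1), len(records) - 1)
    return shuffled[n_test:], shuffled[:n_test]


def normalize_features(
    records: list[ObservationRecord], stats: NormalizationStats | None = None
) -> tuple[np.ndarray, NormalizationStats]:
    """Min–max scale the 8 design parameters to [0, 1].

    With ``stats`` given, re-uses previously fitted statistics (prediction
    time); otherwise fits them on ``records``. A constant feature maps to
    0.5 with a warning.
    """
    if len(records) < 2 and stats is None:
        raise ValueError("need at least 2 records to fit normalization statistics")
    x = np.array([r.design.to_vector() for r in records], dtype=float)
    if stats is None:
        minima = x.min(axis=0)
        maxima = x.max(axis=0)
        if np.any(maxima - minima == 0):
            constant = [FEATURE_NAMES[i] for i in np.nonzero(maxima == minima)[0]]
            warnings.warn(f"constant feature(s) mapped to 0.5: {', '.join(constant)}")
        stats = NormalizationStats(feature_names=FEATURE_NAMES,
                                   minima=minima, maxima=maxima)
    return stats.transform(x), stats


def summarize(records: list[ObservationRecord]) -> DatasetSummary:
    diameters = [r.outcome.diameter_um for r in records]
    rates = [r.outcome.rate_hz for r in records]
    n_drip = sum(1 for r in records if r.outcome.regime == DRIPPING)
    n_jet = sum(1 for r in records if r.outcome.regime == JETTING)
    return DatasetSummary(
        n_total=len(records),
        n_dripping=n_drip,
        n_jetting=n_jet,
        diameter_range_um=(min(diameters), max(diameters)) if diameters else (0.0, 0.0),
        rate_range_hz=(min(rates), max(rates)) if rates else (0.0, 0.0),
    )
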