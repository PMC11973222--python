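"""Percentile and width statistics of number-based measurand distributions.

Quantile convention, used everywhere in the package (bootstrap included):
linear interpolation between closest order statistics at fractional rank
``1 + (n - 1) * p`` — numpy's ``method="linear"``.  D-values D10..D90 are the
corresponding percentiles; the normalized interquartile range
``IQR% = 100 * (D75 - D25) / D50`` is the polydispersity proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .particle_data import ParticleDataError

#: Percentile labels in rank order and their probability levels.
PERCENTILE_LABELS = ("D10", "D25", "D50", "D75", "D90")
PERCENTILE_FRACTIONS = {"D10": 0.10, "D25": 0.25, "D50": 0.50, "D75": 0.75, "D90": 0.90}


@dataclass(frozen=True)
class PercentileSet:
    """The five percentiles D10..D90 of one distribution (measurand units)."""

    d10: float
    d25: float
    d50: float
    d75: float
    d90: float

    def __post_init__(self):
        vals = self.as_array()
        if np.any(np.diff(vals) < 0):
            raise ParticleDataError(f"percentiles not monotone: {vals.tolist()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.d10, self.d25, self.d50, self.d75, self.d90])

    def __getitem__(self, label: str) -> float:
        return float(self.as_array()[PERCENTILE_LABELS.index(label)])


@dataclass(frozen=True)
class PSDSummary:
    """Percentiles plus width statistics of one measurand distribution."""

    percentiles: PercentileSet
    iqr: float
    iqr_pct: float
    n: int

    def to_dict(self) -> dict:
        p = self.percentiles
        return {
            "d10": p.d10, "d25": p.d25, "d50": p.d50, "d75": p.d75, "d90": p.d90,
            "iqr": self.iqr, "iqr_pct": self.iqr_pct, "n": self.n,
        }


def percentile(values, p: float) -> float:
    """Order statistic with linear interpolation at rank ``1 + (n - 1) * p``.

    ``p`` is a fraction in (0, 1).  Deterministic; ties handled implicitly by
    sorting.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParticleDataError("percentile of an empty vector")
    if not np.all(np.isfinite(values)):
        raise ParticleDataError("percentile requires finite values")
    if not 0.0 < p < 1.0:
        raise ParticleDataError(f"p must be in (0, 1), got {p}")
    return float(np.quantile(values, p, method="linear"))


def percentile_set(values) -> PercentileSet:
    """All five D-values of ``values`` under the package quantile convention."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParticleDataError("percentiles of an empty vector")
    q = np.quantile(values, [0.10, 0.25, 0.50, 0.75, 0.90], method="linear")
    return PercentileSet(*map(float, q))


def summarize(values) -> PSDSummary:
    """Percentiles, IQR and IQR% of a positive-valued measurand vector."""
    values = np.asarray(values, dtype=float)
    ps = percentile_set(values)
    if ps.d50 <= 0:
        raise ParticleDataError("IQR% undefined for non-positive median")
    iqr = ps.d75 - ps.d25
    return PSDSummary(
        percentiles=ps,
        iqr=float(iqr),
        iqr_pct=float(100.0 * iqr / ps.d50),
        n=int(values.size),
    )
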