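"""Cross-material scaling of the minimum particle count with polydispersity.

The minimum count N_m needed to reach a given percentile precision grows as a
power law of the normalized distribution width IQR%.  This module fits that
power law (least squares in log-log space, mirroring the 1/sqrt(N) scaling of
quantile standard errors, for which N_m is approximately proportional to the
squared width), predicts N_m ex ante from a known or estimated IQR%, and maps
an IQR% to the practical material categories used as measurement guidance:

    size polydispersity   I: IQR% <= 30    II: 30 < IQR% <= 55    III: 55 < IQR% <= 80
    shape polydispersity  I: IQR% <= 30    II: 30 < IQR% <= 55

Size categories carry the published guidance counts (particles to measure to
reach U_N = 10% / 5% on the median): I 35/150, II 110/450, III 260/1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .particle_data import ParticleDataError

#: Guidance counts per size category at U_N = 10% and 5% (fractions as keys).
SIZE_RECOMMENDED_N = {
    "I": {0.10: 35, 0.05: 150},
    "II": {0.10: 110, 0.05: 450},
    "III": {0.10: 260, 0.05: 1000},
}
SIZE_BOUNDS = {"I": (0.0, 30.0), "II": (30.0, 55.0), "III": (55.0, 80.0)}
SHAPE_BOUNDS = {"I": (0.0, 30.0), "II": (30.0, 55.0)}

OUT_OF_RANGE = "out-of-range"


@dataclass(frozen=True)
class MaterialCategory:
    """Polydispersity category with its IQR% range (half-open, upper bound
    inclusive) and, for size mode, the published guidance counts."""

    label: str
    mode: str
    iqr_range: tuple[float, float] | None
    recommended_n: dict[float, int] | None

    @property
    def in_range(self) -> bool:
        return self.label != OUT_OF_RANGE


@dataclass(frozen=True)
class PowerLawModel:
    """N_m = a * (IQR%)^b, fitted in log-log space at one target U_N."""

    coefficient_a: float
    exponent_b: float
    u_target: float
    fit_r2: float
    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if self.coefficient_a <= 0:
            raise ParticleDataError("power-law coefficient must be > 0")

    def to_dict(self) -> dict:
        return {
            "coefficient_a": self.coefficient_a,
            "exponent_b": self.exponent_b,
            "u_target": self.u_target,
            "fit_r2": self.fit_r2,
            "points": [list(p) for p in self.points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PowerLawModel":
        return cls(
            coefficient_a=float(d["coefficient_a"]),
            exponent_b=float(d["exponent_b"]),
            u_target=float(d["u_target"]),
            fit_r2=float(d["fit_r2"]),
            points=tuple(tuple(p) for p in d["points"]),
        )


def fit_power_law(points, u_target: float) -> PowerLawModel:
    """Least-squares fit of log(N_m) on log(IQR%).

    ``points`` is a list of (iqr_pct, n_m) pairs, all positive, >= 3 of them
    with at least two distinct IQR% values.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ParticleDataError("power-law fit needs at least 3 points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.any(x <= 0) or np.any(y <= 0):
        raise ParticleDataError("power-law fit needs positive entries")
    if np.unique(x).size < 2:
        raise ParticleDataError("rank deficient: all IQR% values identical")
    lx, ly = np.log(x), np.log(y)
    b, log_a = np.polyfit(lx, ly, 1)
    resid = ly - (b * lx + log_a)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawModel(
        coefficient_a=float(math.exp(log_a)),
        exponent_b=float(b),
        u_target=float(u_target),
        fit_r2=float(r2),
        points=tuple(pts),
    )


def categorize(iqr_pct: float, mode: str = "size") -> MaterialCategory:
    """Map an IQR% to its polydispersity category (upper bounds inclusive).

    Values above the categorized range (80 for size, 55 for shape) return an
    explicit out-of-range result — never a silent clamp — because the
    grouping is only defined over the materials it was derived from.
    """
    if iqr_pct <= 0:
        raise ParticleDataError("iqr_pct must be > 0")
    if mode not in ("size", "shape"):
        raise ParticleDataError(f"unknown mode {mode!r}")
    bounds = SIZE_BOUNDS if mode == "size" else SHAPE_BOUNDS
    for label, (lo, hi) in bounds.items():
        if lo < iqr_pct <= hi:
            rec = SIZE_RECOMMENDED_N[label] if mode == "size" else None
            return MaterialCategory(label, mode, (lo, hi), rec)
    return MaterialCategory(OUT_OF_RANGE, mode, None, None)


def predict_nm(model: PowerLawModel, iqr_pct: float) -> int:
    """Ex ante minimum-count prediction ceil(a * IQR%^b).

    IQR% outside 0.5x–2x the fitted range is allowed but is extrapolation;
    inspect ``model.points`` when that matters.
    """
    if iqr_pct <= 0:
        raise ParticleDataError("iqr_pct must be > 0")
    value = model.coefficient_a * iqr_pct**model.exponent_b
    return int(math.ceil(value - 1e-9))  # guard against float noise above integers


def prediction_is_extrapolated(model: PowerLawModel, iqr_pct: float) -> bool:
    xs = [p[0] for p in model.points]
    return not (0.5 * min(xs) <= iqr_pct <= 2.0 * max(xs))
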