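"""Seeded particle-population generators with known ground truth.

The generators emulate the spectrum of real nanomaterial datasets the method
is designed for — narrow colloids (lognormal), right-skewed powders (gamma),
left-skewed populations (weibull at high shape), multimodal powders (two-
component lognormal mixture) and rod-like particles — parameterized by the
target median (nm) and polydispersity IQR% of the number-based distribution.
A replicate-design variant adds multiplicative between-day effects and a
global bias, producing a :class:`~psdcount.particle_data.ValidationDesign`
with the realized effects recorded as ground truth.

The module also provides the asymptotic analytic oracle for quantile
precision: the sampling standard error of the p-th sample quantile is
sqrt(p (1-p) / n) / f(x_p), so the relative expanded (k=2) uncertainty is

    U_N = 2 sqrt(p (1-p) / n) / (f(x_p) x_p),

which for the lognormal median reduces to 2 s sqrt(pi/2) / sqrt(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .particle_data import ParticleDataError, ParticleDataset, ValidationDesign

#: Standard normal upper quartile, z_{0.75}.
Z75 = float(stats.norm.ppf(0.75))  # 0.6744897501960817

FAMILIES = ("lognormal", "gamma", "weibull", "bimodal_mixture", "rod")


@dataclass(frozen=True)
class DesignSpec:
    """Replicate design: ``days`` x ``reps_per_day`` datasets with a
    multiplicative lognormal between-day effect of coefficient of variation
    ``between_day_cv`` and a global multiplicative bias ``bias_fraction``."""

    days: int = 3
    reps_per_day: int = 2
    between_day_cv: float = 0.03
    bias_fraction: float = 0.0

    def __post_init__(self):
        if self.days < 2 or self.reps_per_day < 1:
            raise ParticleDataError("design needs >= 2 days and >= 1 replicate/day")
        if self.between_day_cv < 0:
            raise ParticleDataError("between_day_cv must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of a particle population (and optional design).

    ``median`` (nm) and ``iqr_pct`` set the location and normalized width of
    the primary size measurand (Fmin); ``iqr_pct = 0`` denotes a degenerate
    constant population.  ``family_params`` carries family-specific free
    parameters (mixture weight/separation, rod aspect-ratio distribution).
    """

    family: str
    median: float = 20.0
    iqr_pct: float = 30.0
    n: int = 20000
    seed: int = 0
    family_params: dict = field(default_factory=dict)
    design: DesignSpec | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParticleDataError(f"unknown family {self.family!r}")
        if self.median <= 0 or self.iqr_pct < 0 or self.n < 2:
            raise ParticleDataError("need median > 0, iqr_pct >= 0, n >= 2")


def iqr_to_logsd(iqr_pct: float) -> float:
    """Lognormal shape s hitting a target IQR% exactly.

    Quartiles of a lognormal sit at median * exp(+-z75 s), so
    IQR% = 200 sinh(z75 s); the closed-form inverse is
    s = asinh(IQR% / 200) / z75.
    """
    if iqr_pct <= 0:
        raise ParticleDataError("iqr_pct must be > 0")
    return float(np.arcsinh(iqr_pct / 200.0) / Z75)


def _gamma_shape(iqr_pct: float) -> float:
    # IQR% of a gamma depends only on the shape parameter; invert numerically
    def f(log_a):
        a = math.exp(log_a)
        q = stats.gamma.ppf([0.25, 0.5, 0.75], a)
        return 100.0 * (q[2] - q[0]) / q[1] - iqr_pct

    return math.exp(brentq(f, math.log(1e-2), math.log(1e6), xtol=1e-12))


def _weibull_shape(iqr_pct: float) -> float:
    def f(log_c):
        c = math.exp(log_c)
        q = stats.weibull_min.ppf([0.25, 0.5, 0.75], c)
        return 100.0 * (q[2] - q[0]) / q[1] - iqr_pct

    return math.exp(brentq(f, math.log(1e-2), math.log(1e3), xtol=1e-12))


class _LognormMixture:
    """Two-component lognormal mixture with scipy-like pdf/cdf/ppf/rvs."""

    def __init__(self, weight, medians, s_components):
        if not 0 < weight < 1:
            raise ParticleDataError("mixture weight must be in (0, 1)")
        self.w = float(weight)
        self.components = [
            stats.lognorm(s, scale=m) for m, s in zip(medians, s_components)
        ]

    def pdf(self, x):
        return self.w * self.components[0].pdf(x) + (1 - self.w) * self.components[1].pdf(x)

    def cdf(self, x):
        return self.w * self.components[0].cdf(x) + (1 - self.w) * self.components[1].cdf(x)

    def ppf(self, p):
        lo = min(c.ppf(1e-9) for c in self.components)
        hi = max(c.ppf(1 - 1e-9) for c in self.components)
        return brentq(lambda x: self.cdf(x) - p, lo, hi, xtol=1e-12)

    def rvs(self, size, random_state):
        pick = random_state.random(size) < self.w
        out = np.where(
            pick,
            self.components[0].rvs(size=size, random_state=random_state),
            self.components[1].rvs(size=size, random_state=random_state),
        )
        return out


def population_distribution(
    family: str, median: float, iqr_pct: float, **family_params
):
    """Frozen distribution of the primary size measurand for a unimodal or
    mixture family, matched to the target median (exactly) and IQR% (exactly
    for unimodal families; mixtures are matched on the median only)."""
    if family == "lognormal":
        return stats.lognorm(iqr_to_logsd(iqr_pct), scale=median)
    if family == "gamma":
        a = _gamma_shape(iqr_pct)
        return stats.gamma(a, scale=median / stats.gamma.ppf(0.5, a))
    if family == "weibull":
        c = _weibull_shape(iqr_pct)
        return stats.weibull_min(c, scale=median / stats.weibull_min.ppf(0.5, c))
    if family == "bimodal_mixture":
        w = family_params.get("weight", 0.5)
        sep = family_params.get("separation", 3.0)
        if sep <= 0:
            raise ParticleDataError("mixture separation must be > 0")
        comp_iqr = family_params.get("component_iqr_pct", 20.0)
        s = iqr_to_logsd(comp_iqr)
        base = _LognormMixture(w, (1.0, sep), (s, s))
        scale = median / base.ppf(0.5)
        return _LognormMixture(w, (scale, scale * sep), (s, s))
    raise ParticleDataError(f"no closed-form distribution for family {family!r}")


def _draw_sizes(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.iqr_pct == 0:
        return np.full(n, spec.median)
    if spec.family in ("lognormal", "rod"):  # rod widths are lognormal
        s = iqr_to_logsd(spec.iqr_pct)
        return spec.median * np.exp(s * rng.standard_normal(n))
    dist = population_distribution(
        spec.family, spec.median, spec.iqr_pct, **spec.family_params
    )
    return np.asarray(dist.rvs(size=n, random_state=rng), dtype=float)


def _rod_table(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    width = _draw_sizes(spec, n, rng)
    ar_median = float(spec.family_params.get("ar_median", 3.0))
    ar_iqr = float(spec.family_params.get("ar_iqr_pct", 0.0))
    if ar_median < 1:
        raise ParticleDataError("rod ar_median must be >= 1")
    if ar_iqr > 0:
        s_ar = iqr_to_logsd(ar_iqr)
        ar = ar_median * np.exp(s_ar * rng.standard_normal(n))
    else:
        ar = np.full(n, ar_median)
    ar = np.maximum(ar, 1.0)  # rods: fmax >= fmin always
    length = width * ar
    # spherocylinder projected area: A = W (L - W) + pi W^2 / 4
    area = width * (length - width) + math.pi * width**2 / 4.0
    ecd = np.sqrt(4.0 * area / math.pi)
    return pd.DataFrame(
        {"fmin_nm": width, "fmax_nm": length, "micd_nm": width.copy(), "ecd_nm": ecd}
    )


def _population_table(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    if spec.family == "rod":
        return _rod_table(spec, n, rng)
    fmin = _draw_sizes(spec, n, rng)
    cols = {"fmin_nm": fmin}
    ar_median = spec.family_params.get("ar_median")
    if ar_median is not None:
        ar_iqr = float(spec.family_params.get("ar_iqr_pct", 0.0))
        if ar_iqr > 0:
            ar = float(ar_median) * np.exp(
                iqr_to_logsd(ar_iqr) * rng.standard_normal(n)
            )
        else:
            ar = np.full(n, float(ar_median))
        cols["fmax_nm"] = fmin * np.maximum(ar, 1.0)
    return pd.DataFrame(cols)


def generate(spec: SyntheticSpec):
    """Generate a seeded population table or, when ``spec.design`` is set, a
    full :class:`ValidationDesign` of days x replicates datasets.

    Design variant: every dataset of day d is multiplied by a day factor
    drawn lognormal with mean 1 and CV ``between_day_cv``, and all datasets by
    the global factor (1 + ``bias_fraction``).  The realized day factors and
    the applied bias are recorded in ``design.ground_truth``.
    """
    if spec.design is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed]))
        df = _population_table(spec, spec.n, rng)
        return ParticleDataset(material_id=f"synthetic-{spec.family}", particles=df)

    d = spec.design
    day_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 104729]))
    if d.between_day_cv > 0:
        sd_log = math.sqrt(math.log(1.0 + d.between_day_cv**2))
        factors = np.exp(sd_log * day_rng.standard_normal(d.days) - sd_log**2 / 2.0)
    else:
        factors = np.ones(d.days)
    bias_factor = 1.0 + d.bias_fraction

    entries = []
    for day in range(1, d.days + 1):
        for rep in range(1, d.reps_per_day + 1):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, day, rep]))
            df = _population_table(spec, spec.n, rng)
            scaled = df * (factors[day - 1] * bias_factor)
            entries.append(
                (day, rep, ParticleDataset(f"synthetic-{spec.family}-d{day}r{rep}", scaled))
            )
    return ValidationDesign(
        datasets=tuple(entries),
        certified_value=spec.median,
        u_certified=0.0,
        u_cal_rel=0.0,
        ground_truth={
            "day_factors": factors.tolist(),
            "bias_fraction": d.bias_fraction,
            "true_median": spec.median,
            "between_day_cv": d.between_day_cv,
        },
    )


def analytic_un(family: str, params: dict, p: float, n: int) -> float:
    """Asymptotic relative expanded uncertainty of the p-th sample quantile.

    U_N = 2 sqrt(p (1 - p) / n) / (f(x_p) x_p) with x_p the population
    quantile and f its density; exact 1/sqrt(n) scaling.  ``params`` holds
    ``median``, ``iqr_pct`` and any family parameters.
    """
    if not 0 < p < 1:
        raise ParticleDataError("p must be in (0, 1)")
    if n < 30:
        raise ParticleDataError("asymptotic formula needs n >= 30")
    dist = population_distribution(
        family, params.get("median", 20.0), params["iqr_pct"],
        **{k: v for k, v in params.items() if k not in ("median", "iqr_pct")},
    )
    x_p = float(dist.ppf(p))
    f_xp = float(dist.pdf(x_p))
    if f_xp <= 0:
        raise ParticleDataError("zero density at the requested quantile")
    return 2.0 * math.sqrt(p * (1.0 - p) / n) / (f_xp * x_p)
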