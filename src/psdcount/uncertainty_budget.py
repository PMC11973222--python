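"""Total expanded measurement uncertainty as a function of particle count.

Precision from the particle count alone is only part of the uncertainty
budget of an electron-microscopy particle-size measurement.  Given a
validation design of repeated datasets (days x within-day replicates), this
module estimates, per subset size N,

* u_IP — intermediate precision: per simulation repetition one random subset
  of N particles is drawn from every validation dataset, the percentile of
  interest is computed per subset, and a one-way variance decomposition with
  day as grouping factor combines within-day and between-day variation:
  u_IP = sqrt(s_between^2 + MS_within) / Dbar (relative), averaged over reps;
* u_tr — trueness versus a certified value: u_tr = sqrt(bias^2 +
  u_certified^2 + se_mean^2) / certified (the standard CRM bias-assessment
  combination); without a certified value a fixed relative u_tr must be
  supplied;
* u_cal — the constant relative calibration uncertainty;

and combines them into the total expanded uncertainty
U_cx = 2 sqrt(u_IP^2 + u_tr^2 + u_cal^2) (k = 2).

U_cx(N) falls with N while the count contribution dominates, then saturates
at the floor set by day-to-day, trueness and calibration effects.  The
breakpoint N_opt of a continuous two-segment linear fit in (log10 N,
log10 U_cx) marks the count beyond which measuring more particles is no
longer effective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .count_precision import bootstrap_percentiles, sigma_of_draws
from .particle_data import (
    Measurand,
    ParticleDataError,
    ParticleDataset,
    ValidationDesign,
    derive_measurand,
)
from .psd_statistics import PERCENTILE_FRACTIONS

DEFAULT_REPS = 500


@dataclass(frozen=True)
class BudgetCurve:
    """Uncertainty components and total expanded uncertainty per subset size.

    All components are relative standard uncertainties except ``u_cx`` and
    ``u_n_component`` which are expanded (k=2).  Invariant (exact):
    u_cx = 2 sqrt(u_ip^2 + u_tr^2 + u_cal^2) elementwise.
    """

    n_grid: np.ndarray
    u_ip: np.ndarray
    u_tr: np.ndarray
    u_cal: float
    u_cx: np.ndarray
    u_n_component: np.ndarray
    measurand: str
    percentile_label: str
    reps: int
    seed: int

    def __post_init__(self):
        for name in ("n_grid", "u_ip", "u_tr", "u_cx", "u_n_component"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if np.any(self.u_ip < 0) or np.any(self.u_tr < 0) or self.u_cal < 0:
            raise ParticleDataError("uncertainty components must be >= 0")

    def to_dict(self) -> dict:
        return {
            "measurand": self.measurand,
            "percentile_label": self.percentile_label,
            "reps": self.reps,
            "seed": self.seed,
            "n": self.n_grid.tolist(),
            "u_ip": self.u_ip.tolist(),
            "u_tr": self.u_tr.tolist(),
            "u_cal": self.u_cal,
            "u_cx": self.u_cx.tolist(),
            "u_n_component": self.u_n_component.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BudgetCurve":
        return cls(
            n_grid=np.array(d["n"]), u_ip=np.array(d["u_ip"]),
            u_tr=np.array(d["u_tr"]), u_cal=float(d["u_cal"]),
            u_cx=np.array(d["u_cx"]), u_n_component=np.array(d["u_n_component"]),
            measurand=d["measurand"], percentile_label=d["percentile_label"],
            reps=int(d["reps"]), seed=int(d["seed"]),
        )


def _design_percentile_draws(design, m, percentile_label, n, reps, seed):
    """(reps, n_datasets) matrix: one percentile per dataset per repetition."""
    p = PERCENTILE_FRACTIONS[percentile_label]
    cols = []
    for day, rep, ds in design.datasets:
        if n > ds.n_tot:
            raise ParticleDataError(
                f"subset size {n} exceeds dataset (day {day}, rep {rep}) size {ds.n_tot}"
            )
        values = derive_measurand(ds, m)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(n), day, rep]))
        idx = rng.integers(0, values.size, size=(reps, n))
        cols.append(np.quantile(values[idx], p, axis=1, method="linear"))
    return np.column_stack(cols)


def _oneway_u_ip(P: np.ndarray, days: np.ndarray):
    """Per-rep one-way variance decomposition of the (reps, J) percentile
    matrix with day as the grouping factor; negative between-day components
    are clipped to zero.  Returns (u_ip_per_rep, grand_mean_per_rep)."""
    uniq = np.unique(days)
    D = uniq.size
    J = P.shape[1]
    gm = P.mean(axis=1)
    day_means = np.column_stack([P[:, days == d].mean(axis=1) for d in uniq])
    r_d = np.array([(days == d).sum() for d in uniq], dtype=float)
    ms_b = ((day_means - gm[:, None]) ** 2 * r_d).sum(axis=1) / (D - 1)
    if J > D:
        within = np.zeros(len(P))
        for k, d in enumerate(uniq):
            within += ((P[:, days == d] - day_means[:, [k]]) ** 2).sum(axis=1)
        ms_w = within / (J - D)
    else:
        ms_w = np.zeros(len(P))  # one replicate per day: no within-day term
    rbar = D / (1.0 / r_d).sum()  # harmonic-mean replicates per day
    s_b2 = np.maximum(0.0, (ms_b - ms_w) / rbar)
    return np.sqrt(s_b2 + ms_w) / gm, gm


def intermediate_precision(
    design: ValidationDesign,
    m: Measurand,
    percentile_label: str = "D50",
    n: int = 100,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> tuple[float, float]:
    """Relative intermediate-precision standard uncertainty at subset size n.

    Returns ``(u_ip, dbar)`` where both are averaged over ``reps``
    subsampling simulations.
    """
    if len(set(design.day_indices)) < 2:
        raise ParticleDataError("intermediate precision needs >= 2 days")
    P = _design_percentile_draws(design, m, percentile_label, n, reps, seed)
    u_per_rep, gm = _oneway_u_ip(P, design.day_indices)
    return float(u_per_rep.mean()), float(gm.mean())


def trueness_uncertainty(
    dbar: float, certified_value: float, u_certified: float, se_mean: float
) -> float:
    """Relative trueness component from a certified reference value:
    u_tr = sqrt((dbar - certified)^2 + u_certified^2 + se_mean^2) / certified."""
    if certified_value <= 0:
        raise ParticleDataError("certified value must be > 0")
    delta = dbar - certified_value
    return math.sqrt(delta**2 + u_certified**2 + se_mean**2) / certified_value


def combine_expanded(u_ip: float, u_tr: float, u_cal: float) -> float:
    """Total expanded uncertainty U_cx = 2 sqrt(u_IP^2 + u_tr^2 + u_cal^2)."""
    return 2.0 * math.sqrt(u_ip**2 + u_tr**2 + u_cal**2)


def budget_curve(
    design: ValidationDesign,
    m: Measurand,
    percentile_label: str = "D50",
    n_grid=None,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    u_tr_fixed: float | None = None,
) -> BudgetCurve:
    """Full uncertainty budget per subset size N.

    Without a certified value in the design, ``u_tr_fixed`` (a relative
    standard uncertainty) is required — there is no silent default.  The
    diagnostic ``u_n_component`` is the count-only expanded uncertainty from
    the pooled particles of all datasets.
    """
    if n_grid is None:
        n_grid = _default_budget_grid(design.min_size)
    g = np.asarray(n_grid, dtype=int)
    if np.any(np.diff(g) <= 0) or g[-1] > design.min_size:
        raise ParticleDataError(
            f"grid must be strictly increasing and <= min dataset size {design.min_size}"
        )
    J = len(design.datasets)
    u_ip_arr = np.empty(len(g))
    u_tr_arr = np.empty(len(g))
    u_nc = np.empty(len(g))
    pooled = _pooled_dataset(design)
    for i, n in enumerate(g):
        P = _design_percentile_draws(design, m, percentile_label, int(n), reps, seed)
        u_per_rep, gm = _oneway_u_ip(P, design.day_indices)
        u_ip_arr[i] = u_per_rep.mean()
        dbar = float(gm.mean())
        if design.certified_value is not None:
            ds_means = P.mean(axis=0)
            se_mean = float(ds_means.std(ddof=1) / math.sqrt(J))
            u_tr_arr[i] = trueness_uncertainty(
                dbar, design.certified_value, design.u_certified or 0.0, se_mean
            )
        elif u_tr_fixed is not None:
            u_tr_arr[i] = u_tr_fixed
        else:
            raise ParticleDataError(
                "no certified value in design: a fixed relative u_tr is required"
            )
        db, sg = sigma_of_draws(
            bootstrap_percentiles(pooled, m, int(n), reps=reps, seed=seed)[
                :, _label_index(percentile_label)
            ]
        )
        u_nc[i] = 2.0 * sg / db
    u_cal = design.u_cal_rel
    u_cx = 2.0 * np.sqrt(u_ip_arr**2 + u_tr_arr**2 + u_cal**2)
    return BudgetCurve(
        n_grid=g, u_ip=u_ip_arr, u_tr=u_tr_arr, u_cal=u_cal, u_cx=u_cx,
        u_n_component=u_nc, measurand=m.name, percentile_label=percentile_label,
        reps=reps, seed=seed,
    )


def _label_index(label: str) -> int:
    from .psd_statistics import PERCENTILE_LABELS

    return PERCENTILE_LABELS.index(label)


def _default_budget_grid(min_size: int, points: int = 12) -> np.ndarray:
    g = np.unique(np.round(np.logspace(1, math.log10(min_size), points)).astype(int))
    g[-1] = min_size
    return np.unique(g)


def _pooled_dataset(design: ValidationDesign) -> ParticleDataset:
    import pandas as pd

    frames = [ds.particles for _, _, ds in design.datasets]
    return ParticleDataset("pooled", pd.concat(frames, ignore_index=True))


# --- piecewise log-log fit and N_opt ---------------------------------------

@dataclass(frozen=True)
class PiecewiseFit:
    """Continuous two-segment linear fit of log10 U_cx on log10 N.

    ``n_opt`` = round(10^breakpoint).  ``identifiable`` is False when the
    two-segment model improves the single-line SSE by less than 5%.
    """

    breakpoint_log10n: float
    slope_left: float
    slope_right: float
    intercept_left: float
    n_opt: int
    sse: float
    identifiable: bool

    def predict(self, n) -> np.ndarray:
        x = np.log10(np.asarray(n, dtype=float))
        c = self.breakpoint_log10n
        y = (
            self.intercept_left
            + self.slope_left * np.minimum(x, c)
            + self.slope_right * np.maximum(0.0, x - c)
        )
        return 10.0**y

    def to_dict(self) -> dict:
        return {
            "breakpoint_log10n": self.breakpoint_log10n,
            "slope_left": self.slope_left,
            "slope_right": self.slope_right,
            "intercept_left": self.intercept_left,
            "n_opt": self.n_opt,
            "sse": self.sse,
            "identifiable": self.identifiable,
        }


def _segment_sse(x, y, c):
    # y = a + b*x + d*max(0, x-c), continuous at c
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - c)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def fit_piecewise(n_grid, u_cx) -> PiecewiseFit:
    """Exhaustive-search continuous two-segment fit; the breakpoint candidate
    set is the interior data positions plus a 10x sub-grid refinement around
    the best candidate, ties broken toward the smaller N_opt."""
    x = np.log10(np.asarray(n_grid, dtype=float))
    y = np.log10(np.asarray(u_cx, dtype=float))
    if len(x) < 6:
        raise ParticleDataError("piecewise fit needs >= 6 grid points")
    if x[-1] - x[0] < 1.0:
        raise ParticleDataError("piecewise fit needs a grid spanning >= 1 decade")

    b1, a1 = np.polyfit(x, y, 1)
    sse0 = float(((y - (a1 + b1 * x)) ** 2).sum())

    candidates = x[2:-2]  # >= 2 points strictly on each side
    best_c, best_sse, best_coef = None, np.inf, None
    for c in candidates:
        sse, coef = _segment_sse(x, y, c)
        if sse < best_sse - 1e-15:
            best_c, best_sse, best_coef = c, sse, coef
    # sub-grid refinement around the best data-position candidate
    i = int(np.searchsorted(x, best_c))
    lo = x[max(i - 1, 1)]
    hi = x[min(i + 1, len(x) - 2)]
    for c in np.linspace(lo, hi, 21):
        sse, coef = _segment_sse(x, y, c)
        if sse < best_sse - 1e-15:
            best_c, best_sse, best_coef = c, sse, coef

    identifiable = sse0 > 0 and (sse0 - best_sse) / sse0 >= 0.05
    a, b, d = best_coef
    return PiecewiseFit(
        breakpoint_log10n=float(best_c),
        slope_left=float(b),
        slope_right=float(b + d),
        intercept_left=float(a),
        n_opt=int(round(10.0**best_c)),
        sse=float(best_sse),
        identifiable=bool(identifiable),
    )
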