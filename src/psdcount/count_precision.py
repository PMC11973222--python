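"""Bootstrap estimation of percentile precision versus particle count.

The engine repeatedly draws with-replacement subsets of ``n`` particles from a
dataset, computes the five percentiles D10..D90 of the chosen measurand per
subset, and summarizes each percentile's spread over ``reps`` repetitions as

    sigma = sample standard deviation of the reps percentile values
            (divisor reps - 1), and
    U_N   = 2 * sigma / dbar        (relative expanded uncertainty, k = 2).

Repeating over a grid of subset sizes N yields a precision curve U_N(N).  On
log-log axes the curve is close to a straight line of slope -1/2 (the
asymptotic 1/sqrt(N) scaling of order-statistic standard errors), so an
ordinary least-squares fit of log10 U_N on log10 N gives a robust way to
invert the curve for the minimum particle count N_m at a target precision.
A cross-validated smoothing-spline fit (isotonic-corrected to non-increasing)
is available as an alternative inversion route.

Reproducibility: one RNG substream per subset size N is derived from the
master seed, so an N grid can be extended without changing the draws at
already-computed sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

from .particle_data import Measurand, ParticleDataError, ParticleDataset, derive_measurand
from .psd_statistics import PERCENTILE_FRACTIONS, PERCENTILE_LABELS

DEFAULT_REPS = 500
GRID_FLOOR = 10
DEFAULT_GRID_POINTS = 30


class DegenerateDispersionError(ParticleDataError):
    """Raised when the data have zero dispersion so the log-log fit of U_N is
    undefined; carries the (all-zero) ``u_n`` vector as diagnostics."""

    def __init__(self, message: str, u_n: np.ndarray):
        super().__init__(message)
        self.u_n = u_n


def default_grid(n_tot: int, points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Log-spaced integer grid from 10 to ``n_tot`` (deduplicated, ends kept)."""
    if n_tot < GRID_FLOOR:
        raise ParticleDataError(f"dataset too small for a grid (n_tot={n_tot})")
    g = np.unique(
        np.round(np.logspace(math.log10(GRID_FLOOR), math.log10(n_tot), points)).astype(int)
    )
    g[0], g[-1] = GRID_FLOOR, n_tot
    return np.unique(g)


def _substream(seed: int, n: int) -> np.random.Generator:
    # one substream per subset size: grids extend without reshuffling
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(n)]))


def bootstrap_percentiles(
    dataset: ParticleDataset,
    m: Measurand,
    n: int,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``reps`` with-replacement subsets of size ``n`` and return a
    (reps, 5) matrix of their D10..D90 percentiles.

    Bit-identical for identical (dataset, measurand, n, reps, seed).
    """
    if n < GRID_FLOOR:
        raise ParticleDataError(f"subset size below floor {GRID_FLOOR}: {n}")
    if reps < 2:
        raise ParticleDataError("need at least 2 repetitions")
    values = derive_measurand(dataset, m)
    rng = _substream(seed, n)
    idx = rng.integers(0, values.size, size=(reps, n))
    fracs = [PERCENTILE_FRACTIONS[l] for l in PERCENTILE_LABELS]
    q = np.quantile(values[idx], fracs, axis=1, method="linear")
    return np.ascontiguousarray(q.T)


def sigma_of_draws(draws) -> tuple[float, float]:
    """Mean and sample standard deviation (divisor reps - 1) of percentile
    draws — at 500 repetitions the divisor is 499."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ParticleDataError("need at least 2 draws")
    return float(draws.mean()), float(draws.std(ddof=1))


def u_n(dbar: float, sigma: float) -> float:
    """Relative expanded uncertainty U_N = 2 * sigma / dbar (k = 2).

    Dimensionless fraction; multiply by 100 for percent.
    """
    if dbar <= 0:
        raise ParticleDataError("dbar must be positive")
    if sigma < 0:
        raise ParticleDataError("sigma must be >= 0")
    return 2.0 * sigma / dbar


@dataclass(frozen=True)
class PrecisionCurve:
    """Per-percentile precision versus subset size, with log-log fit.

    ``u_n`` is the relative expanded uncertainty (k=2) at each grid size;
    ``loglog_slope``/``loglog_intercept`` describe the OLS fit of
    log10(u_n) on log10(n).
    """

    measurand: str
    percentile_label: str
    n_grid: np.ndarray
    dbar: np.ndarray
    sigma: np.ndarray
    u_n: np.ndarray
    reps: int
    seed: int
    loglog_slope: float
    loglog_intercept: float
    fit_r2: float

    def __post_init__(self):
        for name in ("n_grid", "dbar", "sigma", "u_n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        k = len(self.n_grid)
        if not (len(self.dbar) == len(self.sigma) == len(self.u_n) == k):
            raise ParticleDataError("curve arrays must have equal length")
        if np.any(self.sigma < 0) or np.any(self.u_n < 0):
            raise ParticleDataError("sigma and u_n must be >= 0")

    @property
    def n_tot(self) -> int:
        return int(self.n_grid[-1])

    def to_dict(self) -> dict:
        return {
            "measurand": self.measurand,
            "percentile_label": self.percentile_label,
            "reps": self.reps,
            "seed": self.seed,
            "n": self.n_grid.tolist(),
            "dbar": self.dbar.tolist(),
            "sigma": self.sigma.tolist(),
            "u_n": self.u_n.tolist(),
            "fit": {
                "slope": self.loglog_slope,
                "intercept": self.loglog_intercept,
                "r2": self.fit_r2,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrecisionCurve":
        return cls(
            measurand=d["measurand"],
            percentile_label=d["percentile_label"],
            n_grid=np.array(d["n"]),
            dbar=np.array(d["dbar"]),
            sigma=np.array(d["sigma"]),
            u_n=np.array(d["u_n"]),
            reps=int(d["reps"]),
            seed=int(d["seed"]),
            loglog_slope=float(d["fit"]["slope"]),
            loglog_intercept=float(d["fit"]["intercept"]),
            fit_r2=float(d["fit"]["r2"]),
        )


def fit_loglog(n_grid, u_vals) -> tuple[float, float, float]:
    """OLS fit of log10(u) on log10(n); returns (slope, intercept, r2)."""
    n_grid = np.asarray(n_grid, dtype=float)
    u_vals = np.asarray(u_vals, dtype=float)
    if np.any(u_vals <= 0):
        raise DegenerateDispersionError(
            "zero-dispersion data: U_N contains zeros, log-log fit undefined",
            u_n=u_vals,
        )
    x, y = np.log10(n_grid), np.log10(u_vals)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), float(r2)


def _curve_tables(dataset, m, n_grid, reps, seed):
    """dbar/sigma matrices (len(grid), 5) for all percentile labels at once."""
    dbar = np.empty((len(n_grid), 5))
    sigma = np.empty((len(n_grid), 5))
    for i, n in enumerate(n_grid):
        draws = bootstrap_percentiles(dataset, m, int(n), reps=reps, seed=seed)
        dbar[i] = draws.mean(axis=0)
        sigma[i] = draws.std(axis=0, ddof=1)
    return dbar, sigma


def _resolve_grid(dataset, n_grid):
    if n_grid is None:
        return default_grid(dataset.n_tot)
    g = np.asarray(n_grid, dtype=int)
    if np.any(np.diff(g) <= 0):
        raise ParticleDataError("n_grid must be strictly increasing")
    if g[0] < GRID_FLOOR or g[-1] > dataset.n_tot:
        raise ParticleDataError(
            f"n_grid must lie in [{GRID_FLOOR}, n_tot={dataset.n_tot}]"
        )
    return g


def precision_curve(
    dataset: ParticleDataset,
    m: Measurand,
    percentile_label: str = "D50",
    n_grid=None,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> PrecisionCurve:
    """Full precision curve U_N(N) for one percentile of one measurand.

    The grid defaults to 30 log-spaced integers from 10 to n_tot.  Raises
    :class:`DegenerateDispersionError` for zero-dispersion data (u_n all
    zero, reported in the exception's diagnostics).
    """
    if percentile_label not in PERCENTILE_LABELS:
        raise ParticleDataError(f"unknown percentile label {percentile_label!r}")
    g = _resolve_grid(dataset, n_grid)
    dbar, sigma = _curve_tables(dataset, m, g, reps, seed)
    j = PERCENTILE_LABELS.index(percentile_label)
    u_vals = 2.0 * sigma[:, j] / dbar[:, j]
    slope, intercept, r2 = fit_loglog(g, u_vals)
    return PrecisionCurve(
        measurand=m.name,
        percentile_label=percentile_label,
        n_grid=g,
        dbar=dbar[:, j],
        sigma=sigma[:, j],
        u_n=u_vals,
        reps=reps,
        seed=seed,
        loglog_slope=slope,
        loglog_intercept=intercept,
        fit_r2=r2,
    )


def fit_spline(curve: PrecisionCurve, smoothing: float | None = None):
    """Smooth monotone non-increasing fit of U_N(N), returned as a callable.

    The spline is fitted in log-log coordinates; if ``smoothing`` is None the
    smoothing factor is chosen by leave-one-out cross-validation over a
    logarithmic candidate grid, then the evaluated curve is isotonic-corrected
    (running minimum) to be non-increasing in N.  The callable accepts scalar
    or array N, clipped to [min grid, max grid].
    """
    g = curve.n_grid
    if len(g) < 5:
        raise ParticleDataError("spline fit needs at least 5 grid points")
    if np.any(curve.u_n <= 0):
        raise DegenerateDispersionError(
            "zero-dispersion data: spline fit undefined", u_n=curve.u_n
        )
    x = np.log10(g.astype(float))
    y = np.log10(curve.u_n)

    if smoothing is None:
        scatter = max(float(np.var(np.diff(y)) / 2.0), 1e-8)
        candidates = scatter * len(x) * np.logspace(-2, 2, 9)
        best, best_err = candidates[0], np.inf
        for s in candidates:
            errs = []
            for i in range(len(x)):
                mask = np.arange(len(x)) != i
                try:
                    sp = UnivariateSpline(x[mask], y[mask], k=3, s=s * (len(x) - 1) / len(x))
                except Exception:
                    errs = None
                    break
                errs.append((float(sp(x[i])) - y[i]) ** 2)
            if errs is not None and np.mean(errs) < best_err:
                best, best_err = s, float(np.mean(errs))
        smoothing = best
    sp = UnivariateSpline(x, y, k=3, s=smoothing)

    fine_x = np.linspace(x[0], x[-1], 512)
    fine_y = np.minimum.accumulate(sp(fine_x))  # isotonic: non-increasing in N

    def u_of_n(n):
        lx = np.clip(np.log10(np.asarray(n, dtype=float)), x[0], x[-1])
        out = 10.0 ** np.interp(lx, fine_x, fine_y)
        return float(out) if np.isscalar(n) else out

    return u_of_n


@dataclass(frozen=True)
class MinCountResult:
    """Minimum particle count with provenance flags.

    ``flag`` is None, "at_grid_floor" (curve already below target at N=10) or
    "extrapolated_beyond_n_tot".
    """

    n_m: int
    u_target: float
    method: str
    flag: str | None = None

    def __int__(self):
        return self.n_m


def minimum_count(
    curve: PrecisionCurve, u_target: float, method: str = "loglog"
) -> MinCountResult:
    """Smallest integer N with fitted U_N(N) <= ``u_target`` (a fraction).

    Default inversion uses the log-log line: N_m = ceil(10 ** ((log10 u -
    intercept) / slope)); the spline route searches the monotone fitted curve.
    Clamped to the grid floor (10) when already below target there;
    extrapolation beyond n_tot is permitted but flagged.
    """
    if not 0.0 < u_target < 1.0:
        raise ParticleDataError("u_target must be a fraction in (0, 1)")
    if method == "loglog":
        a, b = curve.loglog_slope, curve.loglog_intercept
        if a >= 0:
            raise ParticleDataError(f"non-decreasing precision curve (slope={a:.3g})")
        if a * math.log10(GRID_FLOOR) + b <= math.log10(u_target):
            return MinCountResult(GRID_FLOOR, u_target, method, "at_grid_floor")
        n_m = math.ceil(10.0 ** ((math.log10(u_target) - b) / a))
        flag = "extrapolated_beyond_n_tot" if n_m > curve.n_tot else None
        return MinCountResult(int(n_m), u_target, method, flag)
    if method == "spline":
        f = fit_spline(curve)
        grid = np.arange(GRID_FLOOR, curve.n_tot + 1)
        vals = f(grid)
        below = np.flatnonzero(vals <= u_target)
        if below.size == 0:
            # fall back to the log-log tail beyond the data range
            res = minimum_count(curve, u_target, method="loglog")
            return MinCountResult(res.n_m, u_target, method, "extrapolated_beyond_n_tot")
        n_m = int(grid[below[0]])
        flag = "at_grid_floor" if n_m == GRID_FLOOR and vals[0] <= u_target else None
        return MinCountResult(n_m, u_target, method, flag)
    raise ParticleDataError(f"unknown inversion method {method!r}")


def percentile_profile(
    dataset: ParticleDataset,
    m: Measurand,
    u_target: float,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    n_grid=None,
    method: str = "loglog",
) -> dict[str, MinCountResult]:
    """Minimum particle count per percentile D10..D90 at one target U_N.

    The bootstrap draws are shared across the five percentiles (one pass over
    the N grid), so the profile costs the same as a single curve.
    """
    g = _resolve_grid(dataset, n_grid)
    dbar, sigma = _curve_tables(dataset, m, g, reps, seed)
    out: dict[str, MinCountResult] = {}
    for j, label in enumerate(PERCENTILE_LABELS):
        u_vals = 2.0 * sigma[:, j] / dbar[:, j]
        slope, intercept, r2 = fit_loglog(g, u_vals)
        curve = PrecisionCurve(
            measurand=m.name, percentile_label=label, n_grid=g,
            dbar=dbar[:, j], sigma=sigma[:, j], u_n=u_vals, reps=reps, seed=seed,
            loglog_slope=slope, loglog_intercept=intercept, fit_r2=r2,
        )
        out[label] = minimum_count(curve, u_target, method=method)
    return out
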