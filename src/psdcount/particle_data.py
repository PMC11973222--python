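"""Domain types, validation and I/O for per-particle measurement tables.

The package operates on *number-based* particle measurand tables: one row per
constituent particle, one column per size measurand (nm).  Canonical column
names are ``fmin_nm`` (minimum Feret diameter), ``fmax_nm`` (maximum Feret
diameter), ``micd_nm`` (maximum inscribed circular diameter) and ``ecd_nm``
(area-equivalent circular diameter).  The aspect ratio AR = Fmax/Fmin is a
derived shape measurand and is never stored in input tables.

Tables produced by the ImageJ ParticleSizer plugin are supported through a
best-effort header map (``dialect="particlesizer"``); any other dialect can be
handled with an explicit ``column_map``.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("psdcount")

SCHEMA_VERSION = "1"

#: Canonical size columns, in writing order.  All values are nm.
SIZE_COLUMNS = ("fmin_nm", "fmax_nm", "micd_nm", "ecd_nm")


class ParticleDataError(ValueError):
    """Raised when a particle table violates a structural invariant."""


class Measurand(enum.Enum):
    """A measurand of the per-particle table.

    Size measurands (FMIN, FMAX, MICD, ECD) map to stored columns; the aspect
    ratio AR (= Fmax/Fmin) has kind ``shape`` and is always derived.
    """

    FMIN = ("fmin_nm", "size")
    FMAX = ("fmax_nm", "size")
    MICD = ("micd_nm", "size")
    ECD = ("ecd_nm", "size")
    AR = (None, "shape")

    def __init__(self, column: str | None, kind: str):
        self.column = column
        self.kind = kind

    @classmethod
    def parse(cls, name: str) -> "Measurand":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ParticleDataError(f"unknown measurand {name!r}") from None


@dataclass(frozen=True)
class ParticleDataset:
    """A validated per-particle measurement table with material metadata.

    Invariants (checked on construction): at least one canonical size column,
    all stored values finite and > 0, fmax >= fmin wherever both are present,
    and at least two particles.
    """

    material_id: str
    particles: pd.DataFrame

    def __post_init__(self):
        df = self.particles
        cols = [c for c in SIZE_COLUMNS if c in df.columns]
        if not cols:
            raise ParticleDataError(
                f"no recognizable size column among {SIZE_COLUMNS}"
            )
        object.__setattr__(
            self, "particles", df.loc[:, cols].reset_index(drop=True).astype(float)
        )
        df = self.particles
        if len(df) < 2:
            raise ParticleDataError("a particle dataset needs at least 2 rows")
        vals = df.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ParticleDataError("size values must be finite and > 0")
        if "fmin_nm" in df.columns and "fmax_nm" in df.columns:
            bad = np.flatnonzero(df["fmax_nm"].to_numpy() < df["fmin_nm"].to_numpy())
            if bad.size:
                raise ParticleDataError(
                    f"fmax < fmin in rows {bad.tolist()[:20]}"
                    + (" ..." if bad.size > 20 else "")
                )

    @property
    def n_tot(self) -> int:
        """Total number of measured particles (rows)."""
        return len(self.particles)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.particles.columns)

    def has_measurand(self, m: Measurand) -> bool:
        if m is Measurand.AR:
            return {"fmin_nm", "fmax_nm"} <= set(self.particles.columns)
        return m.column in self.particles.columns


@dataclass(frozen=True)
class ValidationDesign:
    """Repeated measurements organised as days x within-day replicates.

    ``datasets`` is an ordered collection of ``(day_index, replicate_index,
    ParticleDataset)`` tuples (indices >= 1).  ``certified_value`` and
    ``u_certified`` (both nm) describe an optional certified reference value
    used for the trueness component; ``u_cal_rel`` is the constant relative
    standard uncertainty of the instrument calibration.  ``ground_truth``
    optionally records generator-known quantities (realized day factors,
    applied bias) for synthetic designs.
    """

    datasets: tuple[tuple[int, int, ParticleDataset], ...]
    certified_value: float | None = None
    u_certified: float | None = None
    u_cal_rel: float = 0.0
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "datasets", tuple(self.datasets))
        if len(self.datasets) < 2:
            raise ParticleDataError("a validation design needs >= 2 datasets")
        days = {d for d, _, _ in self.datasets}
        if len(days) < 2:
            raise ParticleDataError("a validation design needs >= 2 distinct days")
        if any(d < 1 or r < 1 for d, r, _ in self.datasets):
            raise ParticleDataError("day and replicate indices start at 1")
        if self.u_cal_rel < 0:
            raise ParticleDataError("u_cal_rel must be >= 0")
        if self.u_certified is not None and self.u_certified < 0:
            raise ParticleDataError("u_certified must be >= 0")

    @property
    def day_indices(self) -> np.ndarray:
        return np.array([d for d, _, _ in self.datasets])

    @property
    def min_size(self) -> int:
        return min(ds.n_tot for _, _, ds in self.datasets)


# --- reading / writing ------------------------------------------------------

#: Best-effort header map for ImageJ ParticleSizer result tables (the exact
#: header set varies across plugin versions; user column maps override).
_PARTICLESIZER_MAP = {
    "minferet": "fmin_nm",
    "min feret": "fmin_nm",
    "min. feret": "fmin_nm",
    "feret": "fmax_nm",
    "maxferet": "fmax_nm",
    "ecd": "ecd_nm",
    "area equivalent diameter": "ecd_nm",
    "area-equivalent diameter": "ecd_nm",
    "diameter": "ecd_nm",
    "micd": "micd_nm",
    "inscribed circle diameter": "micd_nm",
    "max inscribed circle": "micd_nm",
}


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    counts = {sep: header.count(sep) for sep in (",", "\t", ";")}
    sep = max(counts, key=counts.get)
    return sep if counts[sep] > 0 else ","


def read_particle_table(
    path,
    dialect: str = "generic",
    column_map: dict | None = None,
    material_id: str | None = None,
) -> ParticleDataset:
    """Read a delimited per-particle table into a validated ParticleDataset.

    ``dialect`` is ``"generic"`` (canonical headers) or ``"particlesizer"``
    (ImageJ ParticleSizer result-table headers).  ``column_map`` maps raw
    header names to canonical ones and takes precedence over the dialect map.
    Delimiters comma/tab/semicolon are auto-detected; decimal point only;
    scientific notation is accepted.  Rows containing non-finite or
    non-positive values in any recognized size column are dropped with a
    logged count; rows with fmax < fmin are an error (they indicate upstream
    segmentation faults and must be surfaced).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("generic", "particlesizer"):
        raise ParticleDataError(f"unknown dialect {dialect!r}")
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep)

    mapping: dict[str, str] = {}
    for col in raw.columns:
        key = str(col).strip()
        low = key.lower()
        if column_map and key in column_map:
            mapping[col] = column_map[key]
        elif low in SIZE_COLUMNS:
            mapping[col] = low
        elif dialect == "particlesizer" and low in _PARTICLESIZER_MAP:
            mapping[col] = _PARTICLESIZER_MAP[low]
    df = raw.rename(columns=mapping)
    cols = [c for c in SIZE_COLUMNS if c in df.columns]
    if not cols:
        raise ParticleDataError(
            f"no recognizable size column in {path.name}; headers: "
            f"{list(raw.columns)}"
        )
    df = df.loc[:, cols].apply(pd.to_numeric, errors="coerce")

    ok = np.ones(len(df), dtype=bool)
    vals = df.to_numpy(dtype=float)
    ok &= np.all(np.isfinite(vals) & (vals > 0), axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d row(s) with non-finite or non-positive values",
            path.name,
            n_dropped,
        )
    df = df.loc[ok]

    if "fmin_nm" in df.columns and "fmax_nm" in df.columns:
        bad = np.flatnonzero(df["fmax_nm"].to_numpy() < df["fmin_nm"].to_numpy())
        if bad.size:
            rows = df.index[bad].tolist()
            raise ParticleDataError(
                f"{path.name}: fmax < fmin in row(s) {rows[:20]}"
                + (" ..." if bad.size > 20 else "")
            )
    return ParticleDataset(material_id=material_id or path.stem, particles=df)


def write_particle_table(dataset: ParticleDataset, path) -> None:
    """Write a dataset as canonical CSV; values keep full (repr) precision so
    that a read-back compares equal."""
    path = Path(path)
    dataset.particles.to_csv(path, index=False)


def derive_measurand(dataset: ParticleDataset, m: Measurand) -> np.ndarray:
    """Return one value per particle for measurand ``m``.

    Size measurands are returned as stored; AR_i = fmax_i / fmin_i and is
    >= 1 for every particle of a valid dataset.
    """
    df = dataset.particles
    if m is Measurand.AR:
        if not dataset.has_measurand(m):
            raise ParticleDataError("AR requires both fmin_nm and fmax_nm columns")
        return (df["fmax_nm"] / df["fmin_nm"]).to_numpy()
    if m.column not in df.columns:
        raise ParticleDataError(f"measurand {m.name} not present in dataset")
    return df[m.column].to_numpy()


# --- JSON result helpers ----------------------------------------------------

def save_json(obj: dict, path) -> None:
    """Write a result object as JSON, stamping the schema version."""
    payload = {"schema_version": SCHEMA_VERSION, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
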