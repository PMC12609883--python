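"""Orbit measurement records and proportional shape indices.

An orbit (the bony eye socket) is characterized here by three linear
dimensions in millimetres: depth (D, anteroposterior), height (H,
vertical rim-to-rim) and width (W, mediolateral).  Three dimensionless
indices standardize shape across individuals and imaging modalities:

* depth index  ``DI = D / W``
* width index  ``WI = W / H``
* height index ``HI = H / W``

``WI`` and ``HI`` are reciprocals, so ``HI * WI = 1`` identically.  All
indices are kept at full floating-point precision; rounding (half away
from zero, two decimals) happens only at presentation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "DIMENSION_COLUMNS",
    "OrbitMeasurement",
    "ProportionIndices",
    "compute_indices",
    "add_indices",
    "read_measurements",
    "write_measurements",
    "round_display",
]

#: canonical CSV column names for the three linear dimensions
DIMENSION_COLUMNS = ("depth_mm", "height_mm", "width_mm")

#: full canonical column order of the measurement CSV dialect
CSV_COLUMNS = (
    "orbit_id",
    "side",
    "sex",
    "age_years",
    "depth_mm",
    "height_mm",
    "width_mm",
    "modality",
    "true_type",
)

SIDES = frozenset({"left", "right", "unknown"})
SEXES = frozenset({"M", "F", "unknown"})
MODALITIES = frozenset({"CBCT", "FBCT", "synthetic", "unknown"})

#: default plausibility window (mm); values outside warn but are kept
PLAUSIBLE_MM = (15.0, 70.0)


@dataclass(frozen=True)
class OrbitMeasurement:
    """One orbit's three linear dimensions plus demographic covariates.

    Dimensions must be strictly positive.  Values outside the
    plausibility window trigger a warning, never a rejection: unusual
    orbits (paediatric, post-traumatic) are data, not errors.
    """

    orbit_id: str
    depth_mm: float
    height_mm: float
    width_mm: float
    side: str = "unknown"
    sex: str = "unknown"
    age_years: Optional[float] = None
    modality: str = "unknown"
    true_type: Optional[str] = None
    plausible_mm: tuple = field(default=PLAUSIBLE_MM, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("depth_mm", "height_mm", "width_mm"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {sorted(SIDES)}, got {self.side!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {sorted(SEXES)}, got {self.sex!r}")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"modality must be one of {sorted(MODALITIES)}, got {self.modality!r}"
            )
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"age_years must be non-negative, got {self.age_years!r}")
        lo, hi = self.plausible_mm
        for name in ("depth_mm", "height_mm", "width_mm"):
            value = getattr(self, name)
            if not lo <= value <= hi:
                warnings.warn(
                    f"orbit {self.orbit_id!r}: {name}={value} mm outside the "
                    f"plausibility window [{lo}, {hi}] mm",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class ProportionIndices:
    """Dimensionless shape descriptors DI = D/W, WI = W/H, HI = H/W."""

    di: float
    wi: float
    hi: float


def compute_indices(
    m: "OrbitMeasurement | None" = None,
    *,
    depth_mm: Optional[float] = None,
    height_mm: Optional[float] = None,
    width_mm: Optional[float] = None,
) -> ProportionIndices:
    """Compute the three proportional indices for one orbit.

    Accepts either an :class:`OrbitMeasurement` or the three raw
    dimensions as keyword arguments.  Indices are scale invariant:
    multiplying all three dimensions by any positive constant leaves
    them unchanged.

    Raises
    ------
    ValueError
        If height or width is zero or negative (the ratios are undefined).
    """
    if m is not None:
        depth_mm, height_mm, width_mm = m.depth_mm, m.height_mm, m.width_mm
    if depth_mm is None or height_mm is None or width_mm is None:
        raise ValueError("provide a measurement or all three dimensions")
    if height_mm <= 0 or width_mm <= 0:
        raise ValueError("height and width must be strictly positive to form ratios")
    return ProportionIndices(
        di=depth_mm / width_mm,
        wi=width_mm / height_mm,
        hi=height_mm / width_mm,
    )


def add_indices(frame: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of *frame* with ``di``, ``wi``, ``hi`` columns appended."""
    missing = [c for c in DIMENSION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing dimension columns: {missing}")
    if (frame["height_mm"] <= 0).any() or (frame["width_mm"] <= 0).any():
        raise ValueError("height and width must be strictly positive to form ratios")
    out = frame.copy()
    out["di"] = out["depth_mm"] / out["width_mm"]
    out["wi"] = out["width_mm"] / out["height_mm"]
    out["hi"] = out["height_mm"] / out["width_mm"]
    return out


def round_display(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for printed tables.

    Python's built-in ``round`` is banker's rounding; descriptive tables
    in the morphometric literature round 0.005 up, so presentation code
    goes through this helper.
    """
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def read_measurements(
    path: "str | Path",
    *,
    on_bad_rows: str = "raise",
    plausible_mm: tuple = PLAUSIBLE_MM,
) -> pd.DataFrame:
    """Read a measurement table from CSV.

    The file must contain the three dimension columns
    ``depth_mm, height_mm, width_mm``; covariate columns are optional and
    missing values become ``"unknown"`` (categoricals) or ``NaN`` (age).

    Parameters
    ----------
    on_bad_rows:
        ``"raise"`` (default) raises a :class:`ValueError` listing the
        0-based row indices whose dimensions cannot be parsed or are
        non-positive; ``"skip"`` drops them with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"orbit_id": str, "true_type": str})
    if frame.empty:
        raise ValueError(f"{path}: no measurement rows")
    missing = [c for c in DIMENSION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    dims = frame[list(DIMENSION_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = dims.isna().any(axis=1) | (dims <= 0).any(axis=1)
    if bad.any():
        rows = [int(i) for i in frame.index[bad]]
        msg = f"{path}: unparseable or non-positive dimensions in row(s) {rows}"
        if on_bad_rows == "raise":
            raise ValueError(msg)
        warnings.warn(msg + " — rows dropped", stacklevel=2)
        frame = frame.loc[~bad].copy()
        dims = dims.loc[~bad]
    frame[list(DIMENSION_COLUMNS)] = dims.astype(float)

    if "orbit_id" not in frame.columns:
        frame["orbit_id"] = [f"row{i}" for i in frame.index]
    for col, allowed in (("side", SIDES), ("sex", SEXES), ("modality", MODALITIES)):
        if col not in frame.columns:
            frame[col] = "unknown"
        else:
            frame[col] = frame[col].fillna("unknown")
            unknown = ~frame[col].isin(allowed)
            if unknown.any():
                frame.loc[unknown, col] = "unknown"
    if "age_years" in frame.columns:
        frame["age_years"] = pd.to_numeric(frame["age_years"], errors="coerce")
    else:
        frame["age_years"] = float("nan")
    if "true_type" not in frame.columns:
        frame["true_type"] = None

    lo, hi = plausible_mm
    outside = ((dims < lo) | (dims > hi)).any(axis=1)
    if outside.any():
        warnings.warn(
            f"{path}: {int(outside.sum())} row(s) have dimensions outside the "
            f"plausibility window [{lo}, {hi}] mm",
            stacklevel=2,
        )
    ordered = [c for c in CSV_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in ordered]
    return frame[ordered + extra].reset_index(drop=True)


def write_measurements(
    frame: pd.DataFrame, path: "str | Path", *, indices: bool = False
) -> None:
    """Write a measurement table as CSV (UTF-8, decimal point).

    With ``indices=True`` the three proportional indices are appended as
    ``di, wi, hi`` columns.
    """
    out = add_indices(frame) if indices else frame
    out.to_csv(path, index=False, encoding="utf-8")


def records_to_frame(records: Iterable[OrbitMeasurement]) -> pd.DataFrame:
    """Assemble :class:`OrbitMeasurement` records into the canonical table."""
    rows = [
        {
            "orbit_id": r.orbit_id,
            "side": r.side,
            "sex": r.sex,
            "age_years": r.age_years,
            "depth_mm": r.depth_mm,
            "height_mm": r.height_mm,
            "width_mm": r.width_mm,
            "modality": r.modality,
            "true_type": r.true_type,
        }
        for r in records
    ]
    if not rows:
        raise ValueError("no records")
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))
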