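"""Ground verification of raster heights against field-measured points.

Surveys are checked by manually measuring vegetation height at a set of
points (typically 20 scrub + 10 ground-vegetation points per site, with
some deliberately close to the 1 m band boundary) and comparing each
with the height raster: the point's cell must fall in the expected band,
and the signed height error is recorded.  The report carries the full
per-point error table plus the two consistent-error bounds normally
quoted: the largest overestimate (raster above field measurement) and
the largest underestimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import GROUND, SCRUB, ClassRaster, HeightBandScheme
from .raster import GridRaster

__all__ = ["VerificationPoint", "VerificationReport", "verify_points", "read_points_csv"]


@dataclass
class VerificationPoint:
    """A field-measured check point: location, tape-measured height, expected band."""

    x: float
    y: float
    measured_height_m: float
    expected_band: str

    def __post_init__(self) -> None:
        if self.measured_height_m < 0:
            raise ValueError(f"measured height must be ≥ 0, got {self.measured_height_m}")
        if self.expected_band not in (GROUND, SCRUB):
            raise ValueError(
                f"expected_band must be {GROUND} or {SCRUB}, got {self.expected_band!r}"
            )


@dataclass
class VerificationReport:
    """Per-point comparison table plus the consistent-error extrema.

    ``max_overestimate_m`` is the largest positive (raster − measured)
    difference, ``max_underestimate_m`` the largest positive
    (measured − raster); both are 0 when no point errs in that direction.
    Unsampleable points (outside the extent or on nodata) are kept in the
    table, flagged, and excluded from the statistics.
    """

    table: pd.DataFrame
    n_points: int
    n_sampled: int
    n_band_mismatches: int
    max_overestimate_m: float
    max_underestimate_m: float

    def __str__(self) -> str:
        return (
            f"{self.n_sampled}/{self.n_points} points sampled, "
            f"{self.n_band_mismatches} band mismatches; "
            f"overestimate ≤ {self.max_overestimate_m * 100:.1f} cm, "
            f"underestimate ≤ {self.max_underestimate_m * 100:.1f} cm"
        )


def verify_points(
    chm: GridRaster, cls: ClassRaster, points: list[VerificationPoint]
) -> VerificationReport:
    """Compare field points against the height raster and its classification.

    Sampling is nearest-cell — the value of the cell containing each
    point — because band membership is a per-cell property in this
    pipeline, not an interpolated one.  A warning-level inconsistency
    (a point whose *measured* height does not match its declared band
    under the active scheme) is reported in the table, not raised.
    """
    chm.require_same_grid(cls.raster, what="CHM and class raster")
    scheme: HeightBandScheme = cls.scheme
    rows = []
    for p in points:
        row, col = chm.transform.index_of(p.x, p.y)
        in_extent = 0 <= row < chm.shape[0] and 0 <= col < chm.shape[1]
        sampled = bool(in_extent and chm.data_mask[row, col])
        rec = {
            "x": p.x,
            "y": p.y,
            "measured_height_m": p.measured_height_m,
            "expected_band": p.expected_band,
            "declared_band_consistent": scheme.band_of(p.measured_height_m)
            == p.expected_band,
            "sampled": sampled,
            "raster_height_m": float("nan"),
            "raster_band": None,
            "band_match": None,
            "error_m": float("nan"),
        }
        if sampled:
            h = float(chm.values[row, col])
            band = cls.codes.label_of(int(cls.values[row, col]))
            rec.update(
                raster_height_m=h,
                raster_band=band,
                band_match=band == p.expected_band,
                error_m=h - p.measured_height_m,
            )
        rows.append(rec)
    table = pd.DataFrame(rows)
    sampled = table[table["sampled"]]
    errors = sampled["error_m"]
    return VerificationReport(
        table=table,
        n_points=len(points),
        n_sampled=int(table["sampled"].sum()),
        n_band_mismatches=int((~sampled["band_match"].astype(bool)).sum()),
        max_overestimate_m=float(errors[errors > 0].max()) if (errors > 0).any() else 0.0,
        max_underestimate_m=float(-errors[errors < 0].min()) if (errors < 0).any() else 0.0,
    )


def read_points_csv(path) -> list[VerificationPoint]:
    """Load verification points from a CSV with columns x,y,measured_height_m,expected_band."""
    df = pd.read_csv(path)
    required = {"x", "y", "measured_height_m", "expected_band"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"points CSV is missing columns: {sorted(missing)}")
    return [
        VerificationPoint(
            x=float(r.x),
            y=float(r.y),
            measured_height_m=float(r.measured_height_m),
            expected_band=str(r.expected_band).upper(),
        )
        for r in df.itertuples()
    ]
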