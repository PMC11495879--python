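"""Scrub cover accounting: stands, areas, site percentages, scenarios.

A *stand* is a maximal connected group of scrub cells.  Connectivity is
configurable (4- or 8-adjacency; default 8, the more inclusive reading of
a contiguous stand — two scrub cells touching at a corner belong to the
same patch).  Cover percentage is simply scrub area divided by the site
denominator area × 100; the denominator may be the digitised boundary
area or an externally quoted official site area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import GridRaster

__all__ = [
    "StandTable",
    "CoverSummary",
    "EpochChange",
    "label_stands",
    "cover_summary",
    "compare_epochs",
    "scenario_remove_stands",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class StandTable:
    """Labelled connected scrub components with per-stand statistics.

    ``table`` has one row per stand: ``stand_id`` (consecutive from 1, in
    row-major order of each stand's first cell), ``cell_count``,
    ``area_m2`` (= cell_count × cell_area, exactly) and the cell-centre
    centroid.  ``labels`` is the label grid (0 = not scrub).
    """

    table: pd.DataFrame
    labels: np.ndarray | None
    connectivity: int
    cell_area: float

    @property
    def n_stands(self) -> int:
        return len(self.table)

    @property
    def total_area_m2(self) -> float:
        # total cells × cell area, not a float sum of per-stand areas, so the
        # identity total == n_scrub_cells × cell_area holds exactly
        return float(self.table["cell_count"].sum()) * self.cell_area


def label_stands(scrub_mask: GridRaster, connectivity: int = 8) -> StandTable:
    """Delineate scrub stands by connected-component labelling.

    ``scrub_mask`` must be binary: data cells are 0/1 (or all 1 with
    non-scrub as nodata, as produced by set-null isolation).  Stand ids
    are deterministic: consecutive from 1, ordered by each stand's first
    cell in a row-major scan.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    data = scrub_mask.data_mask
    vals = scrub_mask.values
    stray = np.setdiff1d(np.unique(vals[data]), [0, 1])
    if stray.size:
        raise ValueError(f"scrub mask is not binary: found values {stray.tolist()}")
    binary = data & (vals == 1)

    labels, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    if n:
        # renumber to row-major first-occurrence order (deterministic contract)
        flat = labels.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        nz = np.flatnonzero(flat)
        # reversed so earlier indices win
        first[flat[nz[::-1]]] = nz[::-1]
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=np.int64)
        remap[1 + order] = np.arange(1, n + 1)
        labels = remap[labels]

    cell_area = scrub_mask.cell_area
    ids = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    rows_idx, cols_idx = np.nonzero(labels)
    if n:
        X = scrub_mask.transform.origin_x + (cols_idx + 0.5) * scrub_mask.transform.cell_w
        Y = scrub_mask.transform.origin_y - (rows_idx + 0.5) * scrub_mask.transform.cell_h
        lab = labels[rows_idx, cols_idx]
        cx = np.bincount(lab, weights=X, minlength=n + 1)[1:] / counts
        cy = np.bincount(lab, weights=Y, minlength=n + 1)[1:] / counts
    else:
        cx = cy = np.array([])
    table = pd.DataFrame(
        {
            "stand_id": ids,
            "cell_count": counts,
            "area_m2": counts * cell_area,
            "centroid_x": cx,
            "centroid_y": cy,
        }
    )
    return StandTable(table=table, labels=labels, connectivity=connectivity,
                      cell_area=cell_area)


@dataclass
class CoverSummary:
    """Scrub cover bookkeeping for one epoch.

    Percentages and areas are stored at full precision; presentation-layer
    rounding (2 dp) happens only in reports.
    """

    epoch_label: str
    scrub_area_m2: float
    site_area_m2: float
    percent_cover: float
    n_stands: int
    stand_min_m2: float | None = None
    stand_max_m2: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.percent_cover <= 100:
            raise ValueError(
                f"percent_cover outside [0, 100]: {self.percent_cover} "
                "(scrub area larger than the site denominator?)"
            )
        if (
            self.n_stands >= 1
            and self.stand_min_m2 is not None
            and self.stand_max_m2 is not None
            and self.stand_min_m2 > self.stand_max_m2
        ):
            raise ValueError("stand_min_m2 > stand_max_m2")

    def round_trip_dict(self) -> dict:
        """Full-precision machine-readable form."""
        return {
            "epoch_label": self.epoch_label,
            "scrub_area_m2": self.scrub_area_m2,
            "site_area_m2": self.site_area_m2,
            "percent_cover": self.percent_cover,
            "n_stands": self.n_stands,
            "stand_min_m2": self.stand_min_m2,
            "stand_max_m2": self.stand_max_m2,
        }

    def __str__(self) -> str:  # human report: 2 dp, like the field reports
        return (
            f"{self.epoch_label}: scrub {self.scrub_area_m2:.2f} m² "
            f"({self.percent_cover:.2f}% of {self.site_area_m2:.2f} m²), "
            f"{self.n_stands} stands"
        )


def cover_summary(
    scrub_mask: GridRaster,
    stands: StandTable,
    site_area_m2: float,
    epoch_label: str = "",
) -> CoverSummary:
    """Summarise scrub cover: area, percentage of site, stand statistics.

    The scrub area is the stand-table total (cell count × cell area), so
    the summary is exactly consistent with the delineation.
    """
    if not site_area_m2 > 0:
        raise ValueError(f"site_area_m2 must be positive, got {site_area_m2}")
    area = stands.total_area_m2
    return CoverSummary(
        epoch_label=epoch_label,
        scrub_area_m2=area,
        site_area_m2=float(site_area_m2),
        percent_cover=area / site_area_m2 * 100.0,
        n_stands=stands.n_stands,
        stand_min_m2=float(stands.table["area_m2"].min()) if stands.n_stands else None,
        stand_max_m2=float(stands.table["area_m2"].max()) if stands.n_stands else None,
    )


@dataclass
class EpochChange:
    """Between-epoch cover change, reported both ways people quote it.

    ``percentage_point_difference`` is newer.percent − older.percent (a
    difference of percentages of the site); ``relative_change_percent`` is
    the change in scrub area relative to the older epoch's area × 100.
    Both are signed: positive = scrub increased.
    """

    older_label: str
    newer_label: str
    percentage_point_difference: float
    relative_change_percent: float
    older_area_m2: float
    newer_area_m2: float


def compare_epochs(older: CoverSummary, newer: CoverSummary) -> EpochChange:
    """Change record between two cover summaries over the same denominator."""
    if older.site_area_m2 != newer.site_area_m2:
        raise ValueError(
            "cover summaries use different site denominators "
            f"({older.site_area_m2} vs {newer.site_area_m2} m²); "
            "comparisons across different site definitions are invalid"
        )
    rel = (
        (newer.scrub_area_m2 - older.scrub_area_m2) / older.scrub_area_m2 * 100.0
        if older.scrub_area_m2 > 0
        else float("nan")
    )
    return EpochChange(
        older_label=older.epoch_label,
        newer_label=newer.epoch_label,
        percentage_point_difference=newer.percent_cover - older.percent_cover,
        relative_change_percent=rel,
        older_area_m2=older.scrub_area_m2,
        newer_area_m2=newer.scrub_area_m2,
    )


def scenario_remove_stands(
    stands: StandTable,
    remove_ids: list[int],
    site_area_m2: float,
    epoch_label: str = "scenario",
) -> CoverSummary:
    """Cover summary after a hypothetical removal of the listed stands.

    Models a management scenario — e.g. clearing the largest stands along
    a site border — without touching any raster.
    """
    ids = set(stands.table["stand_id"])
    unknown = set(remove_ids) - ids
    if unknown:
        raise KeyError(f"unknown stand ids: {sorted(unknown)}")
    kept = stands.table[~stands.table["stand_id"].isin(set(remove_ids))]
    residual = StandTable(
        table=kept.reset_index(drop=True),
        labels=None,
        connectivity=stands.connectivity,
        cell_area=stands.cell_area,
    )
    if not site_area_m2 > 0:
        raise ValueError(f"site_area_m2 must be positive, got {site_area_m2}")
    area = residual.total_area_m2
    return CoverSummary(
        epoch_label=epoch_label,
        scrub_area_m2=area,
        site_area_m2=float(site_area_m2),
        percent_cover=area / site_area_m2 * 100.0,
        n_stands=residual.n_stands,
        stand_min_m2=float(kept["area_m2"].min()) if len(kept) else None,
        stand_max_m2=float(kept["area_m2"].max()) if len(kept) else None,
    )
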