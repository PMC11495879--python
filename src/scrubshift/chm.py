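"""Canopy height model construction and cross-epoch grid alignment.

The vegetation-height layer is the plain per-cell difference DSM − DTM:
subtracting the bare-ground terrain from the photogrammetric surface
leaves only the height of vegetation and other above-ground features.
Because both models come from the same reconstruction, any vertical datum
offset (surveys referenced to the drone launch position, for instance)
cancels in the difference.

Surveys flown in different years rarely share a ground sample distance,
so before any cell-wise change arithmetic the finer epoch is brought onto
the coarser epoch's grid.  Continuous heights are block-averaged (the
mean of the contributing fine cells); class codes are never resampled —
heights are aligned first and classified after.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GridRaster, CRSMismatchError

__all__ = ["EpochSurvey", "compute_chm", "align_to_grid"]


@dataclass
class EpochSurvey:
    """One survey epoch: paired DSM and DTM on a common grid.

    ``gsd_m`` is the nominal ground sample distance in metres per pixel;
    it is informational (the authoritative cell size lives in the raster
    transform).
    """

    epoch_label: str
    dsm: GridRaster
    dtm: GridRaster
    gsd_m: float | None = None

    def __post_init__(self) -> None:
        self.dsm.require_same_grid(self.dtm, what="DSM and DTM")
        if self.gsd_m is not None and not self.gsd_m > 0:
            raise ValueError(f"gsd_m must be positive, got {self.gsd_m}")


def compute_chm(survey: EpochSurvey, clamp_negative: bool = True) -> GridRaster:
    """Vegetation height per cell: DSM − DTM.

    Nodata in either input propagates.  Small negative differences are
    photogrammetric noise — heights below the terrain are physically
    meaningless — and are clamped to 0 by default, which places them in
    the ground band downstream.
    """
    dsm, dtm = survey.dsm, survey.dtm
    valid = dsm.data_mask & dtm.data_mask
    chm = np.full(dsm.shape, dsm.nodata, dtype=np.float64)
    diff = dsm.values.astype(np.float64) - dtm.values.astype(np.float64)
    if clamp_negative:
        diff = np.maximum(diff, 0.0)
    chm[valid] = diff[valid]
    return GridRaster(
        values=chm, transform=dsm.transform, crs_tag=dsm.crs_tag, nodata=float(dsm.nodata)
    )


def align_to_grid(
    source: GridRaster, target: GridRaster, method: str = "block_average"
) -> GridRaster:
    """Resample ``source`` onto the grid of ``target``.

    ``block_average`` assigns each target cell the mean of the source data
    cells whose centres fall inside it (nodata-aware); it requires the
    target cell size to be at least the source's, i.e. downsampling only.
    ``nearest`` takes the value of the source cell containing the target
    cell centre.  Either way, a target cell with no contributing data is
    nodata.
    """
    if source.crs_tag != target.crs_tag:
        raise CRSMismatchError(
            f"source CRS {source.crs_tag!r} != target CRS {target.crs_tag!r}"
        )
    if method not in ("block_average", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    st, tt = source.transform, target.transform
    if source.same_grid(target):
        return target.with_values(source.values.copy(), nodata=source.nodata)

    out = np.full(target.shape, source.nodata, dtype=np.float64)

    if method == "block_average":
        if tt.cell_w < st.cell_w or tt.cell_h < st.cell_h:
            raise ValueError(
                "block_average is downsampling only: target cell "
                f"({tt.cell_w}×{tt.cell_h} m) is finer than source "
                f"({st.cell_w}×{st.cell_h} m); use method='nearest'"
            )
        X, Y = st.centers(source.shape)
        trow, tcol = tt.index_of(X.ravel(), Y.ravel())
        data = source.data_mask.ravel()
        inside = (
            data
            & (trow >= 0) & (trow < target.shape[0])
            & (tcol >= 0) & (tcol < target.shape[1])
        )
        flat = trow[inside] * target.shape[1] + tcol[inside]
        sums = np.bincount(flat, weights=source.values.ravel()[inside].astype(np.float64),
                           minlength=target.shape[0] * target.shape[1])
        counts = np.bincount(flat, minlength=target.shape[0] * target.shape[1])
        covered = counts > 0
        out_flat = out.ravel()
        out_flat[covered] = sums[covered] / counts[covered]
        out = out_flat.reshape(target.shape)
    else:  # nearest
        X, Y = tt.centers(target.shape)
        srow, scol = st.index_of(X.ravel(), Y.ravel())
        inside = (
            (srow >= 0) & (srow < source.shape[0])
            & (scol >= 0) & (scol < source.shape[1])
        )
        vals = np.full(srow.shape, source.nodata, dtype=np.float64)
        vals[inside] = source.values[srow[inside], scol[inside]].astype(np.float64)
        out = vals.reshape(target.shape)

    return GridRaster(
        values=out, transform=tt, crs_tag=target.crs_tag, nodata=float(source.nodata)
    )
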