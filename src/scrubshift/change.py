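"""Temporal scrub change: growth/loss maps and directional transitions.

Two layers of change analysis, both strictly older-minus-newer:

* **Growth/loss** — subtract the newer scrub presence grid (0/1) from the
  older one.  +1 marks scrub loss (scrub in the older epoch only), −1
  scrub growth (newer only), 0 no change.  Rendered red / green / grey.

* **Directional change** — subtract the newer class-code grid from the
  older one.  With codes ground 100 / scrub 10 / trees 50, every ordered
  class pair yields a distinct nonzero difference:

      ground→scrub 90, ground→trees 50, trees→scrub 40,
      scrub→trees −40, trees→ground −50, scrub→ground −90,

  and 0 (no change) cells are nulled out.  Per-transition areas divided
  by the site denominator give the directional percentages.

Transitions are finally aggregated into *succession* (movement toward
taller vegetation: ground→scrub, scrub→trees, and optionally
ground→trees) versus *reduction* (movement toward open habitat:
scrub→ground, trees→scrub, and optionally trees→ground) — the framing a
site manager with an open-habitat target actually cares about.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import GROUND, SCRUB, TREES, ClassCodeMap, ClassRaster
from .raster import GridRaster

__all__ = [
    "LOSS",
    "NO_CHANGE",
    "GROWTH",
    "TRANSITION_LABELS",
    "ChangeRaster",
    "TransitionRaster",
    "TransitionStat",
    "TransitionSummary",
    "change_map",
    "encode_transitions",
    "transition_summary",
    "render_change",
    "CHANGE_COLORS",
]

LOSS = 1
NO_CHANGE = 0
GROWTH = -1

#: ordered (older, newer) class pairs, scrub-involving first
TRANSITION_LABELS = (
    (GROUND, SCRUB),
    (TREES, SCRUB),
    (SCRUB, GROUND),
    (SCRUB, TREES),
    (GROUND, TREES),
    (TREES, GROUND),
)

_SCRUB_GAINING = ((GROUND, SCRUB), (TREES, SCRUB))
_SCRUB_LOSING = ((SCRUB, GROUND), (SCRUB, TREES))

#: map colours: growth green, loss red, unchanged grey, nodata white
CHANGE_COLORS = {
    GROWTH: (0x00, 0xA0, 0x00),
    LOSS: (0xD0, 0x00, 0x00),
    NO_CHANGE: (0xBF, 0xBF, 0xBF),
    "nodata": (0xFF, 0xFF, 0xFF),
}


@dataclass
class ChangeRaster:
    """Scrub growth/loss grid: older presence − newer presence per cell."""

    raster: GridRaster
    epoch_pair: tuple[str, str]

    @property
    def values(self) -> np.ndarray:
        return self.raster.values

    def _count(self, code: int) -> int:
        return int((self.raster.data_mask & (self.raster.values == code)).sum())

    @property
    def growth_cells(self) -> int:
        return self._count(GROWTH)

    @property
    def loss_cells(self) -> int:
        return self._count(LOSS)

    @property
    def unchanged_cells(self) -> int:
        return self._count(NO_CHANGE)

    @property
    def growth_area_m2(self) -> float:
        return self.growth_cells * self.raster.cell_area

    @property
    def loss_area_m2(self) -> float:
        return self.loss_cells * self.raster.cell_area


def change_map(older_mask: GridRaster, newer_mask: GridRaster,
               epoch_pair: tuple[str, str] = ("older", "newer")) -> ChangeRaster:
    """Older-minus-newer scrub change grid.

    Inputs are 0/1 scrub presence grids on an identical grid (align
    first); in-site cells without scrub must be 0, not nodata.  A cell
    nodata in either epoch (outside the site or excluded) is nodata in
    the result.
    """
    older_mask.require_same_grid(newer_mask, what="epoch scrub masks")
    for name, m in (("older", older_mask), ("newer", newer_mask)):
        stray = np.setdiff1d(np.unique(m.values[m.data_mask]), [0, 1])
        if stray.size:
            raise ValueError(
                f"{name} mask is not a 0/1 presence grid: found {stray.tolist()}"
            )
    valid = older_mask.data_mask & newer_mask.data_mask
    nodata = np.int16(-128)
    out = np.full(older_mask.shape, nodata, dtype=np.int16)
    diff = older_mask.values.astype(np.int16) - newer_mask.values.astype(np.int16)
    out[valid] = diff[valid]
    raster = GridRaster(out, older_mask.transform, crs_tag=older_mask.crs_tag,
                        nodata=int(nodata))
    return ChangeRaster(raster=raster, epoch_pair=epoch_pair)


@dataclass
class TransitionRaster:
    """Class-transition grid: older code − newer code, no-change cells nulled."""

    raster: GridRaster
    codes: ClassCodeMap
    epoch_pair: tuple[str, str]

    @property
    def decode_table(self) -> dict[int, tuple[str, str]]:
        return self.codes.decode_table()

    def area_of(self, older_label: str, newer_label: str) -> float:
        code = self.codes.transition_code(older_label, newer_label)
        n = int((self.raster.data_mask & (self.raster.values == code)).sum())
        return n * self.raster.cell_area


def encode_transitions(older_cls: ClassRaster, newer_cls: ClassRaster,
                       epoch_pair: tuple[str, str] = ("older", "newer")
                       ) -> TransitionRaster:
    """Encode per-cell class transitions as older code − newer code.

    Requires identical grids and an identical, collision-free code map.
    Unchanged cells (difference 0) are set to nodata, leaving only cells
    whose cover class changed.
    """
    older_cls.raster.require_same_grid(newer_cls.raster, what="epoch class rasters")
    if older_cls.codes != newer_cls.codes:
        raise ValueError(
            f"epochs use different class code maps: {older_cls.codes} "
            f"vs {newer_cls.codes}"
        )
    codes = older_cls.codes  # construction already validated collision-freeness
    valid = older_cls.raster.data_mask & newer_cls.raster.data_mask
    nodata = np.int16(-32768)
    out = np.full(older_cls.raster.shape, nodata, dtype=np.int16)
    diff = older_cls.values.astype(np.int16) - newer_cls.values.astype(np.int16)
    out[valid] = diff[valid]
    out[valid & (diff == 0)] = nodata  # set-null the no-change cells
    raster = GridRaster(out, older_cls.raster.transform,
                        crs_tag=older_cls.raster.crs_tag, nodata=int(nodata))
    return TransitionRaster(raster=raster, codes=codes, epoch_pair=epoch_pair)


@dataclass
class TransitionStat:
    """One transition's area and the percentages it is quoted as."""

    older: str
    newer: str
    area_m2: float
    percent_of_site: float
    percent_of_growth: float | None = None  # only for scrub-gaining transitions
    percent_of_loss: float | None = None  # only for scrub-losing transitions


@dataclass
class TransitionSummary:
    """Per-transition accounting plus the succession/reduction shares.

    ``succession_share_percent`` + ``reduction_share_percent`` = 100 when
    any change within the share basis exists.  By default the shares are
    computed over scrub-involving transitions only; set
    ``include_ground_tree_shares`` in :func:`transition_summary` to let
    ground↔trees change enter the basis as well.
    """

    epoch_pair: tuple[str, str]
    site_area_m2: float
    stats: dict[tuple[str, str], TransitionStat]
    succession_share_percent: float | None
    reduction_share_percent: float | None
    succession_set: tuple[tuple[str, str], ...]
    reduction_set: tuple[tuple[str, str], ...]

    @property
    def growth_area_m2(self) -> float:
        return sum(self.stats[t].area_m2 for t in _SCRUB_GAINING)

    @property
    def loss_area_m2(self) -> float:
        return sum(self.stats[t].area_m2 for t in _SCRUB_LOSING)


def transition_summary(
    tr: TransitionRaster,
    change: ChangeRaster | None,
    site_area_m2: float,
    include_ground_tree_shares: bool = False,
) -> TransitionSummary:
    """Tabulate per-transition areas, site percentages and shares.

    ``percent_of_growth`` is each scrub-gaining transition's share of all
    new scrub; ``percent_of_loss`` likewise over lost scrub.  When a
    :class:`ChangeRaster` for the same epoch pair is given, the summary is
    cross-checked against it exactly (growth = ground→scrub + trees→scrub
    and loss = scrub→ground + scrub→trees areas must match).
    """
    if not site_area_m2 > 0:
        raise ValueError(f"site_area_m2 must be positive, got {site_area_m2}")
    if change is not None and change.epoch_pair != tr.epoch_pair:
        raise ValueError(
            f"transition raster is for epochs {tr.epoch_pair} but change "
            f"raster is for {change.epoch_pair}"
        )
    areas = {pair: tr.area_of(*pair) for pair in TRANSITION_LABELS}
    growth_area = sum(areas[t] for t in _SCRUB_GAINING)
    loss_area = sum(areas[t] for t in _SCRUB_LOSING)
    if change is not None:
        if (growth_area != change.growth_area_m2) or (loss_area != change.loss_area_m2):
            raise ValueError(
                "transition areas disagree with the growth/loss raster: "
                f"growth {growth_area} vs {change.growth_area_m2} m², "
                f"loss {loss_area} vs {change.loss_area_m2} m²"
            )

    stats: dict[tuple[str, str], TransitionStat] = {}
    for pair, area in areas.items():
        stat = TransitionStat(
            older=pair[0],
            newer=pair[1],
            area_m2=area,
            percent_of_site=area / site_area_m2 * 100.0,
        )
        if pair in _SCRUB_GAINING and growth_area > 0:
            stat.percent_of_growth = area / growth_area * 100.0
        if pair in _SCRUB_LOSING and loss_area > 0:
            stat.percent_of_loss = area / loss_area * 100.0
        stats[pair] = stat

    succession_set = [(GROUND, SCRUB), (SCRUB, TREES)]
    reduction_set = [(SCRUB, GROUND), (TREES, SCRUB)]
    if include_ground_tree_shares:
        succession_set.append((GROUND, TREES))
        reduction_set.append((TREES, GROUND))
    succ = sum(areas[t] for t in succession_set)
    red = sum(areas[t] for t in reduction_set)
    total = succ + red
    return TransitionSummary(
        epoch_pair=tr.epoch_pair,
        site_area_m2=float(site_area_m2),
        stats=stats,
        succession_share_percent=succ / total * 100.0 if total > 0 else None,
        reduction_share_percent=red / total * 100.0 if total > 0 else None,
        succession_set=tuple(succession_set),
        reduction_set=tuple(reduction_set),
    )


def render_change(change, out_path) -> None:
    """Render a change or transition raster to a PNG map.

    Growth/loss maps are written one pixel per cell with the fixed
    green / red / grey colour table, so pixel counts per colour equal
    cell counts per change code.  Transition maps get one colour per
    transition with a legend (via matplotlib).
    """
    from PIL import Image

    if isinstance(change, ChangeRaster):
        r = change.raster
        rgb = np.empty((*r.shape, 3), dtype=np.uint8)
        rgb[...] = CHANGE_COLORS["nodata"]
        for code in (GROWTH, LOSS, NO_CHANGE):
            rgb[r.data_mask & (r.values == code)] = CHANGE_COLORS[code]
        Image.fromarray(rgb, mode="RGB").save(out_path, format="PNG")
        return

    if isinstance(change, TransitionRaster):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import BoundaryNorm, ListedColormap
        from matplotlib.patches import Patch

        palette = {
            (GROUND, SCRUB): "#2ca02c",
            (TREES, SCRUB): "#98df8a",
            (SCRUB, GROUND): "#d62728",
            (TREES, GROUND): "#ff9896",
            (SCRUB, TREES): "#1f77b4",
            (GROUND, TREES): "#17becf",
        }
        r = change.raster
        entries = sorted(
            ((change.codes.transition_code(a, b), (a, b)) for a, b in TRANSITION_LABELS)
        )
        codes = [c for c, _ in entries]
        cmap = ListedColormap([palette[pair] for _, pair in entries])
        cmap.set_bad("#FFFFFF")
        bounds = [codes[0] - 0.5] + [
            (codes[i] + codes[i + 1]) / 2 for i in range(len(codes) - 1)
        ] + [codes[-1] + 0.5]
        norm = BoundaryNorm(bounds, cmap.N)
        shown = np.ma.masked_where(~r.data_mask, r.values)
        fig, ax = plt.subplots(figsize=(7, 6))
        ax.imshow(shown, cmap=cmap, norm=norm, interpolation="nearest")
        ax.set_axis_off()
        handles = [
            Patch(facecolor=palette[pair], label=f"{pair[0].lower()} → {pair[1].lower()}")
            for _, pair in entries
        ]
        ax.legend(handles=handles, loc="upper right", fontsize=8, framealpha=0.9)
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return

    raise TypeError(f"cannot render object of type {type(change).__name__}")
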