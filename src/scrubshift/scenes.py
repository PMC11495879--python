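"""Seeded synthetic multi-epoch survey scenes with exact ground truth.

No real drone surveys ship with this package, so every downstream stage
is exercised against generated scenes: a smooth terrain surface (plane
plus seeded low-frequency bumps, so the DSM−DTM cancellation is tested
on non-flat ground), blob/ellipse/rectangle vegetation patches of known
height, and a per-epoch script of transitions (appear, clear to ground,
grow to trees, height drift).  The generator emits standard DSM/DTM
raster pairs and, alongside them, a :class:`SceneTruth` ledger with the
exact per-epoch class grid, patch areas, stand counts and per-transition
cell counts — computed directly from the patch geometry, independently
of the analysis pipeline, so the ledger can serve as an oracle.

Optional height noise is applied to the DSM only and is *bounded*, not
Gaussian, mirroring how photogrammetric height error is reported from
ground verification (e.g. overestimates ≤ +1.6 cm, underestimates
≤ 4 cm).  With noise off, every ledger quantity is exact.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .chm import EpochSurvey
from .raster import DEFAULT_HEIGHT_NODATA, GridRaster, GridTransform

__all__ = [
    "PatchSpec",
    "SceneSpec",
    "SceneTruth",
    "generate_scene",
    "preset_two_site_demo",
    "write_scene",
    "PAPER_NOISE_OVER_M",
    "PAPER_NOISE_UNDER_M",
]

#: verified photogrammetric height-error bounds: overestimate / underestimate
PAPER_NOISE_OVER_M = 0.016
PAPER_NOISE_UNDER_M = 0.04


@dataclass
class PatchSpec:
    """One vegetation patch: footprint geometry, height, per-epoch script.

    ``script`` maps epoch labels to actions: ``"appear"``, ``"persist"``,
    ``"absent"``, ``"clear_to_ground"``, ``"grow_to_trees"``, a number
    (explicit new height in metres) or ``"delta:<±x>"`` (height drift).
    Epochs without an entry persist the previous state; in the first
    epoch the patch is present at ``height_m`` unless scripted absent.
    """

    name: str
    shape: str  # "ellipse" | "rectangle" | "blob"
    row: int
    col: int
    half_rows: int
    half_cols: int
    height_m: float
    script: dict[str, object] = field(default_factory=dict)

    def footprint(self, grid_shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
        """Boolean footprint mask; for blobs, deterministic given the rng state."""
        rows, cols = grid_shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        if self.shape == "rectangle":
            return (np.abs(rr - self.row) <= self.half_rows) & (
                np.abs(cc - self.col) <= self.half_cols
            )
        dist = ((rr - self.row) / self.half_rows) ** 2 + (
            (cc - self.col) / self.half_cols
        ) ** 2
        if self.shape == "ellipse":
            return dist <= 1.0
        if self.shape == "blob":
            wobble = gaussian_filter(rng.standard_normal(grid_shape), sigma=2.0)
            peak = np.abs(wobble).max()
            if peak > 0:
                wobble = wobble / peak * 0.35
            return dist + wobble <= 1.0
        raise ValueError(f"unknown patch shape {self.shape!r}")

    def height_in(self, epoch: str, previous: float | None, trees_height_m: float,
                  is_first: bool) -> float | None:
        """Resolve the patch's height (None = absent) for one epoch."""
        action = self.script.get(epoch, None)
        if action is None:
            action = "appear" if is_first else "persist"
        if isinstance(action, (int, float)):
            return float(action)
        if action == "persist":
            return previous
        if action in ("absent", "clear_to_ground"):
            return None
        if action == "appear":
            return previous if previous is not None else self.height_m
        if action == "grow_to_trees":
            return trees_height_m
        if isinstance(action, str) and action.startswith("delta:"):
            if previous is None:
                raise ValueError(
                    f"patch {self.name!r}: height delta scripted in epoch {epoch!r} "
                    "but the patch is absent"
                )
            return previous + float(action.split(":", 1)[1])
        raise ValueError(f"patch {self.name!r}: unknown script action {action!r}")


@dataclass
class SceneSpec:
    """Full description of a synthetic site and its survey epochs."""

    grid_shape: tuple[int, int]
    cell_size_m: float
    epochs: list[str]
    patches: list[PatchSpec]
    seed: int = 0
    origin_x: float = 0.0
    origin_y: float | None = None  # default: grid_rows × cell size (y grows north)
    crs_tag: str = "SYNTH:LOCAL"
    terrain_base_m: float = 120.0
    terrain_slope_per_m: tuple[float, float] = (0.15, 0.05)
    bump_amplitude_m: float = 1.2
    bump_smoothness_cells: float = 6.0
    noise_over_m: float = 0.0
    noise_under_m: float = 0.0
    trees_height_m: float = 6.5
    lower_scrub_m: float = 1.0
    upper_scrub_m: float = 5.0

    def __post_init__(self) -> None:
        if len(set(self.epochs)) != len(self.epochs) or not self.epochs:
            raise ValueError("epoch labels must be non-empty and unique")
        names = [p.name for p in self.patches]
        if len(set(names)) != len(names):
            raise ValueError("patch names must be unique")
        if self.noise_over_m < 0 or self.noise_under_m < 0:
            raise ValueError("noise bounds are magnitudes and must be ≥ 0")
        if self.origin_y is None:
            self.origin_y = self.grid_shape[0] * self.cell_size_m

    @property
    def transform(self) -> GridTransform:
        return GridTransform(self.origin_x, float(self.origin_y),
                             self.cell_size_m, self.cell_size_m)

    @property
    def site_area_m2(self) -> float:
        rows, cols = self.grid_shape
        return rows * cols * self.cell_size_m ** 2

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["grid_shape"] = tuple(raw["grid_shape"])
        if "terrain_slope_per_m" in raw:
            raw["terrain_slope_per_m"] = tuple(raw["terrain_slope_per_m"])
        raw["patches"] = [PatchSpec(**p) for p in raw.get("patches", [])]
        return cls(**raw)


def _band_label(h: float, lower: float, upper: float) -> str:
    # deliberately inline (not via HeightBandScheme) so the truth ledger is
    # computed independently of the classification module it later checks
    if h < lower:
        return "GROUND"
    if h <= upper:
        return "SCRUB"
    return "TREES"


def _flood_fill_components(mask: np.ndarray) -> list[int]:
    """Component sizes of True cells under 8-adjacency, by iterative BFS."""
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and not seen[r0, c0]:
                size = 0
                queue = deque([(r0, c0)])
                seen[r0, c0] = True
                while queue:
                    r, c = queue.popleft()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < rows and 0 <= cc < cols
                                and mask[rr, cc] and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                queue.append((rr, cc))
                sizes.append(size)
    return sizes


@dataclass
class SceneTruth:
    """Exact ledger of what the generator put into the scene.

    ``class_labels`` holds per-epoch label grids ("GROUND"/"SCRUB"/
    "TREES"); ``transitions`` maps each analysed epoch pair to exact
    cell counts per (older label, newer label); ``cover`` gives the
    expected per-epoch scrub accounting.  All counts are exact for the
    noise-free scene.
    """

    epochs: list[str]
    cell_area_m2: float
    site_area_m2: float
    patch_cells: dict[str, np.ndarray]
    patch_heights: dict[str, dict[str, float | None]]
    class_labels: dict[str, np.ndarray]
    cover: dict[str, dict]
    transitions: dict[tuple[str, str], dict[tuple[str, str], int]]

    def epoch_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.transitions.keys(), key=lambda p: (self.epochs.index(p[0]),
                                                              self.epochs.index(p[1])))

    def growth_cells(self, pair: tuple[str, str]) -> int:
        t = self.transitions[pair]
        return t[("GROUND", "SCRUB")] + t[("TREES", "SCRUB")]

    def loss_cells(self, pair: tuple[str, str]) -> int:
        t = self.transitions[pair]
        return t[("SCRUB", "GROUND")] + t[("SCRUB", "TREES")]

    def to_jsonable(self) -> dict:
        """Ledger summary (no grids) for committing / diffing as JSON."""
        return {
            "epochs": self.epochs,
            "cell_area_m2": self.cell_area_m2,
            "site_area_m2": self.site_area_m2,
            "patch_areas_m2": {
                name: int(cells.sum()) * self.cell_area_m2
                for name, cells in self.patch_cells.items()
            },
            "cover": self.cover,
            "transitions": {
                f"{a}->{b}": {f"{p}->{q}": n for (p, q), n in counts.items()}
                for (a, b), counts in self.transitions.items()
            },
        }


def _analysed_pairs(epochs: list[str]) -> list[tuple[str, str]]:
    pairs = [(epochs[i], epochs[i + 1]) for i in range(len(epochs) - 1)]
    if len(epochs) > 2:
        pairs.append((epochs[0], epochs[-1]))
    return pairs


def generate_scene(spec: SceneSpec) -> tuple[list[EpochSurvey], SceneTruth]:
    """Build per-epoch DSM/DTM surveys and the exact truth ledger.

    DTM = terrain; DSM = DTM + vegetation height (+ optional bounded
    noise on the DSM only).  Patches present in the same epoch must not
    overlap — the truth would be ambiguous — and this is an error.
    Identical spec and seed give bit-identical outputs.
    """
    rows, cols = spec.grid_shape
    rng = np.random.default_rng(spec.seed)

    # terrain: plane + smooth seeded bumps, static across epochs
    transform = spec.transform
    X, Y = transform.centers(spec.grid_shape)
    sx, sy = spec.terrain_slope_per_m
    terrain = spec.terrain_base_m + sx * (X - spec.origin_x) + sy * (Y - (spec.origin_y - rows * spec.cell_size_m))
    if spec.bump_amplitude_m > 0:
        bumps = gaussian_filter(rng.standard_normal(spec.grid_shape),
                                sigma=spec.bump_smoothness_cells)
        peak = np.abs(bumps).max()
        if peak > 0:
            terrain = terrain + bumps / peak * spec.bump_amplitude_m

    # footprints (blob shapes consume the same rng stream → deterministic)
    footprints = {p.name: p.footprint(spec.grid_shape, rng) for p in spec.patches}

    # resolve per-epoch patch heights
    heights: dict[str, dict[str, float | None]] = {p.name: {} for p in spec.patches}
    state: dict[str, float | None] = {p.name: None for p in spec.patches}
    for i, epoch in enumerate(spec.epochs):
        for p in spec.patches:
            state[p.name] = p.height_in(epoch, state[p.name], spec.trees_height_m,
                                        is_first=(i == 0))
            heights[p.name][epoch] = state[p.name]

    # per-epoch height map + truth class grid; overlap check
    surveys: list[EpochSurvey] = []
    class_labels: dict[str, np.ndarray] = {}
    cover: dict[str, dict] = {}
    for epoch in spec.epochs:
        present = [p.name for p in spec.patches if heights[p.name][epoch] is not None]
        stacked = np.zeros(spec.grid_shape, dtype=np.int32)
        for name in present:
            stacked += footprints[name]
        if (stacked > 1).any():
            clash = [n for n in present]
            raise ValueError(
                f"epoch {epoch!r}: patch footprints overlap among {clash}; "
                "ground truth would be ambiguous"
            )
        veg = np.zeros(spec.grid_shape, dtype=np.float64)
        labels = np.full(spec.grid_shape, "GROUND", dtype="<U6")
        for name in present:
            h = heights[name][epoch]
            veg[footprints[name]] = h
            labels[footprints[name]] = _band_label(h, spec.lower_scrub_m,
                                                   spec.upper_scrub_m)
        class_labels[epoch] = labels

        dsm_vals = terrain + veg
        if spec.noise_over_m > 0 or spec.noise_under_m > 0:
            dsm_vals = dsm_vals + rng.uniform(-spec.noise_under_m, spec.noise_over_m,
                                              size=spec.grid_shape)
        dsm = GridRaster(dsm_vals, transform, crs_tag=spec.crs_tag,
                         nodata=DEFAULT_HEIGHT_NODATA)
        dtm = GridRaster(terrain.copy(), transform, crs_tag=spec.crs_tag,
                         nodata=DEFAULT_HEIGHT_NODATA)
        surveys.append(EpochSurvey(epoch_label=epoch, dsm=dsm, dtm=dtm,
                                   gsd_m=spec.cell_size_m))

        scrub_mask = labels == "SCRUB"
        sizes = _flood_fill_components(scrub_mask)
        areas = [s * transform.cell_area for s in sizes]
        scrub_area = float(scrub_mask.sum()) * transform.cell_area
        cover[epoch] = {
            "scrub_area_m2": scrub_area,
            "site_area_m2": spec.site_area_m2,
            "percent_cover": scrub_area / spec.site_area_m2 * 100.0,
            "n_stands": len(sizes),
            "stand_min_m2": min(areas) if areas else None,
            "stand_max_m2": max(areas) if areas else None,
        }

    # transition ledger for consecutive pairs + oldest-vs-newest
    label_pairs = [(a, b) for a in ("GROUND", "SCRUB", "TREES")
                   for b in ("GROUND", "SCRUB", "TREES") if a != b]
    transitions = {}
    for a, b in _analysed_pairs(spec.epochs):
        older, newer = class_labels[a], class_labels[b]
        transitions[(a, b)] = {
            (p, q): int(((older == p) & (newer == q)).sum()) for p, q in label_pairs
        }

    truth = SceneTruth(
        epochs=list(spec.epochs),
        cell_area_m2=transform.cell_area,
        site_area_m2=spec.site_area_m2,
        patch_cells=footprints,
        patch_heights=heights,
        class_labels=class_labels,
        cover=cover,
        transitions=transitions,
    )
    return surveys, truth


def preset_two_site_demo() -> tuple[SceneSpec, SceneSpec]:
    """Two fixed demo sites mirroring the shapes of real monitoring cases.

    Site A: a sloped bank surveyed three times; scrub cover rises between
    the first two epochs (new colonisation) then falls by the third
    (managed cutting plus one stand succeeding to woodland).  Site B: a
    flat island site surveyed twice with heavy clearance — net loss, and
    loss area greater than growth area.
    """
    site_a = SceneSpec(
        grid_shape=(60, 60),
        cell_size_m=0.5,
        epochs=["2015", "2017", "2021"],
        seed=20150601,
        terrain_base_m=122.0,
        terrain_slope_per_m=(0.8, 0.4),  # steep bank, ~50 m rise over the site
        bump_amplitude_m=1.5,
        patches=[
            PatchSpec("hawthorn_core", "ellipse", 14, 14, 6, 8, 2.5),
            PatchSpec("bank_edge", "rectangle", 14, 42, 5, 6, 3.0,
                      script={"2021": "clear_to_ground"}),
            PatchSpec("new_colony", "blob", 42, 14, 5, 6, 1.8,
                      script={"2015": "absent", "2017": "appear"}),
            PatchSpec("old_thicket", "ellipse", 42, 42, 4, 5, 4.2,
                      script={"2021": "grow_to_trees"}),
            PatchSpec("beech_line", "rectangle", 55, 30, 2, 12, 9.0),
        ],
    )
    site_b = SceneSpec(
        grid_shape=(50, 50),
        cell_size_m=0.5,
        epochs=["2019", "2021"],
        seed=20190521,
        terrain_base_m=30.0,
        terrain_slope_per_m=(0.02, 0.01),
        bump_amplitude_m=0.8,
        patches=[
            PatchSpec("gull_ridge", "ellipse", 10, 12, 5, 7, 2.2),
            PatchSpec("south_block", "rectangle", 34, 12, 7, 7, 3.5,
                      script={"2021": "clear_to_ground"}),
            PatchSpec("east_scatter", "blob", 12, 38, 4, 5, 1.6,
                      script={"2021": "clear_to_ground"}),
            PatchSpec("new_fringe", "ellipse", 40, 40, 2, 3, 1.4,
                      script={"2019": "absent", "2021": "appear"}),
            PatchSpec("sycamore_clump", "ellipse", 26, 30, 3, 3, 8.0,
                      script={"2021": 3.0}),  # topped: trees → scrub height
        ],
    )
    return site_a, site_b


def write_scene(surveys: list[EpochSurvey], truth: SceneTruth, outdir) -> None:
    """Write DSM/DTM GeoTIFF pairs and the truth ledger (JSON + per-epoch CSV)."""
    import os

    import pandas as pd

    from .raster import write_raster

    os.makedirs(outdir, exist_ok=True)
    for s in surveys:
        write_raster(s.dsm, os.path.join(outdir, f"dsm_{s.epoch_label}.tif"))
        write_raster(s.dtm, os.path.join(outdir, f"dtm_{s.epoch_label}.tif"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=2, sort_keys=True)
    rows = [
        {"epoch": e, **{k: v for k, v in truth.cover[e].items()}}
        for e in truth.epochs
    ]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "truth_cover.csv"), index=False)
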