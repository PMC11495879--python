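"""Height-band classification of vegetation-height rasters.

Scrub is defined operationally by height alone: transitional woody
vegetation between ground vegetation and woodland, taken here as 1–5 m
tall.  Every finite non-negative height maps to exactly one of three
bands:

* GROUND — ground vegetation and other surfaces, height in [0, 1) m
* SCRUB  — height in [1, 5] m (both boundaries belong to scrub)
* TREES  — other/taller vegetation, height in (5, ∞) m

The 1 m boundary is forced to the scrub side by field-verification
points straddling it (ground points at 0.984/0.991 m, scrub points at
1.015/1.04 m); the 5 m boundary is assigned to scrub to keep the stated
"1–5 m" range inclusive.

Class rasters carry small integer codes (ground 100, scrub 10, trees 50
by default).  The codes are chosen so that every ordered pair of classes
has a distinct nonzero difference — that property is what makes the
older-minus-newer transition encoding decodable, and user-supplied codes
are validated for it up front.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .raster import GridRaster, DEFAULT_CLASS_NODATA

__all__ = [
    "GROUND",
    "SCRUB",
    "TREES",
    "LABELS",
    "HeightBandScheme",
    "ClassCodeMap",
    "ClassRaster",
    "classify_heights",
    "isolate_class",
    "class_presence_mask",
]

GROUND = "GROUND"
SCRUB = "SCRUB"
TREES = "TREES"
LABELS = (GROUND, SCRUB, TREES)


@dataclass(frozen=True)
class HeightBandScheme:
    """Ordered height thresholds partitioning heights into the three bands.

    Closure convention: GROUND = [0, lower), SCRUB = [lower, upper],
    TREES = (upper, ∞).
    """

    lower_scrub_m: float = 1.0
    upper_scrub_m: float = 5.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower_scrub_m) and math.isfinite(self.upper_scrub_m)):
            raise ValueError("band thresholds must be finite")
        if not 0 < self.lower_scrub_m < self.upper_scrub_m:
            raise ValueError(
                "need 0 < lower_scrub_m < upper_scrub_m, got "
                f"{self.lower_scrub_m} and {self.upper_scrub_m}"
            )

    def band_of(self, height_m: float) -> str:
        """Band label for a single height (vectorised path is classify_heights)."""
        if height_m < self.lower_scrub_m:
            return GROUND
        if height_m <= self.upper_scrub_m:
            return SCRUB
        return TREES


@dataclass(frozen=True)
class ClassCodeMap:
    """Integer codes for the three bands (defaults ground 100, scrub 10, trees 50).

    Valid code maps are collision-free: all ordered-pair differences
    (older − newer) are pairwise distinct and nonzero, so a transition
    raster can be decoded unambiguously.
    """

    ground: int = 100
    scrub: int = 10
    trees: int = 50

    def __post_init__(self) -> None:
        codes = (self.ground, self.scrub, self.trees)
        if len(set(codes)) != 3:
            raise ValueError(f"class codes must be pairwise distinct, got {codes}")
        diffs = [a - b for a, b in permutations(codes, 2)]
        if 0 in diffs or len(set(diffs)) != len(diffs):
            raise ValueError(
                f"class codes {codes} do not give a collision-free transition "
                "encoding: some ordered class pairs share a difference"
            )

    def code_of(self, label: str) -> int:
        try:
            return {GROUND: self.ground, SCRUB: self.scrub, TREES: self.trees}[label]
        except KeyError:
            raise KeyError(f"unknown class label {label!r}; expected one of {LABELS}")

    def label_of(self, code: int) -> str:
        for label in LABELS:
            if self.code_of(label) == code:
                return label
        raise KeyError(f"unknown class code {code}")

    def transition_code(self, older_label: str, newer_label: str) -> int:
        """Older-class code minus newer-class code (0 means no change)."""
        return self.code_of(older_label) - self.code_of(newer_label)

    def decode_table(self) -> dict[int, tuple[str, str]]:
        """Nonzero transition code → (older label, newer label)."""
        return {
            self.transition_code(a, b): (a, b)
            for a in LABELS
            for b in LABELS
            if a != b
        }


@dataclass
class ClassRaster:
    """A class-coded grid together with the scheme and code map that built it."""

    raster: GridRaster
    scheme: HeightBandScheme
    codes: ClassCodeMap = field(default_factory=ClassCodeMap)

    def __post_init__(self) -> None:
        valid = {self.codes.ground, self.codes.scrub, self.codes.trees}
        data = self.raster.data_values()
        stray = set(np.unique(data)) - {float(c) for c in valid} - set(valid)
        if stray:
            raise ValueError(f"class raster holds codes outside the code map: {stray}")

    @property
    def values(self) -> np.ndarray:
        return self.raster.values

    @property
    def nodata(self):
        return self.raster.nodata

    def label_mask(self, label: str) -> np.ndarray:
        """Boolean grid, True on data cells of the given class."""
        return self.raster.data_mask & (self.raster.values == self.codes.code_of(label))


def classify_heights(
    chm: GridRaster,
    scheme: HeightBandScheme | None = None,
    codes: ClassCodeMap | None = None,
    nodata: int = DEFAULT_CLASS_NODATA,
) -> ClassRaster:
    """Classify a height raster (metres) into the three height bands.

    Nodata propagates.  The CHM is expected to be non-negative (negative
    photogrammetric noise is clamped upstream); any negative height falls
    in the ground band regardless.
    """
    scheme = scheme or HeightBandScheme()
    codes = codes or ClassCodeMap()
    h = chm.values
    out = np.full(chm.shape, nodata, dtype=np.int16)
    data = chm.data_mask
    out[data & (h < scheme.lower_scrub_m)] = codes.ground
    out[data & (h >= scheme.lower_scrub_m) & (h <= scheme.upper_scrub_m)] = codes.scrub
    out[data & (h > scheme.upper_scrub_m)] = codes.trees
    raster = GridRaster(out, chm.transform, crs_tag=chm.crs_tag, nodata=nodata)
    return ClassRaster(raster=raster, scheme=scheme, codes=codes)


def isolate_class(cls: ClassRaster, label: str = SCRUB) -> GridRaster:
    """Binary mask of one class, every other cell nulled.

    Cells of the class → 1; all other cells (other classes and original
    nodata alike) → nodata, mirroring a set-null reclassification.
    """
    code_nodata = int(cls.raster.nodata)
    mask = np.full(cls.raster.shape, code_nodata, dtype=np.int16)
    mask[cls.label_mask(label)] = 1
    return GridRaster(
        mask, cls.raster.transform, crs_tag=cls.raster.crs_tag, nodata=code_nodata
    )


def class_presence_mask(cls: ClassRaster, label: str = SCRUB) -> GridRaster:
    """0/1 presence grid for one class, keeping in-site absences as 0.

    Unlike :func:`isolate_class` (which nulls non-class cells), data cells
    of other classes become 0 — the form change detection needs, where
    "inside the site but not scrub" is a real observation.
    """
    code_nodata = int(cls.raster.nodata)
    out = np.full(cls.raster.shape, code_nodata, dtype=np.int16)
    out[cls.raster.data_mask] = 0
    out[cls.label_mask(label)] = 1
    return GridRaster(
        out, cls.raster.transform, crs_tag=cls.raster.crs_tag, nodata=code_nodata
    )
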