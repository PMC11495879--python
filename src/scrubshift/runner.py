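"""Whole-site analysis runner: config in, report bundle out.

Drives the full pipeline for one site from a YAML config: per epoch
DSM/DTM → CHM → clip → (align to the coarsest epoch's grid) → height-band
classification → scrub isolation → stands and cover summary; then for
every analysed epoch pair (consecutive, plus oldest-vs-newest when there
are more than two epochs) the growth/loss raster, the transition raster
and their summaries; plus ground verification where point files are
given.  Everything lands in the output directory as CSV / GeoTIFF / PNG
with one machine-readable ``bundle.json`` carrying every number at full
precision together with every parameter used (thresholds, codes,
connectivity, closure, denominator), so a run is reproducible from its
own output.

All cross-epoch arithmetic runs on a single common grid — the coarsest
epoch's — with continuous heights block-averaged before classification
(class codes are never resampled).  Rounding is confined to the CSV
presentation layer; re-running on identical inputs gives byte-identical
outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .change import (TRANSITION_LABELS, change_map, encode_transitions,
                     render_change, transition_summary)
from .chm import EpochSurvey, align_to_grid, compute_chm
from .classify import (SCRUB, ClassCodeMap, HeightBandScheme, class_presence_mask,
                       classify_heights, isolate_class)
from .raster import GridRaster, load_site_polygons, read_raster, write_raster
from .stands import compare_epochs, cover_summary, label_stands
from .verification import read_points_csv, verify_points

__all__ = ["EpochConfig", "SiteConfig", "run_site"]


@dataclass
class EpochConfig:
    label: str
    dsm: str
    dtm: str
    points: str | None = None  # optional ground-verification CSV


@dataclass
class SiteConfig:
    """Everything needed to analyse one site."""

    name: str
    epochs: list[EpochConfig]
    output_dir: str
    boundary: str | None = None
    exclusions: str | None = None
    denominator_area_m2: float | None = None
    lower_scrub_m: float = 1.0
    upper_scrub_m: float = 5.0
    codes: dict = field(default_factory=lambda: {"ground": 100, "scrub": 10, "trees": 50})
    connectivity: int = 8
    align_method: str = "block_average"
    clamp_negative: bool = True
    include_ground_tree_shares: bool = False

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("site config needs at least one epoch")
        labels = [e.label for e in self.epochs]
        if len(set(labels)) != len(labels):
            raise ValueError(f"epoch labels must be unique, got {labels}")

    @classmethod
    def from_yaml(cls, path) -> "SiteConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        site = raw.get("site", raw)
        bands = site.pop("bands", {})
        epochs = [EpochConfig(**e) for e in site.pop("epochs")]
        return cls(
            epochs=epochs,
            lower_scrub_m=bands.get("lower_scrub_m", 1.0),
            upper_scrub_m=bands.get("upper_scrub_m", 5.0),
            codes=bands.get("codes", {"ground": 100, "scrub": 10, "trees": 50}),
            **site,
        )


def _analysed_pairs(labels: list[str]) -> list[tuple[str, str]]:
    pairs = [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]
    if len(labels) > 2:
        pairs.append((labels[0], labels[-1]))
    return pairs


def _stage(name: str):
    """Decorator-free stage context: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_site(config: SiteConfig) -> dict:
    """Run the full analysis for one site; returns the bundle dict.

    Any stage failure aborts with the stage name and the offending input
    in the message.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    scheme = HeightBandScheme(config.lower_scrub_m, config.upper_scrub_m)
    codes = ClassCodeMap(**config.codes)

    site = None
    if config.boundary:
        with _stage("load site polygons"):
            site = load_site_polygons(
                config.boundary,
                exclusions_path=config.exclusions,
                denominator_area_m2=config.denominator_area_m2,
            )

    # --- per-epoch CHM -------------------------------------------------
    chms: dict[str, GridRaster] = {}
    with _stage("read rasters / compute CHM"):
        for e in config.epochs:
            survey = EpochSurvey(e.label, read_raster(e.dsm), read_raster(e.dtm))
            chm = compute_chm(survey, clamp_negative=config.clamp_negative)
            if site is not None:
                from .raster import clip_to_site

                chm = clip_to_site(chm, site)
            chms[e.label] = chm

    crs_tags = {lbl: c.crs_tag for lbl, c in chms.items()}
    if len(set(crs_tags.values())) > 1:
        raise _StageError(
            f"stage 'grid alignment' failed: epochs use different CRS tags: {crs_tags}"
        )

    # --- common grid: the coarsest epoch's -----------------------------
    with _stage("grid alignment"):
        coarsest = max(chms.values(), key=lambda c: c.cell_area)
        chms = {
            lbl: (c if c.same_grid(coarsest)
                  else align_to_grid(c, coarsest, method=config.align_method))
            for lbl, c in chms.items()
        }

    # --- classification, stands, cover ---------------------------------
    labels = [e.label for e in config.epochs]
    cls = {}
    covers = {}
    with _stage("classification and cover"):
        for lbl in labels:
            cls[lbl] = classify_heights(chms[lbl], scheme, codes)
            mask = isolate_class(cls[lbl], SCRUB)
            stands = label_stands(mask, connectivity=config.connectivity)
            denominator = (
                config.denominator_area_m2
                or (site.site_area_m2 if site is not None else None)
                or chms[lbl].n_data * chms[lbl].cell_area
            )
            covers[lbl] = cover_summary(mask, stands, denominator, epoch_label=lbl)
            stands.table.to_csv(
                os.path.join(config.output_dir, f"stands_{lbl}.csv"),
                index=False, float_format="%.6f",
            )
            pd.DataFrame([covers[lbl].round_trip_dict()]).to_csv(
                os.path.join(config.output_dir, f"cover_{lbl}.csv"),
                index=False, float_format="%.6f",
            )

    # --- pairwise change and transitions --------------------------------
    pair_records = {}
    with _stage("change and transition analysis"):
        for a, b in _analysed_pairs(labels):
            older_mask = class_presence_mask(cls[a], SCRUB)
            newer_mask = class_presence_mask(cls[b], SCRUB)
            change = change_map(older_mask, newer_mask, epoch_pair=(a, b))
            tr = encode_transitions(cls[a], cls[b], epoch_pair=(a, b))
            summary = transition_summary(
                tr, change, covers[a].site_area_m2,
                include_ground_tree_shares=config.include_ground_tree_shares,
            )
            write_raster(change.raster,
                         os.path.join(config.output_dir, f"change_{a}_{b}.tif"))
            render_change(change, os.path.join(config.output_dir, f"change_{a}_{b}.png"))
            write_raster(tr.raster,
                         os.path.join(config.output_dir, f"transitions_{a}_{b}.tif"))
            render_change(tr, os.path.join(config.output_dir,
                                           f"transitions_{a}_{b}.png"))

            rows = []
            for pair in TRANSITION_LABELS:
                s = summary.stats[pair]
                rows.append({
                    "older": s.older, "newer": s.newer, "area_m2": s.area_m2,
                    "percent_of_site": s.percent_of_site,
                    "percent_of_growth": s.percent_of_growth,
                    "percent_of_loss": s.percent_of_loss,
                })
            pd.DataFrame(rows).to_csv(
                os.path.join(config.output_dir, f"transitions_{a}_{b}.csv"),
                index=False, float_format="%.6f",
            )
            epoch_change = compare_epochs(covers[a], covers[b])
            pd.DataFrame([{
                "older": a, "newer": b,
                "growth_area_m2": change.growth_area_m2,
                "loss_area_m2": change.loss_area_m2,
                "growth_percent_of_site": change.growth_area_m2
                / covers[a].site_area_m2 * 100.0,
                "loss_percent_of_site": change.loss_area_m2
                / covers[a].site_area_m2 * 100.0,
                "percentage_point_difference": epoch_change.percentage_point_difference,
                "relative_change_percent": epoch_change.relative_change_percent,
            }]).to_csv(
                os.path.join(config.output_dir, f"change_{a}_{b}.csv"),
                index=False, float_format="%.6f",
            )
            pair_records[f"{a}->{b}"] = {
                "growth_area_m2": change.growth_area_m2,
                "loss_area_m2": change.loss_area_m2,
                "growth_percent_of_site": change.growth_area_m2
                / covers[a].site_area_m2 * 100.0,
                "loss_percent_of_site": change.loss_area_m2
                / covers[a].site_area_m2 * 100.0,
                "percentage_point_difference": epoch_change.percentage_point_difference,
                "relative_change_percent": epoch_change.relative_change_percent,
                "succession_share_percent": summary.succession_share_percent,
                "reduction_share_percent": summary.reduction_share_percent,
                "transitions": {
                    f"{p}->{q}": {
                        "area_m2": summary.stats[(p, q)].area_m2,
                        "percent_of_site": summary.stats[(p, q)].percent_of_site,
                        "percent_of_growth": summary.stats[(p, q)].percent_of_growth,
                        "percent_of_loss": summary.stats[(p, q)].percent_of_loss,
                    }
                    for p, q in TRANSITION_LABELS
                },
            }

    # --- ground verification --------------------------------------------
    verification = {}
    with _stage("ground verification"):
        for e in config.epochs:
            if e.points:
                report = verify_points(chms[e.label], cls[e.label],
                                       read_points_csv(e.points))
                report.table.to_csv(
                    os.path.join(config.output_dir, f"verification_{e.label}.csv"),
                    index=False, float_format="%.6f",
                )
                verification[e.label] = {
                    "n_points": report.n_points,
                    "n_sampled": report.n_sampled,
                    "n_band_mismatches": report.n_band_mismatches,
                    "max_overestimate_m": report.max_overestimate_m,
                    "max_underestimate_m": report.max_underestimate_m,
                }

    bundle = {
        "site": config.name,
        "scrubshift_version": __version__,
        "parameters": {
            "lower_scrub_m": scheme.lower_scrub_m,
            "upper_scrub_m": scheme.upper_scrub_m,
            "band_closure": "GROUND=[0,lower), SCRUB=[lower,upper], TREES=(upper,inf)",
            "codes": {"ground": codes.ground, "scrub": codes.scrub,
                      "trees": codes.trees},
            "connectivity": config.connectivity,
            "align_method": config.align_method,
            "clamp_negative": config.clamp_negative,
            "cell_inclusion": "cell centre inside polygon (closed test)",
            "denominator_area_m2": covers[labels[0]].site_area_m2,
            "include_ground_tree_shares": config.include_ground_tree_shares,
        },
        "cover": {lbl: covers[lbl].round_trip_dict() for lbl in labels},
        "pairs": pair_records,
        "verification": verification,
    }
    with open(os.path.join(config.output_dir, "bundle.json"), "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    return bundle
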