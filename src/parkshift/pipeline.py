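"""End-to-end orchestration: surfaces → projections → assemblages →
functional indices → model-II regression, with validation and a
reproducible run report."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assemblages as asm
from . import io as psio
from . import traitspace as ts
from .change import (
    DEFAULT_TIE_ORDER,
    CellCategory,
    ParkMask,
    SuitabilitySurface,
    apply_review_filters,
    classify_grid,
    summarize_park,
)
from .regression import ma_regression

OUTPUT_FILES = (
    "projections.csv",
    "trend_groups.csv",
    "functional_indices.csv",
    "restrictedness.csv",
    "regional_summary.csv",
    "regression.csv",
)


@dataclass
class PipelineConfig:
    surfaces: str
    parks: str
    traits: str
    review: str | None = None
    regions: str | None = None  # optional park_id,region CSV overriding parks
    seasons: tuple[str, ...] = ("summer", "winter")
    n_axes: int = 6
    functional_exclude: tuple[str, ...] = ()
    tie_order: tuple[str, ...] = tuple(c.value for c in DEFAULT_TIE_ORDER)
    n_perm: int = 999
    seed: int = 0
    out_dir: str = "out"
    base_dir: str = "."

    def __post_init__(self) -> None:
        if self.n_axes < 2:
            raise ValueError("n_axes must be >= 2")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if set(self.tie_order) != {
            c.value for c in CellCategory if c is not CellCategory.ABSENT
        }:
            raise ValueError("tie_order must list the five change categories")

    def path(self, name: str | None) -> Path | None:
        return None if name is None else Path(self.base_dir) / name

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        raw.setdefault("base_dir", str(path.parent))
        for key in ("seasons", "functional_exclude", "tie_order"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_canonical_dict(self) -> dict:
        d = {
            "surfaces": self.surfaces,
            "parks": self.parks,
            "traits": self.traits,
            "review": self.review,
            "regions": self.regions,
            "seasons": list(self.seasons),
            "n_axes": self.n_axes,
            "functional_exclude": list(self.functional_exclude),
            "tie_order": list(self.tie_order),
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    removal_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    space_msd: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stage_counts": self.stage_counts,
                "removal_fractions": self.removal_fractions,
                "space_msd": self.space_msd,
                "warnings": self.warnings,
                "manifest": self.manifest,
            },
            sort_keys=True,
            indent=2,
        )


def _load_inputs(config: PipelineConfig):
    surfaces = psio.read_surfaces(config.path(config.surfaces))
    shape = next(iter(surfaces.values())).values.shape
    parks = psio.read_parks(config.path(config.parks), shape)
    traits = psio.read_traits(config.path(config.traits))
    review = (
        psio.read_review(config.path(config.review))
        if config.review
        else pd.DataFrame(columns=["species_id", "park_id", "season", "flag"])
    )
    regions = {p.park_id: p.region for p in parks}
    if config.regions:
        rdf = pd.read_csv(config.path(config.regions))
        regions.update(dict(zip(rdf["park_id"], rdf["region"])))
    return surfaces, parks, traits, review, regions


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Static consistency checks; returns a list of issue records.

    Each issue has keys ``severity`` ("fatal" | "warning") and
    ``message``. Never mutates inputs.
    """
    issues: list[dict] = []

    def fatal(msg: str) -> None:
        issues.append({"severity": "fatal", "message": msg})

    def warn(msg: str) -> None:
        issues.append({"severity": "warning", "message": msg})

    try:
        surfaces, parks, traits, review, regions = _load_inputs(config)
    except (ValueError, FileNotFoundError, KeyError) as exc:
        fatal(str(exc))
        return issues

    shapes = {s.values.shape for s in surfaces.values()}
    if len(shapes) > 1:
        fatal(f"surfaces on incongruent grids: {sorted(shapes)}")
        return issues
    shape = shapes.pop()

    species = sorted({k[0] for k in surfaces})
    for sp in species:
        for season in config.seasons:
            for period in ("baseline", "scenario"):
                if (sp, season, period) not in surfaces:
                    fatal(f"missing surface {sp}/{season}/{period}")
    missing_traits = [sp for sp in species if sp not in traits.index]
    if missing_traits:
        fatal(f"species missing from trait table: {missing_traits}")
    if traits.isna().any().any():
        fatal("trait table has missing values")

    for p in parks:
        try:
            p.validate_against(shape)
        except ValueError as exc:
            fatal(str(exc))
        if p.park_id not in regions:
            fatal(f"park {p.park_id!r} has no region mapping")

    park_ids = {p.park_id for p in parks}
    for row in review.itertuples():
        if row.species_id not in species:
            warn(f"review flag references unknown species {row.species_id!r}")
        if row.park_id not in park_ids:
            warn(f"review flag references unknown park {row.park_id!r}")
    unknown_parks = set(config.functional_exclude) - park_ids
    if unknown_parks:
        warn(f"functional_exclude lists unknown parks: {sorted(unknown_parks)}")
    return issues


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages for each season and write the six report files."""
    issues = validate_inputs(config)
    fatal = [i["message"] for i in issues if i["severity"] == "fatal"]
    if fatal:
        raise ValueError("input validation failed: " + "; ".join(fatal))

    report = RunReport(config_hash=config.config_hash(), seed=config.seed)
    report.warnings.extend(i["message"] for i in issues)
    surfaces, parks, traits, review, regions = _load_inputs(config)
    species = sorted({k[0] for k in surfaces})
    tie_order = tuple(CellCategory(v) for v in config.tie_order)

    proj_rows = []
    all_pairs: list[asm.AssemblagePair] = []
    trend_rows = []
    func_rows = []
    tres_frames = []
    regr_rows = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for season in config.seasons:
            projections = []
            for sp in species:
                grid = classify_grid(
                    surfaces[(sp, season, "baseline")],
                    surfaces[(sp, season, "scenario")],
                )
                for park in parks:
                    proj = summarize_park(grid, park, sp, season, tie_order)
                    if proj is not None:
                        projections.append(proj)
            kept, fractions = apply_review_filters(
                projections, review[review["season"] == season]
                if "season" in review.columns and len(review)
                else review
            )
            report.stage_counts[f"projections_{season}_raw"] = len(projections)
            report.stage_counts[f"projections_{season}_kept"] = len(kept)
            report.removal_fractions[season] = fractions

            for p in kept:
                counts = {
                    f"n_{c.value}": p.category_counts.get(c, 0)
                    for c in CellCategory
                    if c is not CellCategory.ABSENT
                }
                proj_rows.append(
                    {
                        "park_id": p.park_id,
                        "species_id": p.species_id,
                        "season": season,
                        "majority": p.majority.value,
                        "present_current": p.present_current,
                        "present_future": p.present_future,
                        **counts,
                    }
                )

            pairs = []
            for park in parks:
                pair = asm.assemblage_summary(kept, park.park_id, season)
                if pair is not None:
                    pairs.append(pair)
            all_pairs.extend(pairs)
            trends = asm.classify_trend_groups(pairs, season)
            by_park = {t.park_id: t for t in trends}
            for pair in pairs:
                t = by_park.get(pair.park_id)
                trend_rows.append(
                    {
                        "park_id": pair.park_id,
                        "season": season,
                        "sp_rich_current": pair.sp_rich_current,
                        "sp_rich_future": pair.sp_rich_future,
                        "n_colonisation": pair.n_colonisation,
                        "n_extirpation": pair.n_extirpation,
                        "sorensen_turnover": pair.sorensen_turnover,
                        "jaccard_turnover": pair.jaccard_turnover,
                        "prop_colonisation": t.prop_colonisation if t else np.nan,
                        "prop_extirpation": t.prop_extirpation if t else np.nan,
                        "trend_group": t.group if t else "unclassified",
                    }
                )

            # functional stage on the non-excluded parks
            fparks = [
                p for p in parks if p.park_id not in config.functional_exclude
            ]
            fpairs = [
                p for p in pairs if p.park_id in {q.park_id for q in fparks}
            ]
            pool = sorted(set().union(*[p.current | p.future for p in fpairs]))
            if len(pool) >= config.n_axes + 2:
                space = ts.build_functional_space(
                    traits.loc[pool], n_axes=config.n_axes
                )
                report.stage_counts[f"functional_pool_{season}"] = len(pool)
                report.space_msd[season] = space.msd
                for pair in fpairs:
                    for period, members in (
                        ("baseline", pair.current),
                        ("scenario", pair.future),
                    ):
                        row = {
                            "park_id": pair.park_id,
                            "season": season,
                            "period": period,
                            "sp_rich": len(members),
                        }
                        if members:
                            pts = space.member_coords(members)
                            fric, reason = ts.functional_richness(pts, space)
                            raw, scaled = ts.functional_dispersion(pts, space)
                            row.update(
                                fric=fric,
                                fdis_raw=raw,
                                fdis_scaled=scaled,
                                undefined_reason=reason,
                            )
                        else:
                            row.update(
                                fric=None,
                                fdis_raw=None,
                                fdis_scaled=None,
                                undefined_reason="empty_assemblage",
                            )
                        func_rows.append(row)
                occurrence = {
                    (p.park_id, period): (
                        p.current if period == "baseline" else p.future
                    )
                    for p in fpairs
                    for period in ("baseline", "scenario")
                }
                tres = ts.taxon_restrictedness(
                    occurrence, [p.park_id for p in fparks], season
                )
                tres_frames.append(tres)
            else:
                warnings.warn(
                    f"{season}: pool of {len(pool)} species too small for a "
                    f"{config.n_axes}-axis functional space; stage skipped"
                )

            # model-II regression of future vs current indices
            regr_rows.extend(
                _regression_rows(
                    season, fpairs, func_rows, tres_frames, config
                )
            )
        report.warnings.extend(str(w.message) for w in caught)

    regional = asm.summarize_regions(all_pairs, regions)

    out_dir = config.path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = {
        "projections.csv": pd.DataFrame(proj_rows),
        "trend_groups.csv": pd.DataFrame(trend_rows),
        "functional_indices.csv": pd.DataFrame(func_rows),
        "restrictedness.csv": (
            pd.concat(tres_frames, ignore_index=True)
            if tres_frames
            else pd.DataFrame(columns=["species_id", "season", "period", "tres"])
        ),
        "regional_summary.csv": regional,
        "regression.csv": pd.DataFrame(regr_rows),
    }
    for name, frame in frames.items():
        path = out_dir / name
        frame.to_csv(path, index=False, float_format="%.10g")
        report.manifest[name] = _sha256(path)
    (out_dir / "run_report.json").write_text(report.to_json())
    return report


def _regression_rows(season, fpairs, func_rows, tres_frames, config):
    """Fit future-vs-current MA regressions for each index in one season."""
    rows = []
    datasets: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    if fpairs:
        datasets["sp_rich"] = (
            np.array([p.sp_rich_current for p in fpairs], dtype=float),
            np.array([p.sp_rich_future for p in fpairs], dtype=float),
        )
    fdf = pd.DataFrame([r for r in func_rows if r["season"] == season])
    if len(fdf):
        for index in ("fric", "fdis_scaled"):
            piv = fdf.pivot_table(
                index="park_id", columns="period", values=index
            ).dropna()
            if len(piv) >= 5:
                datasets[index] = (
                    piv["baseline"].to_numpy(),
                    piv["scenario"].to_numpy(),
                )
    tdf = (
        pd.concat(tres_frames, ignore_index=True) if tres_frames else pd.DataFrame()
    )
    if len(tdf):
        tdf = tdf[tdf["season"] == season]
        piv = tdf.pivot_table(
            index="species_id", columns="period", values="tres"
        ).dropna()
        if len(piv) >= 5:
            datasets["tres"] = (
                piv["baseline"].to_numpy(),
                piv["scenario"].to_numpy(),
            )

    for index, (x, y) in datasets.items():
        try:
            fit = ma_regression(
                x, y, n_perm=config.n_perm, seed=config.seed
            )
        except ValueError as exc:
            warnings.warn(f"{index}/{season}: regression skipped ({exc})")
            continue
        rows.append(
            {
                "index": index,
                "season": season,
                "n": fit.n,
                "slope": fit.slope,
                "slope_lo": fit.slope_ci[0],
                "slope_hi": fit.slope_ci[1],
                "slope_ci_wraps": fit.slope_ci_wraps,
                "intercept": fit.intercept,
                "intercept_lo": fit.intercept_ci[0],
                "intercept_hi": fit.intercept_ci[1],
                "r": fit.r,
                "p_perm": fit.p_perm,
                "n_perm": fit.n_perm,
                "departs_from_identity": fit.departs_from_identity,
            }
        )
    return rows
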