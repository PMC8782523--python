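"""Assemblage comparison metrics: richness, turnover, trend groups, regions.

Given current and future presence sets per park and season, this module
computes species richness, Sørensen and Jaccard turnover, counts of
potential colonisations/extirpations, quartile-based park trend groups,
and regional mean ± SE summary tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .change import CellCategory, ParkProjection

TREND_GROUPS = (
    "high_turnover",
    "high_potential_extirpation",
    "high_potential_colonisation",
    "intermediate_change",
    "low_change",
)


@dataclass
class AssemblagePair:
    """Current vs future assemblage of one park/season with its metrics."""

    park_id: str
    season: str
    current: frozenset[str]
    future: frozenset[str]
    sorensen_turnover: float
    jaccard_turnover: float
    n_colonisation: int
    n_extirpation: int
    n_worsening: int
    n_improving: int
    n_stable: int

    @property
    def sp_rich_current(self) -> int:
        return len(self.current)

    @property
    def sp_rich_future(self) -> int:
        return len(self.future)

    @property
    def richness_change(self) -> int:
        return self.sp_rich_future - self.sp_rich_current


def sorensen_turnover(current: set[str], future: set[str]) -> float:
    """Sørensen turnover 1 - 2|A∩B|/(|A|+|B|); 0 = identical, 1 = disjoint."""
    a, b = set(current), set(future)
    if not a and not b:
        raise ValueError("turnover undefined for two empty assemblages")
    return 1.0 - 2.0 * len(a & b) / (len(a) + len(b))


def jaccard_turnover(current: set[str], future: set[str]) -> float:
    """Jaccard turnover 1 - |A∩B|/|A∪B|; weighs unshared species more."""
    a, b = set(current), set(future)
    if not a and not b:
        raise ValueError("turnover undefined for two empty assemblages")
    return 1.0 - len(a & b) / len(a | b)


def assemblage_summary(
    projections: list[ParkProjection], park_id: str, season: str
) -> AssemblagePair | None:
    """Fold one park/season's (review-filtered) projections into a pair.

    Returns ``None`` with a warning when the park has no projections for
    the season (e.g. high-latitude parks with no wintering species).
    """
    projs = [
        p for p in projections if p.park_id == park_id and p.season == season
    ]
    if not projs:
        warnings.warn(f"no projections for {park_id}/{season}; omitted")
        return None
    current = frozenset(p.species_id for p in projs if p.present_current)
    future = frozenset(p.species_id for p in projs if p.present_future)
    by_cat = {cat: 0 for cat in CellCategory}
    for p in projs:
        by_cat[p.majority] += 1
    return AssemblagePair(
        park_id=park_id,
        season=season,
        current=current,
        future=future,
        sorensen_turnover=sorensen_turnover(current, future),
        jaccard_turnover=jaccard_turnover(current, future),
        n_colonisation=by_cat[CellCategory.POTENTIAL_COLONISATION],
        n_extirpation=by_cat[CellCategory.POTENTIAL_EXTIRPATION],
        n_worsening=by_cat[CellCategory.WORSENING],
        n_improving=by_cat[CellCategory.IMPROVING],
        n_stable=by_cat[CellCategory.STABLE],
    )


@dataclass
class TrendClassification:
    park_id: str
    season: str
    prop_colonisation: float
    prop_extirpation: float
    group: str
    quartile_cuts: dict[str, tuple[float, float, float]]  # axis -> (Q1, med, Q3)


def classify_trend_groups(
    pairs: list[AssemblagePair], season: str
) -> list[TrendClassification]:
    """Place each park into one of five trend sectors.

    The proportion of colonisations (scaled by future richness) is plotted
    against the proportion of extirpations (scaled by current richness)
    and the plane is cut by the per-axis medians and upper quartiles:

    - high_turnover: both proportions strictly above their upper quartile;
    - high_potential_colonisation / high_potential_extirpation: exactly
      one proportion strictly above its upper quartile;
    - low_change: both strictly below their median;
    - intermediate_change: everything else (including fully degenerate
      distributions, where no park clears a strict cut).

    Quartiles use numpy's linear-interpolation convention.
    """
    pairs = [p for p in pairs if p.season == season]
    if len(pairs) < 5:
        raise ValueError("need at least 5 parks for quartile-based sectors")
    usable = []
    for p in pairs:
        if p.sp_rich_future == 0 or p.sp_rich_current == 0:
            warnings.warn(
                f"{p.park_id}/{season}: empty assemblage, proportions "
                "undefined; park not classified"
            )
            continue
        usable.append(p)
    if len(usable) < 5:
        raise ValueError("fewer than 5 parks with defined proportions")

    prop_c = np.array([p.n_colonisation / p.sp_rich_future for p in usable])
    prop_e = np.array([p.n_extirpation / p.sp_rich_current for p in usable])
    cuts = {
        "colonisation": tuple(np.percentile(prop_c, [25, 50, 75])),
        "extirpation": tuple(np.percentile(prop_e, [25, 50, 75])),
    }
    _, med_c, q3_c = cuts["colonisation"]
    _, med_e, q3_e = cuts["extirpation"]

    out = []
    for p, c, e in zip(usable, prop_c, prop_e):
        hi_c, hi_e = c > q3_c, e > q3_e
        if hi_c and hi_e:
            group = "high_turnover"
        elif hi_c:
            group = "high_potential_colonisation"
        elif hi_e:
            group = "high_potential_extirpation"
        elif c < med_c and e < med_e:
            group = "low_change"
        else:
            group = "intermediate_change"
        out.append(
            TrendClassification(
                park_id=p.park_id,
                season=season,
                prop_colonisation=float(c),
                prop_extirpation=float(e),
                group=group,
                quartile_cuts=cuts,
            )
        )
    return out


def summarize_regions(
    pairs: list[AssemblagePair], regions: dict[str, str]
) -> pd.DataFrame:
    """Regional and national mean ± SE summary per season.

    One row per (region, season) plus a national row aggregating all
    parks. SE is the sample standard deviation over √n; single-park rows
    report a bare mean (SE = NaN).
    """
    rows = []
    for p in pairs:
        if p.park_id not in regions:
            raise ValueError(f"park {p.park_id!r} has no region mapping")
        rows.append(
            {
                "region": regions[p.park_id],
                "season": p.season,
                "richness_change": p.richness_change,
                "n_colonisation": p.n_colonisation,
                "n_extirpation": p.n_extirpation,
                "turnover": p.sorensen_turnover,
            }
        )
    df = pd.DataFrame(rows)
    metrics = ["richness_change", "n_colonisation", "n_extirpation", "turnover"]

    def _agg(sub: pd.DataFrame, region: str, season: str) -> dict:
        out = {"region": region, "season": season, "n_parks": len(sub)}
        for m in metrics:
            v = sub[m].to_numpy(dtype=float)
            out[f"{m}_mean"] = v.mean()
            out[f"{m}_se"] = (
                v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
            )
        return out

    results = []
    for season in sorted(df["season"].unique()):
        sdf = df[df["season"] == season]
        for region in sorted(sdf["region"].unique()):
            results.append(_agg(sdf[sdf["region"] == region], region, season))
        results.append(_agg(sdf, "National", season))
    return pd.DataFrame(results)
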