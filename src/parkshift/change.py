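"""Per-cell suitability-change classification and per-park summarization.

A species distribution model scores each grid cell with an environmental
suitability value in [0, 1] for a baseline period and a warming scenario.
A species-specific occurrence threshold converts suitability to presence.
Each cell is classified into one of five change categories (plus an
artifact ``absent`` class for cells below threshold in both periods), and
a park receives, per species and season, the category covering the largest
number of its cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd


class CellCategory(str, Enum):
    """Change category of one cell (or, by majority, one park)."""

    ABSENT = "absent"
    POTENTIAL_EXTIRPATION = "potential_extirpation"
    WORSENING = "worsening"
    STABLE = "stable"
    IMPROVING = "improving"
    POTENTIAL_COLONISATION = "potential_colonisation"


#: Categories that imply presence in the baseline period.
CURRENT_CATEGORIES = frozenset(
    {
        CellCategory.POTENTIAL_EXTIRPATION,
        CellCategory.WORSENING,
        CellCategory.STABLE,
        CellCategory.IMPROVING,
    }
)
#: Categories that imply presence under the warming scenario.
FUTURE_CATEGORIES = frozenset(
    {
        CellCategory.WORSENING,
        CellCategory.STABLE,
        CellCategory.IMPROVING,
        CellCategory.POTENTIAL_COLONISATION,
    }
)

#: Tie-break priority for the per-park majority vote (first wins).
#: Change is flagged ahead of stasis so ties err toward management attention.
DEFAULT_TIE_ORDER: tuple[CellCategory, ...] = (
    CellCategory.POTENTIAL_EXTIRPATION,
    CellCategory.POTENTIAL_COLONISATION,
    CellCategory.WORSENING,
    CellCategory.IMPROVING,
    CellCategory.STABLE,
)

REVIEW_FLAGS = ("unconfirmed_baseline", "improbable_colonisation")


@dataclass(frozen=True)
class SuitabilitySurface:
    """One species/season/period grid of suitability scores in [0, 1]."""

    values: np.ndarray
    species_id: str
    season: str
    period: str  # "baseline" | "scenario"
    threshold: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("suitability surface must be a 2-D grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("suitability surface contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("suitability values must lie in [0, 1]")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("occurrence threshold must lie in (0, 1)")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ParkMask:
    """A park as an explicit set of (row, col) grid cells."""

    park_id: str
    cells: frozenset[tuple[int, int]]
    region: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError(f"park {self.park_id!r} has an empty mask")
        object.__setattr__(self, "cells", frozenset(tuple(c) for c in self.cells))

    def validate_against(self, shape: tuple[int, int]) -> None:
        nr, nc = shape
        for r, c in self.cells:
            if not (0 <= r < nr and 0 <= c < nc):
                raise ValueError(
                    f"park {self.park_id!r} references cell ({r}, {c}) "
                    f"outside the {nr}x{nc} grid"
                )


@dataclass
class ParkProjection:
    """Majority change category of one species in one park and season."""

    park_id: str
    species_id: str
    season: str
    category_counts: dict[CellCategory, int]
    majority: CellCategory
    present_current: bool = field(init=False)
    present_future: bool = field(init=False)

    def __post_init__(self) -> None:
        cur, fut = derive_presence(self.majority)
        self.present_current = cur
        self.present_future = fut


def percent_change(baseline_value: float, scenario_value: float) -> float:
    """Percent change of scenario suitability relative to baseline.

    Defined only when the species occurs at baseline (baseline above its
    threshold); below-threshold baselines must be routed to the
    colonisation/absent branches by the classifier instead.
    """
    if baseline_value <= 0.0:
        raise ValueError(
            "percent change undefined for baseline suitability <= 0; "
            "classify such cells as colonisation or absent"
        )
    return 100.0 * (scenario_value - baseline_value) / baseline_value


def classify_cell(
    baseline_value: float, scenario_value: float, threshold: float
) -> CellCategory:
    """Classify one cell's (baseline, scenario) suitability pair.

    Presence in a period means suitability >= threshold. Present->absent is
    potential extirpation, absent->present potential colonisation, absent in
    both is the artifact ``absent`` class. For cells present in both
    periods the percent change partitions into worsening [-100, -25),
    stable [-25, +25] and improving (+25, inf); the +/-25 boundaries
    resolve to stable (conservative toward no change).
    """
    if not (math.isfinite(baseline_value) and math.isfinite(scenario_value)):
        raise ValueError("non-finite suitability value")
    present_b = baseline_value >= threshold
    present_s = scenario_value >= threshold
    if not present_b and not present_s:
        return CellCategory.ABSENT
    if present_b and not present_s:
        return CellCategory.POTENTIAL_EXTIRPATION
    if not present_b and present_s:
        return CellCategory.POTENTIAL_COLONISATION
    delta = percent_change(baseline_value, scenario_value)
    if delta < -25.0:
        return CellCategory.WORSENING
    if delta <= 25.0:
        return CellCategory.STABLE
    return CellCategory.IMPROVING


def classify_grid(
    baseline: SuitabilitySurface, scenario: SuitabilitySurface
) -> np.ndarray:
    """Vectorized per-cell classification of a whole surface pair.

    Returns an object array of :class:`CellCategory` with the grid's shape.
    """
    if baseline.values.shape != scenario.values.shape:
        raise ValueError("baseline and scenario grids differ in shape")
    if baseline.threshold != scenario.threshold:
        raise ValueError("baseline and scenario thresholds differ")
    b, s, thr = baseline.values, scenario.values, baseline.threshold
    pb, ps = b >= thr, s >= thr
    # np.full would coerce the str-enum through str(); fill keeps the object
    out = np.empty(b.shape, dtype=object)
    out.fill(CellCategory.ABSENT)
    out[pb & ~ps] = CellCategory.POTENTIAL_EXTIRPATION
    out[~pb & ps] = CellCategory.POTENTIAL_COLONISATION
    both = pb & ps
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 100.0 * (s - b) / b
    out[both & (delta < -25.0)] = CellCategory.WORSENING
    out[both & (delta >= -25.0) & (delta <= 25.0)] = CellCategory.STABLE
    out[both & (delta > 25.0)] = CellCategory.IMPROVING
    return out


def summarize_park(
    cell_categories: np.ndarray,
    mask: ParkMask,
    species_id: str,
    season: str,
    tie_order: tuple[CellCategory, ...] = DEFAULT_TIE_ORDER,
) -> ParkProjection | None:
    """Majority-cell park projection for one species and season.

    Cells absent in both periods are excluded from the vote; a park whose
    mask is entirely absent yields ``None`` (the species has no projection
    there and joins neither assemblage). Ties are broken by ``tie_order``.
    """
    mask.validate_against(cell_categories.shape)
    counts: dict[CellCategory, int] = {}
    for r, c in mask.cells:
        cat = cell_categories[r, c]
        if cat is CellCategory.ABSENT:
            continue
        counts[cat] = counts.get(cat, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    majority = next(cat for cat in tie_order if counts.get(cat, 0) == best)
    return ParkProjection(
        park_id=mask.park_id,
        species_id=species_id,
        season=season,
        category_counts=counts,
        majority=majority,
    )


def derive_presence(majority: CellCategory) -> tuple[bool, bool]:
    """Current/future presence implied by a park's majority category.

    Extirpation, worsening, stable and improving all imply baseline
    presence; worsening, stable, improving and colonisation imply presence
    under the scenario.
    """
    return majority in CURRENT_CATEGORIES, majority in FUTURE_CATEGORIES


def apply_review_filters(
    projections: list[ParkProjection],
    review: pd.DataFrame,
) -> tuple[list[ParkProjection], dict[str, float]]:
    """Apply expert-review exclusions to park projections.

    ``review`` has columns species_id, park_id, season, flag. An
    ``unconfirmed_baseline`` flag drops a record whose majority implies
    baseline presence (transient/migrant/accidental records excluded from
    the baseline to avoid overprediction); an ``improbable_colonisation``
    flag drops a record whose majority is potential colonisation. A flag
    incompatible with its record's category warns and removes nothing.

    Returns the retained projections and the fraction of input records
    removed per flag class.
    """
    required = {"species_id", "park_id", "season", "flag"}
    if not required.issubset(review.columns):
        raise ValueError(f"review table needs columns {sorted(required)}")
    dup = review.duplicated(subset=["species_id", "park_id", "season"])
    if dup.any():
        raise ValueError("review table has duplicate (species, park, season) keys")
    bad = set(review["flag"]) - set(REVIEW_FLAGS)
    if bad:
        raise ValueError(f"unknown review flags: {sorted(bad)}")

    flags = {
        (r.species_id, r.park_id, r.season): r.flag for r in review.itertuples()
    }
    kept: list[ParkProjection] = []
    removed = {f: 0 for f in REVIEW_FLAGS}
    for proj in projections:
        flag = flags.get((proj.species_id, proj.park_id, proj.season))
        if flag == "unconfirmed_baseline":
            if proj.majority in CURRENT_CATEGORIES:
                removed[flag] += 1
                continue
            warnings.warn(
                f"unconfirmed_baseline flag on a {proj.majority.value} record "
                f"({proj.species_id}/{proj.park_id}/{proj.season}); not removed"
            )
        elif flag == "improbable_colonisation":
            if proj.majority is CellCategory.POTENTIAL_COLONISATION:
                removed[flag] += 1
                continue
            warnings.warn(
                f"improbable_colonisation flag on a {proj.majority.value} record "
                f"({proj.species_id}/{proj.park_id}/{proj.season}); not removed"
            )
        kept.append(proj)
    n = len(projections)
    fractions = {f: (removed[f] / n if n else 0.0) for f in REVIEW_FLAGS}
    return kept, fractions
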