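"""Synthetic landscapes with known ground truth.

Emulates the statistical structure of gridded species-distribution-model
output: each species has a Gaussian suitability response to a latitudinal
environmental gradient; the warming scenario displaces that gradient
northward by a fixed number of cells, producing colonisation at the
leading range edge and extirpation at the trailing edge. Parks are
disjoint axis-aligned rectangles of cells; traits are five mixed-type
columns; review flags emulate the expert-screening step.

The module also carries a brute-force oracle (:func:`oracle_assemblages`)
that re-derives per-park assemblages by exhaustive per-cell enumeration,
written independently of the pipeline's classification code so tests can
compare the two routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .change import ParkMask, SuitabilitySurface

SEASONS = ("summer", "winter")

#: Trait levels used by the generator. Size is ordered smallest to largest.
TRAIT_LEVELS: dict[str, tuple[str, ...]] = {
    "feeding_behavior": (
        "ground_forager",
        "foliage_gleaner",
        "aerial_forager",
        "bark_forager",
        "probing",
    ),
    "primary_food": ("insects", "seeds", "fruit", "vertebrates", "omnivore"),
    "habitat": ("forest", "grassland", "wetland", "shoreline", "alpine"),
    "nesting": ("ground", "shrub", "cavity", "cliff", "floating"),
    "relative_size": ("very_small", "small", "medium", "large", "very_large"),
}
ORDERED_TRAITS = ("relative_size",)


@dataclass(frozen=True)
class LandscapeConfig:
    """Knobs of the synthetic landscape.

    ``shift_cells`` is the signed northward displacement (in rows) of the
    environmental gradient under the scenario; ``response_width`` the
    Gaussian niche breadth in gradient units (= rows); ``noise_sd`` the
    i.i.d. Gaussian suitability noise, clipped so values stay in [0, 1];
    ``threshold`` one shared occurrence threshold for all synthetic
    species. ``review_unconfirmed_rate`` / ``review_improbable_rate`` are
    the expected fractions of baseline-present records flagged as
    unconfirmed and of colonisation records flagged improbable,
    defaulting to the screening intensities of a real expert review
    (17% and 3.2%).
    """

    grid_rows: int = 40
    grid_cols: int = 30
    n_species: int = 30
    n_parks: int = 6
    shift_cells: int = 4
    response_width: float = 6.0
    noise_sd: float = 0.02
    threshold: float = 0.3
    seed: int = 0
    park_rows: int = 4
    park_cols: int = 4
    review_unconfirmed_rate: float = 0.17
    review_improbable_rate: float = 0.032

    def __post_init__(self) -> None:
        if self.grid_rows < 4 or self.grid_cols < 4:
            raise ValueError("grid dimensions must be at least 4x4")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.response_width <= 0:
            raise ValueError("response_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticDataset:
    """A complete generated landscape plus its ground truth."""

    config: LandscapeConfig
    surfaces: dict[tuple[str, str, str], SuitabilitySurface]  # (species, season, period)
    parks: list[ParkMask]
    traits: pd.DataFrame
    regions: dict[str, str]
    review_flags: pd.DataFrame
    truth: dict[tuple[str, str, str], frozenset[str]] = field(default_factory=dict)
    # truth key: (park_id, season, period) -> species present (pre-review)

    @property
    def species_ids(self) -> list[str]:
        return list(self.traits.index)

    def surface(self, species: str, season: str, period: str) -> SuitabilitySurface:
        return self.surfaces[(species, season, period)]


def _niche_field(
    rows: int, cols: int, mu: float, width: float, shift: int
) -> np.ndarray:
    """Noise-free suitability: Gaussian response to the row gradient.

    The gradient value of row r under a shift k is g(r) = r - k, so the
    scenario field at row r reproduces the baseline field at row r - k.
    """
    g = np.arange(rows, dtype=float) - shift
    col = np.exp(-((g - mu) ** 2) / (2.0 * width**2))
    return np.repeat(col[:, None], cols, axis=1)


def _place_parks(config: LandscapeConfig) -> list[ParkMask]:
    """Disjoint rectangular parks on a block grid, deterministic per config."""
    pr, pc = config.park_rows, config.park_cols
    blocks_r = config.grid_rows // (pr + 1)
    blocks_c = config.grid_cols // (pc + 1)
    if blocks_r * blocks_c < config.n_parks:
        raise ValueError(
            f"cannot place {config.n_parks} disjoint {pr}x{pc} parks "
            f"on a {config.grid_rows}x{config.grid_cols} grid"
        )
    # spread parks over the row blocks first so they sample the gradient
    order = [(bi % blocks_r, bi // blocks_r) for bi in range(blocks_r * blocks_c)]
    parks = []
    regions = ("north", "south")
    for k in range(config.n_parks):
        br, bc = order[k]
        r0, c0 = br * (pr + 1), bc * (pc + 1)
        cells = frozenset(
            (r, c) for r in range(r0, r0 + pr) for c in range(c0, c0 + pc)
        )
        region = regions[0] if r0 < config.grid_rows / 2 else regions[1]
        parks.append(ParkMask(park_id=f"park_{k:02d}", cells=cells, region=region))
    return parks


def generate_trait_table(n_species: int, seed: int) -> pd.DataFrame:
    """Five mixed-type traits per species, indexed by species_id.

    Four unordered categorical traits (feeding behavior, primary food,
    habitat, nesting) and one ordered size trait. No missing values.
    """
    if n_species < 2:
        raise ValueError(
            "need at least 2 species (a 1-species trait table has no "
            "pairwise distances)"
        )
    rng = np.random.default_rng(seed)
    data = {
        trait: rng.choice(levels, size=n_species)
        for trait, levels in TRAIT_LEVELS.items()
    }
    idx = pd.Index([f"sp_{i:03d}" for i in range(n_species)], name="species_id")
    df = pd.DataFrame(data, index=idx)
    df["relative_size"] = pd.Categorical(
        df["relative_size"], categories=TRAIT_LEVELS["relative_size"], ordered=True
    )
    return df


def generate_landscape(config: LandscapeConfig) -> SyntheticDataset:
    """Build a complete synthetic dataset from a config; fully seeded."""
    rng = np.random.default_rng(config.seed)
    parks = _place_parks(config)
    traits = generate_trait_table(max(config.n_species, 2), config.seed)
    traits = traits.iloc[: config.n_species]
    species = list(traits.index)

    surfaces: dict[tuple[str, str, str], SuitabilitySurface] = {}
    rows, cols = config.grid_rows, config.grid_cols
    for season in SEASONS:
        # niche optima spread across the grid rows, jittered per season
        mus = np.linspace(0, rows - 1, config.n_species) + rng.normal(
            0.0, 1.0, config.n_species
        )
        for sp, mu in zip(species, mus):
            clean_b = _niche_field(rows, cols, mu, config.response_width, 0)
            clean_s = _niche_field(
                rows, cols, mu, config.response_width, config.shift_cells
            )
            for period, clean in (("baseline", clean_b), ("scenario", clean_s)):
                vals = clean
                if config.noise_sd > 0:
                    vals = clean + rng.normal(0.0, config.noise_sd, clean.shape)
                vals = np.clip(vals, 0.0, 1.0)
                surfaces[(sp, season, period)] = SuitabilitySurface(
                    values=vals,
                    species_id=sp,
                    season=season,
                    period=period,
                    threshold=config.threshold,
                )

    regions = {p.park_id: p.region for p in parks}
    dataset = SyntheticDataset(
        config=config,
        surfaces=surfaces,
        parks=parks,
        traits=traits,
        regions=regions,
        review_flags=pd.DataFrame(
            columns=["species_id", "park_id", "season", "flag"]
        ),
    )
    dataset.truth = oracle_assemblages(dataset)
    dataset.review_flags = _generate_review_flags(dataset, rng)
    return dataset


def _generate_review_flags(
    dataset: SyntheticDataset, rng: np.random.Generator
) -> pd.DataFrame:
    """Flag a seeded fraction of records, emulating expert screening."""
    cfg = dataset.config
    rows = []
    for park in dataset.parks:
        for season in SEASONS:
            current = dataset.truth[(park.park_id, season, "baseline")]
            future = dataset.truth[(park.park_id, season, "scenario")]
            for sp in sorted(current):
                if rng.random() < cfg.review_unconfirmed_rate:
                    rows.append((sp, park.park_id, season, "unconfirmed_baseline"))
            for sp in sorted(future - current):
                if rng.random() < cfg.review_improbable_rate:
                    rows.append((sp, park.park_id, season, "improbable_colonisation"))
    return pd.DataFrame(
        rows, columns=["species_id", "park_id", "season", "flag"]
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracle. Deliberately re-derives the per-cell
# classification and majority vote with its own scalar logic; it must not
# call into parkshift.change.


def _oracle_cell_category(b: float, s: float, thr: float) -> str:
    present_b = b >= thr
    present_s = s >= thr
    if present_b and present_s:
        change = 100.0 * (s - b) / b
        if change < -25.0:
            return "worsening"
        elif change > 25.0:
            return "improving"
        else:
            return "stable"
    elif present_b:
        return "potential_extirpation"
    elif present_s:
        return "potential_colonisation"
    return "absent"


_ORACLE_TIE_ORDER = (
    "potential_extirpation",
    "potential_colonisation",
    "worsening",
    "improving",
    "stable",
)


def oracle_park_category(
    dataset: SyntheticDataset, park: ParkMask, species: str, season: str
) -> str | None:
    """Majority category for one park/species/season by cell enumeration."""
    b = dataset.surface(species, season, "baseline")
    s = dataset.surface(species, season, "scenario")
    tally: dict[str, int] = {}
    for r, c in park.cells:
        cat = _oracle_cell_category(
            float(b.values[r, c]), float(s.values[r, c]), b.threshold
        )
        if cat != "absent":
            tally[cat] = tally.get(cat, 0) + 1
    if not tally:
        return None
    top = max(tally.values())
    for cat in _ORACLE_TIE_ORDER:
        if tally.get(cat, 0) == top:
            return cat
    raise AssertionError("unreachable")


def oracle_assemblages(
    dataset: SyntheticDataset,
) -> dict[tuple[str, str, str], frozenset[str]]:
    """Ground-truth presence sets per (park, season, period), pre-review.

    A species is present at baseline when its majority category is one of
    extirpation/worsening/stable/improving, and under the scenario when it
    is one of worsening/stable/improving/colonisation.
    """
    out: dict[tuple[str, str, str], frozenset[str]] = {}
    for park in dataset.parks:
        for season in SEASONS:
            cur: set[str] = set()
            fut: set[str] = set()
            for sp in dataset.species_ids:
                cat = oracle_park_category(dataset, park, sp, season)
                if cat is None:
                    continue
                if cat in (
                    "potential_extirpation",
                    "worsening",
                    "stable",
                    "improving",
                ):
                    cur.add(sp)
                if cat in (
                    "worsening",
                    "stable",
                    "improving",
                    "potential_colonisation",
                ):
                    fut.add(sp)
            out[(park.park_id, season, "baseline")] = frozenset(cur)
            out[(park.park_id, season, "scenario")] = frozenset(fut)
    return out
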