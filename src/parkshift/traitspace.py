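"""Functional trait space: Gower distances, PCoA, richness and dispersion.

Species are placed in a low-dimensional Euclidean space built from a
mixed-type trait table (Gower distance, then principal coordinates
analysis). Functional richness of an assemblage is the convex-hull
volume it occupies as a fraction of the global pool's hull; functional
dispersion is the mean distance of its members to their centroid, scaled
by half the pool's largest pairwise distance (so an assemblage of the
pool's two most distant species scores exactly 1). Taxon restrictedness
is the fraction of parks a species occupies: 0 = absent everywhere
(completely restricted), 1 = present at every park.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform


def gower_distance(
    traits: pd.DataFrame, ordered: tuple[str, ...] = ("relative_size",)
) -> pd.DataFrame:
    """Unweighted Gower distance over mixed categorical/ordered traits.

    Unordered categorical traits contribute 0 on a match and 1 on a
    mismatch; ordered traits contribute the absolute rank difference
    scaled to the observed rank range. The distance is the plain mean of
    the per-trait contributions. A trait with a single observed level
    contributes 0 everywhere, with a warning.
    """
    if len(traits) < 2:
        raise ValueError("Gower distance needs at least 2 species")
    if traits.isna().any().any():
        raise ValueError("trait table has missing values")
    n = len(traits)
    acc = np.zeros((n, n))
    for col in traits.columns:
        s = traits[col]
        if s.nunique() < 2:
            warnings.warn(f"trait {col!r} has a single level; contributes 0")
            continue
        if col in ordered:
            if isinstance(s.dtype, pd.CategoricalDtype) and s.cat.ordered:
                ranks = s.cat.codes.to_numpy(dtype=float)
            else:
                ranks = s.to_numpy(dtype=float)
            rng = ranks.max() - ranks.min()
            contrib = np.abs(ranks[:, None] - ranks[None, :]) / rng
        else:
            vals = s.to_numpy()
            contrib = (vals[:, None] != vals[None, :]).astype(float)
        acc += contrib
    d = acc / len(traits.columns)
    return pd.DataFrame(d, index=traits.index, columns=traits.index)


@dataclass
class FunctionalSpace:
    """Species coordinates on the retained PCoA axes, plus pool geometry."""

    coords: pd.DataFrame  # species x n_axes
    eigenvalues: np.ndarray  # retained axes, non-increasing, positive
    msd: float | None = None
    pool_hull_volume: float | None = None
    pool_max_distance: float | None = None

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def member_coords(self, species: list[str] | frozenset[str]) -> np.ndarray:
        return self.coords.loc[sorted(species)].to_numpy()


def pcoa_embed(
    distances: pd.DataFrame,
    n_axes: int = 6,
    correction: str | None = "sqrt",
    eig_tol: float = 1e-10,
) -> FunctionalSpace:
    """Principal coordinates analysis of a distance matrix.

    Double-centers -D²/2, eigendecomposes, and keeps the first ``n_axes``
    positive-eigenvalue axes with coordinates eigenvector·√eigenvalue.
    ``correction="sqrt"`` square-root-transforms the dissimilarities first
    (the standard remedy that renders Gower matrices near-Euclidean);
    pass ``None`` for distances that are already Euclidean. If fewer than
    ``n_axes`` eigenvalues exceed ``eig_tol`` the call fails rather than
    silently shrinking the space.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    if correction == "sqrt":
        d = np.sqrt(d)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int(np.sum(eigval > eig_tol))
    if n_pos < n_axes:
        raise ValueError(
            f"only {n_pos} positive eigenvalues; rebuild with n_axes <= {n_pos}"
        )
    lam = eigval[:n_axes]
    coords = eigvec[:, :n_axes] * np.sqrt(lam)
    idx = (
        distances.index
        if isinstance(distances, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    return FunctionalSpace(
        coords=pd.DataFrame(
            coords, index=idx, columns=[f"axis_{i+1}" for i in range(n_axes)]
        ),
        eigenvalues=lam,
    )


def space_quality_msd(distances: pd.DataFrame, space: FunctionalSpace) -> float:
    """Embedding quality: mean squared deviation from the input distances.

    Euclidean distances in the retained space are rescaled by the
    least-squares factor Σxy/Σy² (x = input dissimilarities, y = space
    distances) before averaging the squared deviations over unordered
    pairs, so a space that reproduces the input exactly scores 0.
    """
    x = squareform(np.asarray(distances, dtype=float), checks=False)
    y = pdist(space.coords.to_numpy())
    denom = float(np.dot(y, y))
    if denom == 0.0:
        return float(np.mean(x**2))
    scale = float(np.dot(x, y)) / denom
    return float(np.mean((x - scale * y) ** 2))


def finalize_space(
    distances: pd.DataFrame, space: FunctionalSpace
) -> FunctionalSpace:
    """Attach embedding quality and global-pool hull geometry to a space."""
    space.msd = space_quality_msd(distances, space)
    pts = space.coords.to_numpy()
    space.pool_max_distance = float(pdist(pts).max())
    try:
        space.pool_hull_volume = float(ConvexHull(pts).volume)
    except QhullError as exc:
        raise ValueError(
            "global pool is degenerate in the retained space; cannot form "
            "a reference convex hull"
        ) from exc
    return space


def build_functional_space(
    traits: pd.DataFrame, n_axes: int = 6
) -> FunctionalSpace:
    """Gower → sqrt correction → PCoA → pool geometry, in one call."""
    d = gower_distance(traits)
    space = pcoa_embed(d, n_axes=n_axes, correction="sqrt")
    return finalize_space(d, space)


def functional_richness(
    member_coords: np.ndarray, space: FunctionalSpace
) -> tuple[float | None, str | None]:
    """Convex-hull volume of an assemblage as a fraction of the pool hull.

    Returns ``(fric, None)`` or ``(None, reason)`` when the assemblage has
    too few or affinely dependent members (a hull needs n_axes + 1
    affinely independent points).
    """
    if space.pool_hull_volume is None:
        raise ValueError("space lacks pool hull volume; call finalize_space")
    pts = np.asarray(member_coords, dtype=float)
    if pts.shape[0] < space.n_axes + 1:
        return None, "insufficient_species"
    try:
        vol = float(ConvexHull(pts).volume)
    except QhullError:
        return None, "degenerate_hull"
    return vol / space.pool_hull_volume, None


def functional_dispersion(
    member_coords: np.ndarray, space: FunctionalSpace
) -> tuple[float, float]:
    """Mean member-to-centroid distance, raw and pool-scaled.

    The scaled value divides by half the pool's maximum pairwise distance,
    the dispersion of a two-member assemblage of the pool's most distant
    species; it can legitimately exceed 1 (e.g. an equilateral triangle of
    side d_max scores 2/√3).
    """
    if space.pool_max_distance is None:
        raise ValueError("space lacks pool max distance; call finalize_space")
    pts = np.asarray(member_coords, dtype=float)
    if pts.shape[0] == 0:
        raise ValueError("dispersion undefined for an empty assemblage")
    centroid = pts.mean(axis=0)
    raw = float(np.linalg.norm(pts - centroid, axis=1).mean())
    return raw, raw / (space.pool_max_distance / 2.0)


def taxon_restrictedness(
    occurrence: dict[tuple[str, str], frozenset[str]],
    parks: list[str],
    season: str,
) -> pd.DataFrame:
    """Fraction of parks each species occupies, per period.

    ``occurrence`` maps (park_id, period) to the species set for the given
    season. Only species occurring somewhere in *both* periods are scored;
    others are dropped with a warning (their restrictedness in the missing
    period would be the uninformative 0).
    """
    n_parks = len(parks)
    if n_parks == 0:
        raise ValueError("no parks")
    periods = ("baseline", "scenario")
    counts: dict[str, dict[str, int]] = {p: {} for p in periods}
    for park in parks:
        for period in periods:
            for sp in occurrence.get((park, period), frozenset()):
                counts[period][sp] = counts[period].get(sp, 0) + 1
    in_both = set(counts["baseline"]) & set(counts["scenario"])
    dropped = (set(counts["baseline"]) | set(counts["scenario"])) - in_both
    if dropped:
        warnings.warn(
            f"{len(dropped)} species absent from all parks in one period "
            f"dropped from restrictedness ({season})"
        )
    rows = []
    for sp in sorted(in_both):
        for period in periods:
            rows.append(
                {
                    "species_id": sp,
                    "season": season,
                    "period": period,
                    "tres": counts[period].get(sp, 0) / n_parks,
                }
            )
    return pd.DataFrame(rows, columns=["species_id", "season", "period", "tres"])
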