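"""Reading and writing the pipeline's on-disk formats.

Suitability surfaces are headered delimited-text grids listed in a CSV
manifest; parks are GeoJSON polygons (rasterized to the grid by
cell-center containment) or an explicit cell-list CSV; traits, review
flags and regions are plain CSV. Everything round-trips losslessly at
the precision written.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

from .change import ParkMask, SuitabilitySurface
from .synthetic import TRAIT_LEVELS, SyntheticDataset

GRID_FMT = "%.10f"


# --- suitability surfaces ---------------------------------------------------


def write_surfaces(
    surfaces: dict[tuple[str, str, str], SuitabilitySurface], out_dir: Path
) -> Path:
    """Write each surface as a text grid plus a CSV manifest; returns it."""
    out_dir = Path(out_dir)
    grid_dir = out_dir / "grids"
    grid_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (sp, season, period), surf in sorted(surfaces.items()):
        fname = f"{sp}_{season}_{period}.txt"
        np.savetxt(grid_dir / fname, surf.values, fmt=GRID_FMT)
        rows.append(
            {
                "species_id": sp,
                "season": season,
                "period": period,
                "threshold": surf.threshold,
                "nrows": surf.values.shape[0],
                "ncols": surf.values.shape[1],
                "path": f"grids/{fname}",
            }
        )
    manifest = out_dir / "surfaces.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_surfaces(
    manifest_path: Path,
) -> dict[tuple[str, str, str], SuitabilitySurface]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    out = {}
    for row in df.itertuples():
        values = np.loadtxt(base / row.path, ndmin=2)
        if values.shape != (row.nrows, row.ncols):
            raise ValueError(
                f"{row.path}: grid is {values.shape}, manifest says "
                f"({row.nrows}, {row.ncols})"
            )
        out[(row.species_id, row.season, row.period)] = SuitabilitySurface(
            values=values,
            species_id=row.species_id,
            season=row.season,
            period=row.period,
            threshold=float(row.threshold),
        )
    return out


# --- parks ------------------------------------------------------------------


def write_parks_geojson(parks: list[ParkMask], path: Path) -> None:
    """Parks as polygon features in grid coordinates (x=col, y=row).

    Each cell (r, c) is the unit square [c, c+1] x [r, r+1]; a park's
    polygon is the union of its cells' squares.
    """
    features = []
    for p in sorted(parks, key=lambda q: q.park_id):
        geom = unary_union([box(c, r, c + 1, r + 1) for r, c in p.cells])
        features.append(
            {
                "type": "Feature",
                "properties": {"park_id": p.park_id, "region": p.region},
                "geometry": mapping(geom),
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_parks_geojson(path: Path, grid_shape: tuple[int, int]) -> list[ParkMask]:
    """Rasterize park polygons to the grid by cell-center containment."""
    payload = json.loads(Path(path).read_text())
    nr, nc = grid_shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    xs = (cc + 0.5).ravel()
    ys = (rr + 0.5).ravel()
    parks = []
    for feat in payload["features"]:
        geom = shape(feat["geometry"])
        inside = shapely.contains_xy(geom, xs, ys)
        cells = frozenset(
            (int(r), int(c))
            for r, c in zip(rr.ravel()[inside], cc.ravel()[inside])
        )
        if not cells:
            raise ValueError(
                f"park {feat['properties'].get('park_id')!r} rasterizes to "
                "zero cells"
            )
        parks.append(
            ParkMask(
                park_id=feat["properties"]["park_id"],
                cells=cells,
                region=feat["properties"].get("region", "unassigned"),
            )
        )
    return parks


def write_parks_cells(parks: list[ParkMask], path: Path) -> None:
    rows = [
        {"park_id": p.park_id, "row": r, "col": c, "region": p.region}
        for p in sorted(parks, key=lambda q: q.park_id)
        for r, c in sorted(p.cells)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_parks_cells(path: Path) -> list[ParkMask]:
    df = pd.read_csv(path)
    parks = []
    for park_id, sub in df.groupby("park_id", sort=True):
        region = sub["region"].iloc[0] if "region" in sub else "unassigned"
        cells = frozenset(
            (int(r), int(c)) for r, c in zip(sub["row"], sub["col"])
        )
        parks.append(ParkMask(park_id=str(park_id), cells=cells, region=region))
    return parks


def read_parks(path: Path, grid_shape: tuple[int, int]) -> list[ParkMask]:
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        return read_parks_geojson(path, grid_shape)
    return read_parks_cells(path)


# --- tables -----------------------------------------------------------------


def write_traits(traits: pd.DataFrame, path: Path) -> None:
    """Trait CSV plus a sidecar JSON declaring the ordered size levels."""
    traits.to_csv(path)
    sidecar = Path(path).with_suffix(".levels.json")
    sidecar.write_text(
        json.dumps({"relative_size": list(TRAIT_LEVELS["relative_size"])})
    )


def read_traits(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="species_id")
    sidecar = Path(path).with_suffix(".levels.json")
    if sidecar.exists():
        levels = json.loads(sidecar.read_text())
    else:
        levels = {"relative_size": list(TRAIT_LEVELS["relative_size"])}
    for col, order in levels.items():
        if col in df.columns:
            df[col] = pd.Categorical(df[col], categories=order, ordered=True)
    return df


def write_review(review: pd.DataFrame, path: Path) -> None:
    review.to_csv(path, index=False)


def read_review(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


# --- whole datasets ---------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, out_dir: Path) -> dict[str, str]:
    """Write a synthetic dataset in the formats the pipeline reads.

    Returns the file map used to assemble a pipeline config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_surfaces(dataset.surfaces, out_dir)
    write_parks_geojson(dataset.parks, out_dir / "parks.geojson")
    write_parks_cells(dataset.parks, out_dir / "parks_cells.csv")
    write_traits(dataset.traits, out_dir / "traits.csv")
    write_review(dataset.review_flags, out_dir / "review.csv")
    return {
        "surfaces": "surfaces.csv",
        "parks": "parks.geojson",
        "traits": "traits.csv",
        "review": "review.csv",
    }
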