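"""Readers and writers for the package's standard on-disk formats.

Rasters use the ESRI ASCII grid format (.asc) — the plain-text raster
interchange format classic SDM tooling consumes — one file per layer, with
stack metadata (variable names, scenario) in a JSON sidecar.  Occurrence
sets round-trip through CSV (species,x,y,source); PA matrices are written
both wide (cell_id x species) and as sparse triplets; range-map support can
be exported as a GeoJSON polygon (the union of cell boxes at the 0.5
iso-coverage level).  Generator configuration round-trips through YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .grid import ClimateStack, GridSpec, Scenario
from .occurrence import PAMatrix
from .synth import OccurrenceSet, RangeMap

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_stack",
    "read_stack",
    "write_occurrences",
    "read_occurrences",
    "write_pa_matrix",
    "read_pa_matrix",
    "range_map_to_geojson",
    "read_range_map_geojson",
    "load_config",
    "save_config",
]

_NODATA = -9999.0


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec) -> None:
    """Write one layer as an ESRI ASCII grid (.asc); NaN becomes NODATA."""
    values = np.asarray(values, dtype=float).reshape(grid.shape)
    out = np.where(np.isfinite(values), values, _NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]}\n"
        f"yllcorner {grid.origin[1]}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; NODATA cells come back as NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    values = values.reshape(grid.shape)
    nodata = header.get("nodata_value", _NODATA)
    values[values == nodata] = np.nan
    return values, grid


def write_stack(directory: str | Path, stack: ClimateStack, prefix: str = "climate") -> None:
    """Write a climate stack as one .asc per variable plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in stack.variables:
        write_ascii_grid(directory / f"{prefix}_{name}.asc", stack.layer(name), stack.grid)
    meta = {
        "variables": stack.variables,
        "scenario": {"rcp": stack.scenario.rcp, "forecast": stack.scenario.forecast},
    }
    (directory / f"{prefix}.json").write_text(json.dumps(meta, indent=2))


def read_stack(directory: str | Path, prefix: str = "climate") -> ClimateStack:
    directory = Path(directory)
    meta = json.loads((directory / f"{prefix}.json").read_text())
    layers, grid = [], None
    for name in meta["variables"]:
        values, grid = read_ascii_grid(directory / f"{prefix}_{name}.asc")
        layers.append(values)
    scen = meta["scenario"]
    return ClimateStack(
        grid, list(meta["variables"]), np.stack(layers), Scenario(scen["rcp"], scen["forecast"])
    )


def write_occurrences(path: str | Path, occurrences: list[OccurrenceSet]) -> None:
    frames = [
        pd.DataFrame(
            {
                "species": occ.species_id,
                "x": occ.points[:, 0],
                "y": occ.points[:, 1],
                "source": occ.source_tag,
            }
        )
        for occ in occurrences
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_occurrences(path: str | Path) -> list[OccurrenceSet]:
    df = pd.read_csv(path)
    out = []
    for species, sub in df.groupby("species", sort=False):
        source = str(sub["source"].iloc[0]) if "source" in sub else ""
        out.append(OccurrenceSet(str(species), sub[["x", "y"]].to_numpy(float), source))
    return out


def write_pa_matrix(path: str | Path, pa: PAMatrix, sparse: bool = False) -> None:
    """Wide CSV (cell_id + one column per species), or sparse triplets."""
    if sparse:
        cells, cols = np.nonzero(pa.values)
        pd.DataFrame(
            {"cell_id": cells, "species": [pa.species_ids[j] for j in cols], "value": 1}
        ).to_csv(path, index=False)
    else:
        df = pd.DataFrame(pa.values, columns=pa.species_ids)
        df.insert(0, "cell_id", np.arange(pa.grid.n_cells))
        df.to_csv(path, index=False)


def read_pa_matrix(path: str | Path, grid: GridSpec, provenance: str = "points") -> PAMatrix:
    df = pd.read_csv(path)
    if set(df.columns) == {"cell_id", "species", "value"}:
        species = list(pd.unique(df["species"]))
        values = np.zeros((grid.n_cells, len(species)), dtype=np.int8)
        col_idx = {s: j for j, s in enumerate(species)}
        values[df["cell_id"], [col_idx[s] for s in df["species"]]] = 1
    else:
        species = [c for c in df.columns if c != "cell_id"]
        values = np.zeros((grid.n_cells, len(species)), dtype=np.int8)
        values[df["cell_id"].to_numpy()] = df[species].to_numpy(dtype=np.int8)
    return PAMatrix(grid, species, values, provenance)


def range_map_to_geojson(rmap: RangeMap, threshold: float = 0.5) -> dict:
    """Range-map support as a GeoJSON Feature (union of cell boxes)."""
    support = rmap.coverage > threshold
    if not support.any():
        geom = None
    else:
        cs = rmap.grid.cell_size
        x0, y0 = rmap.grid.origin
        n_rows = rmap.grid.n_rows
        boxes = [
            box(x0 + c * cs, y0 + (n_rows - r - 1) * cs, x0 + (c + 1) * cs, y0 + (n_rows - r) * cs)
            for r, c in zip(*np.nonzero(support))
        ]
        geom = mapping(unary_union(boxes))
    return {
        "type": "Feature",
        "properties": {"species": rmap.species_id, "iso_coverage": threshold},
        "geometry": geom,
    }


def read_range_map_geojson(feature: dict, grid: GridSpec) -> RangeMap:
    """Rasterize a GeoJSON polygon feature to per-cell coverage fractions.

    Coverage is the exact area fraction of each cell inside the polygon
    (shapely intersection areas).
    """
    from shapely.geometry import shape

    geom = shape(feature["geometry"])
    species = str(feature.get("properties", {}).get("species", ""))
    cs = grid.cell_size
    x0, y0 = grid.origin
    coverage = np.zeros(grid.shape)
    minx, miny, maxx, maxy = geom.bounds
    for r in range(grid.n_rows):
        ylo = y0 + (grid.n_rows - r - 1) * cs
        if ylo > maxy or ylo + cs < miny:
            continue
        for c in range(grid.n_cols):
            xlo = x0 + c * cs
            if xlo > maxx or xlo + cs < minx:
                continue
            cell = box(xlo, ylo, xlo + cs, ylo + cs)
            coverage[r, c] = cell.intersection(geom).area / (cs * cs)
    return RangeMap(species, grid, np.clip(coverage, 0, 1))


def save_config(path: str | Path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
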