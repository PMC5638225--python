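"""Presence-absence matrices from range maps and point-locality records.

Two routes onto the analysis grid, mirroring the two biological data types
the pipeline compares:

* range maps: a cell is a presence iff strictly more than half of its area
  is covered by the expert polygon; everything outside is an absence;
* point records: a cell is a presence iff it contains at least one record,
  duplicates within a cell collapsing to a single presence.

Filters implement the study's inclusion rules: a strict more-than-30
presence minimum per species, removal of records farther than 200 km from
the range-map border, and endemic selection by a buffered region mask.
Distances are planar Euclidean in km on the equal-area grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import GridSpec
from .synth import OccurrenceSet, RangeMap

__all__ = [
    "PAMatrix",
    "pa_from_range_maps",
    "pa_from_points",
    "filter_min_presences",
    "filter_records_by_range",
    "select_endemics",
]


@dataclass
class PAMatrix:
    """Cells x species binary presence-absence matrix.

    ``values`` is (n_cells, n_species) with {0,1} entries; ``provenance``
    records which data type produced it ("range_map" or "points").
    """

    grid: GridSpec
    species_ids: list[str]
    values: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.grid.n_cells, len(self.species_ids)):
            raise ValueError("PA matrix shape does not match grid / species list")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("PA matrix must be binary")
        self.values = self.values.astype(np.int8)
        if self.provenance not in ("range_map", "points"):
            raise ValueError("provenance must be 'range_map' or 'points'")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def presence_counts(self) -> np.ndarray:
        """Per-species number of presence cells (column sums)."""
        return self.values.sum(axis=0)

    def column(self, species_id: str) -> np.ndarray:
        return self.values[:, self.species_ids.index(species_id)]


def pa_from_range_maps(
    maps: list[RangeMap], grid: GridSpec, coverage_threshold: float = 0.5
) -> PAMatrix:
    """Rasterize range maps to presences: coverage strictly > threshold.

    Cells not covered (or covered at or below the threshold) are absences.
    """
    values = np.zeros((grid.n_cells, len(maps)), dtype=np.int8)
    ids = []
    for j, rmap in enumerate(maps):
        if rmap.grid != grid:
            raise ValueError(f"range map {rmap.species_id!r} is on a different grid")
        values[:, j] = (rmap.coverage.ravel() > coverage_threshold).astype(np.int8)
        ids.append(rmap.species_id)
    return PAMatrix(grid, ids, values, "range_map")


def pa_from_points(occurrences: list[OccurrenceSet], grid: GridSpec) -> PAMatrix:
    """Grid point records: a cell with >= 1 record is a presence.

    Multiple records in one cell collapse to a single presence (the
    duplicate-removal rule that damps spatial autocorrelation in record
    density).  Records outside the grid extent raise.
    """
    values = np.zeros((grid.n_cells, len(occurrences)), dtype=np.int8)
    ids = []
    for j, occ in enumerate(occurrences):
        if len(occ):
            cells = grid.cell_of(occ.points[:, 0], occ.points[:, 1])
            values[np.unique(cells), j] = 1
        ids.append(occ.species_id)
    return PAMatrix(grid, ids, values, "points")


def filter_min_presences(pa: PAMatrix, min_presences: int = 30) -> PAMatrix:
    """Keep species with strictly more than ``min_presences`` presences."""
    counts = pa.presence_counts
    keep = np.nonzero(counts > min_presences)[0]
    if keep.size == 0:
        warnings.warn("no species passed the minimum-presence filter", stacklevel=2)
    return PAMatrix(
        pa.grid,
        [pa.species_ids[j] for j in keep],
        pa.values[:, keep],
        pa.provenance,
    )


def filter_records_by_range(
    occ: OccurrenceSet, rmap: RangeMap, max_dist_km: float = 200.0
) -> OccurrenceSet:
    """Drop records farther than ``max_dist_km`` from the range-map support.

    Distance is planar Euclidean (km) from each record to the nearest
    cell center with coverage > 0.5; records inside the support are at
    distance at most half a cell diagonal and always retained when
    ``max_dist_km`` exceeds that.
    """
    if occ.species_id != rmap.species_id:
        raise ValueError("occurrence set and range map describe different species")
    support = rmap.support().ravel()
    if not support.any():
        raise ValueError(f"range map for {rmap.species_id!r} has empty support")
    if len(occ) == 0:
        return occ
    centers = rmap.grid.cell_centers()[support]
    dist, _ = cKDTree(centers).query(occ.points)
    # a record in a support cell is "inside": clamp its distance to 0
    inside = support[rmap.grid.cell_of(occ.points[:, 0], occ.points[:, 1])]
    dist = np.where(inside, 0.0, dist)
    keep = dist <= max_dist_km
    return OccurrenceSet(occ.species_id, occ.points[keep], occ.source_tag)


def select_endemics(
    maps: list[RangeMap], region_mask: np.ndarray, buffer_km: float = 200.0
) -> list[str]:
    """Species whose whole range-map support lies in the buffered region.

    The region mask is dilated by ``buffer_km`` (Euclidean distance on cell
    centers); a species is endemic iff every support cell (coverage > 0.5)
    falls inside the dilated region.
    """
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("region mask is empty")
    if not maps:
        return []
    grid = maps[0].grid
    if region.shape != grid.shape:
        raise ValueError("region mask shape does not match grid")
    dist_cells = ndimage.distance_transform_edt(~region)
    buffered = dist_cells * grid.cell_size <= buffer_km
    out = []
    for rmap in maps:
        if rmap.grid != grid:
            raise ValueError("all range maps must share one grid")
        support = rmap.support()
        if support.any() and np.all(buffered[support]):
            out.append(rmap.species_id)
    return out
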