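"""Gridding of raw occurrence records.

Collections data enter the pipeline as point records; the two estimators
consume two different gridded products:

* per-pixel deduplicated presences (one presence per species per analysis
  cell) feed the SDMs, after a minimum-locality filter that drops species
  known from fewer than five distinct cells;
* coarse fishnet blocks (default 10x10 cells) holding the count of distinct
  species per block feed the interpolation, avoiding overrepresentation of
  the many single-species localities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GridGeometry, RasterGrid
from .synthetic_world import OccurrenceRecord


@dataclass(frozen=True, order=True)
class Presence:
    """A deduplicated (species, cell) presence on the analysis grid."""

    species_id: str
    row: int
    col: int


def dedupe_to_pixels(
    records: list[OccurrenceRecord], geometry: GridGeometry
) -> list[Presence]:
    """Collapse records to unique (species, cell) presences.

    Records falling in the same analysis cell represent a single presence.
    Output is sorted by species then cell index so downstream stages are
    order-independent.  Out-of-extent records raise with their indices.
    """
    if not records:
        return []
    xs = np.array([r.x for r in records])
    ys = np.array([r.y for r in records])
    inside = geometry.contains(xs, ys)
    if not inside.all():
        bad = np.nonzero(~inside)[0].tolist()
        raise ValueError(f"records outside the landscape extent at indices {bad}")
    rows, cols = geometry.cell_of(xs, ys)
    seen = {
        Presence(rec.species_id, int(r), int(c))
        for rec, r, c in zip(records, rows, cols)
    }
    return sorted(seen)


def filter_min_presences(
    presences: list[Presence], min_cells: int = 5
) -> tuple[list[Presence], set[str], set[str]]:
    """Drop species known from fewer than ``min_cells`` distinct cells.

    Returns (retained presences, retained species set, excluded species set).
    """
    counts: dict[str, int] = {}
    for p in presences:
        counts[p.species_id] = counts.get(p.species_id, 0) + 1
    retained_sp = {s for s, n in counts.items() if n >= min_cells}
    excluded_sp = set(counts) - retained_sp
    retained = [p for p in presences if p.species_id in retained_sp]
    return retained, retained_sp, excluded_sp


@dataclass
class FishnetCounts:
    """Distinct-species counts on a coarse block grid.

    ``counts`` is a RasterGrid at block resolution; ``sampled_mask`` marks
    blocks containing at least one record — a zero count outside the mask
    means "never visited", not "no species".
    """

    block_size: int
    counts: RasterGrid
    sampled_mask: np.ndarray

    def sample_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, y, value) triples at the centroids of the sampled blocks."""
        rows, cols = np.nonzero(self.sampled_mask)
        g = self.counts.geometry
        x = g.xllcorner + (cols + 0.5) * g.cellsize
        y = g.yllcorner + (rows + 0.5) * g.cellsize
        return x, y, self.counts.values[rows, cols]


def fishnet_counts(
    presences: list[Presence], geometry: GridGeometry, block_size: int = 10
) -> FishnetCounts:
    """Count distinct species per fishnet block.

    Landscape dimensions that do not divide evenly are padded: edge blocks
    cover the remainder.
    """
    n_block_rows = -(-geometry.nrows // block_size)
    n_block_cols = -(-geometry.ncols // block_size)
    block_geom = GridGeometry(
        ncols=n_block_cols,
        nrows=n_block_rows,
        xllcorner=geometry.xllcorner,
        yllcorner=geometry.yllcorner,
        cellsize=geometry.cellsize * block_size,
    )
    per_block: dict[tuple[int, int], set[str]] = {}
    for p in presences:
        key = (p.row // block_size, p.col // block_size)
        per_block.setdefault(key, set()).add(p.species_id)
    counts = np.zeros((n_block_rows, n_block_cols))
    mask = np.zeros((n_block_rows, n_block_cols), dtype=bool)
    for (br, bc), species in per_block.items():
        counts[br, bc] = len(species)
        mask[br, bc] = True
    return FishnetCounts(block_size, RasterGrid(block_geom, counts), mask)
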