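"""Richness surfaces and leave-one-area-out validation.

Two richness estimators are compared:

* ``idw`` — fishnet species counts interpolated by inverse distance
  weighting (the traditional atlas-style approach);
* ``ssdm`` — per-species maxent suitability surfaces stacked by cell-wise
  summation of the continuous logistic outputs, without thresholding to
  presence/absence.

The validation rebuilds each estimator without the records of one
well-surveyed block ("partial" model), correlates it with the all-data
"reference" model inside that block's window, and repeats for every block.
A method that generalizes spatial structure well keeps a high within-window
correlation even when the window's own data are withheld.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import maxent_core as mx
from .idw_interpolation import IDWParams, idw_richness_model
from .occurrence_grid import dedupe_to_pixels, filter_min_presences, fishnet_counts
from .raster import RasterGrid, same_geometry
from .synthetic_world import Block, Landscape, OccurrenceRecord

logger = logging.getLogger(__name__)


@dataclass
class RichnessSurface:
    method: str  # "idw" | "ssdm"
    values: RasterGrid
    provenance: str = "all records"
    skipped_species: list[str] = field(default_factory=list)


@dataclass
class SDMConfig:
    """Knobs of the per-species maxent fit used in stacking."""

    beta: float = mx.DEFAULT_BETA
    background_n: int = mx.DEFAULT_BACKGROUND_N
    tol: float = mx.DEFAULT_TOL
    folds: int = 1  # >1 averages fold models as the final surface
    min_cells: int = 5
    collinearity_threshold: float = 0.8
    fishnet_block: int = 10
    seed: int = 0


@dataclass
class PreparedFeatures:
    """Per-landscape artifacts shared by every SDM fit: background sample,
    collinearity-filtered layer list and the standardized feature matrix."""

    features: mx.FeatureSet
    background_idx: np.ndarray
    retained_layers: list[str]
    selection_report: list[dict]


def prepare_features(landscape: Landscape, config: SDMConfig) -> PreparedFeatures:
    background_idx = mx.sample_background(
        landscape.geometry.n_cells, config.background_n, seed=config.seed
    )
    retained, report = mx.select_variables(
        landscape.continuous_layers, background_idx, config.collinearity_threshold
    )
    features = mx.build_features(landscape, retained, background_idx)
    return PreparedFeatures(features, background_idx, retained, report)


def stack_richness(
    suitability_grids: list[RasterGrid], method: str = "ssdm"
) -> RichnessSurface:
    """Cell-wise sum of per-species suitability — potential richness."""
    if not suitability_grids:
        raise ValueError("at least one species grid is required")
    if not same_geometry(*suitability_grids):
        raise ValueError("geometry mismatch between species grids")
    total = np.zeros(suitability_grids[0].geometry.shape)
    for g in suitability_grids:
        total += g.values
    return RichnessSurface(method, RasterGrid(suitability_grids[0].geometry, total))


def _presence_cells(records, landscape, min_cells):
    presences = dedupe_to_pixels(records, landscape.geometry)
    retained, retained_sp, excluded_sp = filter_min_presences(presences, min_cells)
    return retained, retained_sp, excluded_sp


def ssdm_richness_model(
    records: list[OccurrenceRecord],
    landscape: Landscape,
    prepared: PreparedFeatures,
    config: SDMConfig,
    species_universe: set[str] | None = None,
    provenance: str = "all records",
) -> RichnessSurface:
    """Stacked maxent richness from a record set.

    Species are re-filtered (< ``min_cells`` distinct cells) on the given
    records; a species in ``species_universe`` that fails the filter here is
    skipped and contributes 0 to the stack (logged), mirroring the fate of
    area-endemic species in a leave-area-out run.
    """
    ncols = landscape.geometry.ncols
    presences, retained_sp, excluded_sp = _presence_cells(
        records, landscape, config.min_cells
    )
    skipped = sorted(
        (species_universe - retained_sp) if species_universe else excluded_sp
    )
    for sp in skipped:
        logger.info("ssdm[%s]: species %s below %d cells, contributes 0",
                    provenance, sp, config.min_cells)
    grids: list[RasterGrid] = []
    for sp in sorted(retained_sp):
        cells = np.array(
            [p.row * ncols + p.col for p in presences if p.species_id == sp], int
        )
        if config.folds > 1:
            cv = mx.cv_auc(
                cells, prepared.background_idx, prepared.features,
                k=config.folds, seed=config.seed, beta=config.beta, tol=config.tol,
            )
            logistic = cv.mean_logistic
        else:
            model = mx.fit_maxent(
                cells, prepared.background_idx, prepared.features,
                beta=config.beta, tol=config.tol,
            )
            logistic = mx.predict_logistic(model)
        grids.append(
            RasterGrid(landscape.geometry, logistic.reshape(landscape.geometry.shape))
        )
    surface = stack_richness(grids, "ssdm")
    surface.provenance = provenance
    surface.skipped_species = skipped
    return surface


def idw_richness_from_records(
    records: list[OccurrenceRecord],
    landscape: Landscape,
    params: IDWParams,
    config: SDMConfig,
    provenance: str = "all records",
) -> RichnessSurface:
    """Fishnet counts of the (filtered) presences, interpolated by IDW."""
    presences, _, _ = _presence_cells(records, landscape, config.min_cells)
    fishnet = fishnet_counts(presences, landscape.geometry, config.fishnet_block)
    grid = idw_richness_model(fishnet, landscape.geometry, params)
    surface = RichnessSurface("idw", grid, provenance)
    return surface


def leave_area_out(
    records: list[OccurrenceRecord],
    areas: list[Block],
    method: str,
    landscape: Landscape,
    idw_params: IDWParams | None = None,
    sdm_config: SDMConfig | None = None,
    prepared: PreparedFeatures | None = None,
) -> tuple[RichnessSurface, dict[str, RichnessSurface]]:
    """Reference model from all records plus one partial model per area.

    The partial model for area ``a`` is trained on every record whose source
    tag differs from ``a``; duplicates are removed inside each training
    subset.  Returns (reference, {area_id: partial}).
    """
    config = sdm_config or SDMConfig()
    params = idw_params or IDWParams()
    if method == "ssdm" and prepared is None:
        prepared = prepare_features(landscape, config)

    def build(subset, provenance):
        if method == "idw":
            return idw_richness_from_records(subset, landscape, params, config, provenance)
        if method == "ssdm":
            _, universe, _ = _presence_cells(records, landscape, config.min_cells)
            return ssdm_richness_model(
                subset, landscape, prepared, config,
                species_universe=universe, provenance=provenance,
            )
        raise ValueError(f"unknown method '{method}'")

    reference = build(records, "all records")
    partials: dict[str, RichnessSurface] = {}
    for i in range(len(areas)):
        area_id = f"area{i + 1}"
        subset = [r for r in records if r.source != area_id]
        partials[area_id] = build(subset, f"excluding {area_id}")
    return reference, partials


def window_correlation(
    reference: RichnessSurface, partial: RichnessSurface, window: Block
) -> float | None:
    """Pearson r between the two surfaces over the window's cells.

    Returns None (undefined, flagged upstream) when either surface is
    constant on the window — a zero would overstate what the data say.
    """
    geom = reference.values.geometry
    if (
        window.row0 < 0
        or window.col0 < 0
        or window.row0 + window.nrows > geom.nrows
        or window.col0 + window.ncols > geom.ncols
    ):
        raise ValueError("window extends outside the surface extent")
    a = reference.values.values[window.row_slice, window.col_slice].ravel()
    b = partial.values.values[window.row_slice, window.col_slice].ravel()
    if a.size == 0:
        raise ValueError("empty window")
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ValidationReport:
    """Leave-area-out correlations for both methods, one row per area."""

    entries: list[dict]
    cross_method_r: float | None

    def to_frame(self) -> pd.DataFrame:
        """Table with one row per area and the cross-method correlation as a
        single footer row."""
        rows = [dict(e, cross_method_r=pd.NA) for e in self.entries]
        rows.append(
            {
                "area": "cross_method",
                "presences_excluded": pd.NA,
                "r_idw": pd.NA,
                "r_ssdm": pd.NA,
                "cross_method_r": self.cross_method_r,
            }
        )
        return pd.DataFrame(rows)


def compare_methods(
    records: list[OccurrenceRecord],
    areas: list[Block],
    landscape: Landscape,
    idw_params: IDWParams | None = None,
    sdm_config: SDMConfig | None = None,
) -> ValidationReport:
    """The full comparison: leave-area-out for both methods plus the
    full-extent correlation between the two reference surfaces."""
    config = sdm_config or SDMConfig()
    params = idw_params or IDWParams()
    prepared = prepare_features(landscape, config)
    ref_idw, part_idw = leave_area_out(
        records, areas, "idw", landscape, params, config
    )
    ref_ssdm, part_ssdm = leave_area_out(
        records, areas, "ssdm", landscape, params, config, prepared=prepared
    )
    entries = []
    for i, area in enumerate(areas):
        area_id = f"area{i + 1}"
        excluded = [r for r in records if r.source == area_id]
        n_excluded = len(dedupe_to_pixels(excluded, landscape.geometry)) if excluded else 0
        entries.append(
            {
                "area": area_id,
                "presences_excluded": n_excluded,
                "r_idw": window_correlation(ref_idw, part_idw[area_id], area),
                "r_ssdm": window_correlation(ref_ssdm, part_ssdm[area_id], area),
            }
        )
    full = Block(0, 0, landscape.geometry.nrows, landscape.geometry.ncols)
    cross = window_correlation(ref_idw, ref_ssdm, full)
    return ValidationReport(entries, cross)
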