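"""Synthetic landscapes, virtual species and biased occurrence sampling.

This module builds a controllable stand-in for the kind of data a
presence-only richness study draws on: a stack of spatially autocorrelated
climate-like covariates (with some pairs collinear enough to trigger a
variable filter), a categorical substrate layer, a set of virtual species
with smooth environmental responses and substrate preferences, and a
two-regime sampling process — a few exhaustively surveyed rectangular
blocks versus opportunistic collecting everywhere else that is biased
toward common species, so most opportunistic localities record only one
or two species.

Everything is deterministic given the seeds carried in the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .raster import GridGeometry, RasterGrid


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Block:
    """Axis-aligned rectangle in grid coordinates (0-based, half-open)."""

    row0: int
    col0: int
    nrows: int
    ncols: int

    @property
    def row_slice(self) -> slice:
        return slice(self.row0, self.row0 + self.nrows)

    @property
    def col_slice(self) -> slice:
        return slice(self.col0, self.col0 + self.ncols)

    def contains_cell(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (
            (row >= self.row0)
            & (row < self.row0 + self.nrows)
            & (col >= self.col0)
            & (col < self.col0 + self.ncols)
        )

    def overlaps(self, other: "Block") -> bool:
        return not (
            self.row0 + self.nrows <= other.row0
            or other.row0 + other.nrows <= self.row0
            or self.col0 + self.ncols <= other.col0
            or other.col0 + other.ncols <= self.col0
        )


@dataclass
class Landscape:
    """Environmental layers on a shared geometry.

    ``continuous_layers`` maps layer name -> RasterGrid (standardized,
    finite everywhere); ``categorical_layer`` holds small integer substrate
    codes from ``categorical_codes``.
    """

    geometry: GridGeometry
    continuous_layers: dict[str, RasterGrid]
    categorical_layer: RasterGrid
    categorical_codes: tuple[int, ...]

    def __post_init__(self) -> None:
        for name, layer in self.continuous_layers.items():
            if layer.geometry != self.geometry:
                raise ValueError(f"layer '{name}' geometry mismatch")
            if not np.all(np.isfinite(layer.values)):
                raise ValueError(f"layer '{name}' has non-finite values")
        if self.categorical_layer.geometry != self.geometry:
            raise ValueError("categorical layer geometry mismatch")
        codes = np.unique(self.categorical_layer.values)
        if not set(codes.astype(int)) <= set(self.categorical_codes):
            raise ValueError("categorical layer contains undeclared codes")

    @property
    def layer_names(self) -> list[str]:
        return list(self.continuous_layers)


@dataclass
class VirtualSpecies:
    """A species with a known (logit-linear-quadratic) environmental response.

    Suitability at a cell is
    ``invlogit(intercept + sum_l w_lin[l]*z_l + w_quad[l]*z_l**2) * substrate_preference[code]``
    which lies in [0, 1] by construction.
    """

    species_id: str
    intercept: float
    linear_weights: dict[str, float]
    quadratic_weights: dict[str, float]
    substrate_preference: dict[int, float]
    prevalence: float


@dataclass
class SamplingDesign:
    """Two-regime collection effort over a landscape.

    ``systematic_blocks`` are surveyed near-exhaustively: every occupied
    (cell, species) pair inside a block is recorded with probability
    ``systematic_detection_prob``.  Elsewhere, ``opportunistic_n_localities``
    cells are visited and each occupied species is recorded with probability
    ``opportunistic_base_detection * (prevalence / max prevalence) **
    opportunistic_commonness_bias`` — the larger the bias exponent, the more
    the record stream is dominated by common species.
    """

    systematic_blocks: list[Block]
    systematic_detection_prob: float = 0.95
    opportunistic_n_localities: int = 300
    opportunistic_commonness_bias: float = 2.0
    opportunistic_base_detection: float = 0.8
    seed: int = 0

    def validate(self, geometry: GridGeometry) -> None:
        for i, b in enumerate(self.systematic_blocks):
            if b.row0 < 0 or b.col0 < 0 or b.row0 + b.nrows > geometry.nrows or b.col0 + b.ncols > geometry.ncols:
                raise ValueError(f"block {i} extends outside the landscape")
            for j, other in enumerate(self.systematic_blocks[:i]):
                if b.overlaps(other):
                    raise ValueError(f"blocks {j} and {i} overlap")
        if not 0.0 <= self.systematic_detection_prob <= 1.0:
            raise ValueError("systematic_detection_prob must be in [0, 1]")
        if not 0.0 <= self.opportunistic_base_detection <= 1.0:
            raise ValueError("opportunistic_base_detection must be in [0, 1]")
        if self.opportunistic_commonness_bias < 0:
            raise ValueError("opportunistic_commonness_bias must be >= 0")


# ---------------------------------------------------------------------------
# landscape generation


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise, standardized to mean 0, sd 1."""
    field_ = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = field_.std()
    if sd == 0:
        raise ValueError("degenerate field: zero variance (grid too small?)")
    return (field_ - field_.mean()) / sd


def gen_landscape(
    width_cells: int,
    height_cells: int,
    *,
    cell_size: float = 1.0,
    n_continuous: int = 8,
    correlated_pairs: list[tuple[int, int, float]] | None = None,
    autocorr_sigma: float = 8.0,
    n_categories: int = 3,
    categorical_sigma: float = 12.0,
    seed: int = 0,
) -> Landscape:
    """Generate a landscape of autocorrelated covariates plus a substrate layer.

    Parameters
    ----------
    correlated_pairs
        List of ``(i, j, rho)``: layer ``j`` is rebuilt as
        ``rho * layer_i + sqrt(1 - rho**2) * independent_field`` so the
        realized Pearson correlation over cells is close to ``rho``.
        Defaults to two pairs at rho = 0.9, emulating the collinearity
        found in real bioclimatic stacks.
    """
    if n_continuous < 4:
        raise ValueError("at least 4 continuous layers are required")
    if min(width_cells, height_cells) < 2:
        raise ValueError("grid too small: spatial autocorrelation undefined on a degenerate grid")
    if correlated_pairs is None:
        correlated_pairs = [(0, 1, 0.9), (2, 3, 0.9)]
    for i, j, rho in correlated_pairs:
        if abs(rho) > 1.0:
            raise ValueError(f"impossible correlation target rho={rho} for pair ({i}, {j})")
        if not (0 <= i < n_continuous and 0 <= j < n_continuous) or i == j:
            raise ValueError(f"invalid layer pair ({i}, {j})")

    rng = np.random.default_rng(seed)
    shape = (height_cells, width_cells)
    fields = [_smooth_field(rng, shape, autocorr_sigma) for _ in range(n_continuous)]
    for i, j, rho in correlated_pairs:
        extra = _smooth_field(rng, shape, autocorr_sigma)
        mixed = rho * fields[i] + np.sqrt(1.0 - rho**2) * extra
        fields[j] = (mixed - mixed.mean()) / mixed.std()

    geom = GridGeometry(ncols=width_cells, nrows=height_cells, cellsize=cell_size)
    continuous = {
        f"env{k:02d}": RasterGrid(geom, fields[k]) for k in range(n_continuous)
    }

    # contiguous substrate patches: quantile-bin one more smooth field
    cat_field = _smooth_field(rng, shape, categorical_sigma)
    edges = np.quantile(cat_field, np.linspace(0, 1, n_categories + 1)[1:-1])
    codes_arr = np.digitize(cat_field, edges)
    categorical = RasterGrid(geom, codes_arr.astype(float))
    return Landscape(
        geometry=geom,
        continuous_layers=continuous,
        categorical_layer=categorical,
        categorical_codes=tuple(range(n_categories)),
    )


# ---------------------------------------------------------------------------
# virtual species


def true_suitability(landscape: Landscape, species: VirtualSpecies) -> RasterGrid:
    """Evaluate a species' suitability surface on a landscape; values in [0, 1]."""
    eta = np.full(landscape.geometry.shape, species.intercept, dtype=float)
    for name, w in species.linear_weights.items():
        eta += w * landscape.continuous_layers[name].values
    for name, w in species.quadratic_weights.items():
        eta += w * landscape.continuous_layers[name].values ** 2
    suit = expit(eta)
    codes = landscape.categorical_layer.values.astype(int)
    mult = np.ones_like(suit)
    for code, m in species.substrate_preference.items():
        mult[codes == code] = m
    return RasterGrid(landscape.geometry, suit * mult)


def _calibrate_intercept(
    landscape: Landscape, proto: VirtualSpecies, target: float
) -> float:
    """Bisect the intercept so mean suitability equals the target prevalence."""
    lo, hi = -20.0, 20.0

    def mean_suit(b: float) -> float:
        proto.intercept = b
        return float(true_suitability(landscape, proto).values.mean())

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_suit(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_virtual_species(
    landscape: Landscape,
    n_species: int = 18,
    *,
    seed: int = 0,
    prevalence_range: tuple[float, float] = (0.02, 0.35),
    n_response_layers: int = 2,
) -> tuple[list[VirtualSpecies], list[RasterGrid], list[RasterGrid]]:
    """Draw virtual species and realize their occupancy on a landscape.

    Each species responds to a small random subset of layers through a
    unimodal (linear + negative-quadratic) logit response, prefers one
    substrate code (multiplier 1) and tolerates the others at a random
    multiplier in [0.2, 1].  The intercept is calibrated by bisection so the
    mean suitability over the landscape equals a prevalence drawn
    log-uniformly from ``prevalence_range``, mirroring the many-rare /
    few-common structure of collection data.  Occupancy is Bernoulli in the
    suitability, fixed by the seed.

    Returns (species list, suitability grids, binary occupancy grids).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = prevalence_range
    names = landscape.layer_names
    species_list: list[VirtualSpecies] = []
    suitabilities: list[RasterGrid] = []
    occupancies: list[RasterGrid] = []
    for s in range(n_species):
        prevalence = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        chosen = rng.choice(len(names), size=min(n_response_layers, len(names)), replace=False)
        # every species gets a non-trivial niche: weight magnitudes are bounded
        # away from zero so no virtual species is environmental noise
        lin = {
            names[k]: float(rng.choice([-1, 1]) * rng.uniform(1.0, 2.5))
            for k in chosen
        }
        quad = {names[k]: float(-rng.uniform(0.5, 1.5)) for k in chosen}
        preferred = int(rng.integers(len(landscape.categorical_codes)))
        pref = {
            code: 1.0 if code == preferred else float(rng.uniform(0.2, 1.0))
            for code in landscape.categorical_codes
        }
        sp = VirtualSpecies(
            species_id=f"sp{s:02d}",
            intercept=0.0,
            linear_weights=lin,
            quadratic_weights=quad,
            substrate_preference=pref,
            prevalence=prevalence,
        )
        sp.intercept = _calibrate_intercept(landscape, sp, prevalence)
        suit = true_suitability(landscape, sp)
        occ = (rng.random(landscape.geometry.shape) < suit.values).astype(float)
        species_list.append(sp)
        suitabilities.append(suit)
        occupancies.append(RasterGrid(landscape.geometry, occ))
    return species_list, suitabilities, occupancies


def true_richness(occupancies: list[RasterGrid]) -> RasterGrid:
    """Cell-wise sum of species occupancies."""
    total = np.zeros(occupancies[0].geometry.shape)
    for occ in occupancies:
        total += occ.values
    return RasterGrid(occupancies[0].geometry, total)


# ---------------------------------------------------------------------------
# sampling


@dataclass(frozen=True)
class OccurrenceRecord:
    """One collection event: a species seen at a planar location."""

    species_id: str
    x: float
    y: float
    source: str  # "area1".."areaN" or "opportunistic"


def simulate_sampling(
    occupancies: dict[str, RasterGrid],
    design: SamplingDesign,
) -> list[OccurrenceRecord]:
    """Sample occurrence records from true occupancies under a two-regime design.

    Records from systematic blocks are tagged ``area1`` .. ``areaN``;
    opportunistic records are tagged ``opportunistic``.  Opportunistic
    localities are cells drawn uniformly outside all blocks; per-species
    detection there scales with (global prevalence / max prevalence) raised
    to the commonness-bias exponent, so rare species go under-recorded.
    """
    if not occupancies:
        return []
    first = next(iter(occupancies.values()))
    geom = first.geometry
    design.validate(geom)
    rng = np.random.default_rng(design.seed)

    species_ids = list(occupancies)
    occ_stack = np.stack([occupancies[s].values for s in species_ids])  # (S, H, W)
    prevalences = occ_stack.mean(axis=(1, 2))
    records: list[OccurrenceRecord] = []

    def center(row: int, col: int) -> tuple[float, float]:
        cs = geom.cellsize
        return (geom.xllcorner + (col + 0.5) * cs, geom.yllcorner + (row + 0.5) * cs)

    # systematic: near-complete census inside each block
    for b_idx, block in enumerate(design.systematic_blocks):
        sub = occ_stack[:, block.row_slice, block.col_slice]
        s_i, r_i, c_i = np.nonzero(sub)
        detected = rng.random(s_i.size) < design.systematic_detection_prob
        for s, r, c in zip(s_i[detected], r_i[detected], c_i[detected]):
            x, y = center(block.row0 + r, block.col0 + c)
            records.append(OccurrenceRecord(species_ids[s], x, y, f"area{b_idx + 1}"))

    # opportunistic: biased toward common species, anywhere on the landscape
    # (a cell inside a systematic block can also be visited opportunistically,
    # as real collections overlap surveyed areas)
    if design.opportunistic_n_localities > 0:
        n = min(design.opportunistic_n_localities, geom.n_cells)
        flat = rng.choice(geom.n_cells, size=n, replace=False)
        out_rows, out_cols = flat // geom.ncols, flat % geom.ncols
        pick = np.arange(n)
        max_prev = prevalences.max()
        if max_prev > 0:
            detect_p = design.opportunistic_base_detection * (
                prevalences / max_prev
            ) ** design.opportunistic_commonness_bias
        else:
            detect_p = np.zeros_like(prevalences)
        for idx in pick:
            r, c = int(out_rows[idx]), int(out_cols[idx])
            present = np.nonzero(occ_stack[:, r, c])[0]
            if present.size == 0:
                continue
            detected = present[rng.random(present.size) < detect_p[present]]
            x, y = center(r, c)
            for s in detected:
                records.append(OccurrenceRecord(species_ids[s], x, y, "opportunistic"))
    return records


def locality_richness(records: list[OccurrenceRecord]) -> dict[str, list[int]]:
    """Recorded species count per collection locality, split by regime.

    Returns ``{"systematic": [...], "opportunistic": [...]}`` where each
    entry is the number of distinct species recorded at one locality (a
    distinct (x, y) sampling point).
    """
    per_loc: dict[tuple, set[str]] = {}
    for r in records:
        key = (r.x, r.y, r.source == "opportunistic")
        per_loc.setdefault(key, set()).add(r.species_id)
    out: dict[str, list[int]] = {"systematic": [], "opportunistic": []}
    for (x, y, opportunistic), species in per_loc.items():
        out["opportunistic" if opportunistic else "systematic"].append(len(species))
    return out


# ---------------------------------------------------------------------------
# the default desk-scale world


DEFAULT_BLOCKS = [
    Block(150, 150, 30, 30),
    Block(150, 20, 30, 30),
    Block(85, 85, 30, 30),
    Block(20, 150, 30, 30),
]


def default_design(seed: int = 0) -> SamplingDesign:
    return SamplingDesign(systematic_blocks=list(DEFAULT_BLOCKS), seed=seed)


def default_world(seed: int = 0) -> dict:
    """Generate the default 200x200 world: landscape, 18 species, records.

    Returns a dict with keys ``landscape``, ``species``, ``suitabilities``,
    ``occupancies``, ``design`` and ``records``.  Sub-seeds are derived from
    ``seed`` so distinct stages draw independent streams.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    landscape = gen_landscape(200, 200, seed=seeds[0])
    species, suits, occs = gen_virtual_species(landscape, 18, seed=seeds[1])
    design = default_design(seed=seeds[2])
    records = simulate_sampling(
        {sp.species_id: occ for sp, occ in zip(species, occs)}, design
    )
    return {
        "landscape": landscape,
        "species": species,
        "suitabilities": suits,
        "occupancies": occs,
        "design": design,
        "records": records,
    }
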