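"""Synthetic survey landscape with known ground truth.

The real inputs — >100k historical survey taxa lists, tens of thousands of
modern inventory plots, gridded climate and census archives — are not
publicly deposited, so this module generates a virtual landscape with the
same statistical structure and a *known* ground truth (cluster membership,
planted driver fields, planted effect sizes), giving every downstream stage
a testable, no-download surface. All tables here are synthetic by
construction; taxon ids, trait values and tolerance scores are invented,
not the study region's real species values.

Structure emulated:

* a regular grid of 5 km (25 km^2) cells partitioned into spatially
  contiguous biogeographic clusters, each with its own baseline composition;
* historical observations along survey transects — ~69% points spaced
  100-200 m apart and ~31% line descriptions of ~260 m — whose taxa lists
  name only the most abundant taxa (2-5 per list);
* modern 400 m^2 plots with species-level basal areas, including minor
  species below the 5% filter and congeneric species that must be grouped;
* monthly 1901-1980 temperature and precipitation per cell with planted
  linear trends, and censuses for 1831/1871/1951/2001 whose peak timing
  varies across cells.

The modern composition is the historical composition shifted in
centered-log-ratio (CLR) space along taxon index axes: the shift of taxon t
in cell c is beta_disturbance * z_pop(c) * L_dist(t) + (analogous
temperature and moisture terms) + spatially correlated noise, then mapped
back to the simplex, which keeps abundances valid at any effect size. The
loadings L are the centered standardized taxon indices (disturbance -> TDI,
temperature -> TTI, moisture -> TDTI), so a positive beta_disturbance
pushes composition toward disturbance-adapted (and, since shade tolerance is
built anti-correlated with disturbance adaptation, less shade-tolerant)
taxa. With all betas and noise zero the two periods are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from . import indices as fi
from .grid import Grid
from .ingest import write_observations_csv

__all__ = [
    "ScenarioConfig",
    "TaxonPool",
    "GroundTruth",
    "Scenario",
    "generate_landscape",
    "generate_taxon_pool",
    "generate_ground_truth",
    "generate_historical_surveys",
    "generate_modern_plots",
    "generate_climate_and_census",
    "simulate_scenario",
    "true_frequency_tables",
    "mention_probabilities",
    "write_scenario",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth parameters of a simulated landscape.

    Defaults define the reference scenario: a 20x20 grid of 25 km^2 cells in
    six biogeographic clusters with 17 taxa, a disturbance-driven
    compositional shift and no independent climate effect — the structure of
    the study system, scaled to a desk-size grid.
    """

    n_cells_x: int = 20
    n_cells_y: int = 20
    n_clusters: int = 6
    n_taxa: int = 17
    #: CLR shift per unit standardized log population change
    beta_disturbance: float = 1.5
    beta_temperature: float = 0.0
    beta_moisture: float = 0.0
    obs_per_cell: int = 40
    plots_per_cell: int = 8
    #: sd of the spatially correlated cell-level CLR residual
    noise_sd: float = 0.15
    spatial_range_km: float = 15.0
    #: share of point (vs line) observations
    point_fraction: float = 0.69
    #: planted mean temperature trend (degC/yr) and its across-cell sd
    temp_trend: float = 0.01
    temp_trend_sd: float = 0.004
    #: planted precipitation trend (mm/month per yr) and its across-cell sd
    prcp_trend: float = 0.0
    prcp_trend_sd: float = 0.05
    #: sd of monthly temperature noise around the seasonal cycle (degC)
    climate_noise_sd: float = 1.5
    n_years: int = 80
    start_year: int = 1901
    cell_size_km: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_cells_x,
            self.n_cells_y,
            self.n_clusters,
            self.n_taxa,
            self.obs_per_cell,
            self.plots_per_cell,
            self.n_years,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.n_clusters > self.n_cells_x * self.n_cells_y:
            raise ValueError("n_clusters exceeds the number of cells")
        if not 0.0 <= self.point_fraction <= 1.0:
            raise ValueError("point_fraction must be in [0, 1]")
        for name in ("beta_disturbance", "beta_temperature", "beta_moisture"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0 or self.spatial_range_km <= 0:
            raise ValueError("noise_sd >= 0 and spatial_range_km > 0 required")

    def grid(self) -> Grid:
        return Grid(self.n_cells_x, self.n_cells_y, self.cell_size_km)


@dataclass
class TaxonPool:
    """Species pool: traits, tolerance scores, ranges, genus structure."""

    species: list[str]
    genus_map: dict[str, str]
    trait_table: pd.DataFrame  # species x 11 traits
    orientations: dict[str, int]
    tolerance: pd.DataFrame  # species x (tdti, tsti), 1-5 scale
    temperature_raster: np.ndarray
    range_masks: dict[str, np.ndarray]
    species_share: pd.Series  # within-taxon abundance share of each species

    @property
    def taxa(self) -> list[str]:
        return sorted(set(self.genus_map.values()))

    def taxon_indices(self, tti_statistic: str = "median") -> pd.DataFrame:
        """Raw taxon-level TTI/TDTI/TSTI/TDI (genus-averaged)."""
        tti = pd.Series(
            {
                sp: fi.compute_tti(
                    self.range_masks[sp], self.temperature_raster, tti_statistic
                )
                for sp in self.species
            },
            name="tti",
        )
        tdi = fi.compute_tdi(self.trait_table, self.orientations).rename("tdi")
        sp_idx = pd.concat([tti, self.tolerance, tdi], axis=1)
        return fi.genus_average(sp_idx, self.genus_map)

    def standardized_indices(self, tti_statistic: str = "median") -> pd.DataFrame:
        return fi.standardize_indices(self.taxon_indices(tti_statistic))


@dataclass
class GroundTruth:
    """Planted truth of a scenario."""

    cluster: np.ndarray  # cell -> cluster label
    hist_abund: np.ndarray  # (n_cells, n_taxa) simplex rows
    mod_abund: np.ndarray
    taxa: list[str]
    pop_change: np.ndarray  # persons/km^2
    temp_slope: np.ndarray  # degC/yr
    prcp_slope: np.ndarray  # mm/month per yr


@dataclass
class Scenario:
    """Everything a downstream pipeline needs, bundled."""

    config: ScenarioConfig
    grid: Grid
    pool: TaxonPool
    truth: GroundTruth
    observations: pd.DataFrame
    plots: pd.DataFrame
    climate: pd.DataFrame
    census: pd.DataFrame


# -- landscape and truth ------------------------------------------------------


def generate_landscape(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[Grid, np.ndarray]:
    """Grid plus contiguous cluster labels (Voronoi around seed cells)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    grid = config.grid()
    cents = grid.centroids().to_numpy()
    seeds = rng.choice(grid.n_cells, size=config.n_clusters, replace=False)
    d = cdist(cents, cents[seeds])
    labels = np.argmin(d, axis=1)

    # Voronoi regions are convex, but their rasterization onto cells can in
    # rare cases pinch off a corner-connected fragment; reattach any minor
    # fragment to the dominant neighboring cluster.
    adj = grid.adjacency()
    for _ in range(grid.n_cells):
        changed = False
        for lab in range(config.n_clusters):
            members = np.flatnonzero(labels == lab)
            if members.size == 0:
                continue
            sub = adj[members][:, members]
            n_comp, comp = connected_components(sub, directed=False)
            if n_comp == 1:
                continue
            sizes = np.bincount(comp)
            main = np.argmax(sizes)
            for frag in members[comp != main]:
                neigh = adj[frag].indices
                neigh_labs = labels[neigh]
                neigh_labs = neigh_labs[neigh_labs != lab]
                if neigh_labs.size:
                    labels[frag] = np.bincount(neigh_labs).argmax()
                    changed = True
        if not changed:
            break
    return grid, labels


def _smooth_field(
    rng: np.random.Generator, cents: np.ndarray, range_km: float, n: int = 1
) -> np.ndarray:
    """Spatially correlated standard-normal field(s) on cell centroids."""
    D = cdist(cents, cents)
    C = np.exp(-D / range_km) + 1e-8 * np.eye(len(cents))
    L = np.linalg.cholesky(C)
    z = L @ rng.standard_normal((len(cents), n))
    return z[:, 0] if n == 1 else z


def _clr(p: np.ndarray) -> np.ndarray:
    logp = np.log(p)
    return logp - logp.mean(axis=-1, keepdims=True)


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _scale_driver(v: np.ndarray) -> np.ndarray:
    """Scale a planted driver field by its spread without centering.

    Drivers act with their actual sign and level (all cells with positive
    population change shift toward disturbance-adapted taxa, more so where
    the change is larger); a spatially constant field passes unscaled.
    """
    sd = v.std()
    return v / sd if sd > 0 else v.astype(float)


def generate_taxon_pool(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> TaxonPool:
    """Synthetic species pool spanning gradients of all four indices.

    Species carry a latent disturbance-adaptation score u in [0, 1]; the 11
    TDI traits are noisy monotone functions of u with realistic ranges and
    declared orientations, and shade tolerance (hence TSTI) decreases with
    u, mirroring the real-world anti-correlation between shade tolerance and
    disturbance adaptation. Drought tolerance is independent. Geographic
    ranges are latitudinal bands on a synthetic continental temperature
    raster so the TTI axis spans cold- to warm-affiliated species. The first
    min(4, n_taxa) taxa are multi-species genus groups (2 species each) to
    exercise genus averaging and grouping.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if config.n_taxa < 2:
        raise ValueError("taxon pool requires n_taxa >= 2")
    taxa = [f"tax{i:02d}" for i in range(config.n_taxa)]
    n_multi = min(4, config.n_taxa)
    species: list[str] = []
    genus_map: dict[str, str] = {}
    for i, tax in enumerate(taxa):
        members = [f"{tax}_sp{j}" for j in (1, 2)] if i < n_multi else [tax]
        species.extend(members)
        for sp in members:
            genus_map[sp] = tax
    n_sp = len(species)

    u = rng.permutation(np.linspace(0.0, 1.0, n_sp))  # latent disturbance axis

    def trait(lo, hi, increasing, noise=0.12):
        base = u if increasing else 1.0 - u
        val = lo + (hi - lo) * np.clip(
            base + noise * rng.standard_normal(n_sp), 0.0, 1.0
        )
        return val

    # orientation: +1 when a larger raw value means more disturbance-adapted
    orientations = {
        "shade_tolerance": -1,
        "growth_rate": +1,
        "longevity": -1,
        "age_sexual_maturity": -1,
        "vegetative_reproduction": +1,
        "fruiting_frequency": +1,
        "seed_abundance": +1,
        "seed_dispersal": +1,
        "germination_substrate": +1,
        "seedling_vigor": +1,
        "response_to_release": +1,
    }
    trait_table = pd.DataFrame(
        {
            "shade_tolerance": trait(1.0, 5.0, increasing=False),
            "growth_rate": trait(10.0, 90.0, increasing=True),  # cm/yr
            "longevity": trait(80.0, 400.0, increasing=False),  # yr
            "age_sexual_maturity": trait(5.0, 40.0, increasing=False),  # yr
            "vegetative_reproduction": np.round(trait(0.0, 3.0, True)),
            "fruiting_frequency": trait(1.0, 5.0, increasing=True),
            "seed_abundance": trait(1.0, 5.0, increasing=True),
            "seed_dispersal": trait(1.0, 5.0, increasing=True),
            "germination_substrate": trait(1.0, 5.0, increasing=True),
            "seedling_vigor": trait(1.0, 5.0, increasing=True),
            "response_to_release": np.round(trait(0.0, 4.0, True)),
        },
        index=pd.Index(species, name="species"),
    )
    tolerance = pd.DataFrame(
        {
            "tdti": rng.uniform(1.0, 5.0, n_sp),
            "tsti": trait_table["shade_tolerance"].to_numpy(),
        },
        index=trait_table.index,
    )

    # synthetic continental raster: colder northward (increasing row index)
    n_rows, n_cols = 60, 40
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    raster = 26.0 - 0.45 * rows + 0.02 * cols
    # latitudinal range bands per species, ordered by a thermal optimum
    optimum = rng.permutation(np.linspace(0.05, 0.95, n_sp))
    masks: dict[str, np.ndarray] = {}
    half_height = max(4, n_rows // 8)
    for sp, opt in zip(species, optimum):
        center = int(round((1.0 - opt) * (n_rows - 1)))
        lo = max(0, center - half_height)
        hi = min(n_rows, center + half_height + 1)
        m = np.zeros((n_rows, n_cols), dtype=bool)
        m[lo:hi, :] = True
        masks[sp] = m

    share = pd.Series(1.0, index=trait_table.index)
    for tax in taxa:
        members = [s for s, t in genus_map.items() if t == tax]
        if len(members) > 1:
            w = rng.dirichlet(np.full(len(members), 3.0))
            share[members] = w
    return TaxonPool(
        species=species,
        genus_map=genus_map,
        trait_table=trait_table,
        orientations=orientations,
        tolerance=tolerance,
        temperature_raster=raster,
        range_masks=masks,
        species_share=share,
    )


def generate_ground_truth(
    config: ScenarioConfig,
    grid: Grid,
    cluster: np.ndarray,
    pool: TaxonPool,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Plant per-cell compositions and driver fields.

    Historical composition = cluster baseline jittered (identically shared
    by both periods) in CLR space; modern composition = historical shifted
    along the taxon index loadings by the planted betas times the
    standardized driver fields, plus spatially correlated noise.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    cents = grid.centroids().to_numpy()
    n_cells = grid.n_cells
    taxa = pool.taxa
    n_taxa = len(taxa)

    baselines = rng.dirichlet(np.full(n_taxa, 1.5), size=config.n_clusters)
    baselines = np.clip(baselines, 1e-4, None)
    baselines /= baselines.sum(axis=1, keepdims=True)
    hist_clr = _clr(baselines[cluster])
    hist_clr += 0.15 * rng.standard_normal(hist_clr.shape)  # within-cluster
    hist = _softmax(hist_clr)

    # planted driver fields: settlement strongest in the south (low y)
    y_rel = 1.0 - cents[:, 1] / cents[:, 1].max() if n_cells > 1 else np.ones(1)
    z_raw = 1.6 * y_rel + 0.5 * _smooth_field(rng, cents, config.spatial_range_km)
    pop_change = np.maximum(10.0 ** np.clip(z_raw, 0.0, 2.2) - 1.0, 0.0)
    temp_slope = config.temp_trend + config.temp_trend_sd * _smooth_field(
        rng, cents, config.spatial_range_km
    )
    prcp_slope = config.prcp_trend + config.prcp_trend_sd * _smooth_field(
        rng, cents, config.spatial_range_km
    )

    std = pool.standardized_indices()
    std = std.loc[taxa]
    load_dist = std["tdi"].to_numpy() - std["tdi"].mean()
    load_temp = std["tti"].to_numpy() - std["tti"].mean()
    load_moist = std["tdti"].to_numpy() - std["tdti"].mean()

    z_pop = _scale_driver(np.log10(pop_change + 1.0))
    z_temp = _scale_driver(temp_slope)
    z_moist = _scale_driver(prcp_slope)

    shift = (
        config.beta_disturbance * np.outer(z_pop, load_dist)
        + config.beta_temperature * np.outer(z_temp, load_temp)
        + config.beta_moisture * np.outer(z_moist, load_moist)
    )
    if config.noise_sd > 0:
        noise = config.noise_sd * _smooth_field(
            rng, cents, config.spatial_range_km, n=n_taxa
        )
        shift = shift + noise
    mod = _softmax(_clr(hist) + shift)
    return GroundTruth(
        cluster=cluster,
        hist_abund=hist,
        mod_abund=mod,
        taxa=taxa,
        pop_change=pop_change,
        temp_slope=temp_slope,
        prcp_slope=prcp_slope,
    )


# -- observation and plot sampling --------------------------------------------


def _list_length(rng: np.random.Generator, n_available: int) -> int:
    """Taxa per list: 2 + Binomial(3, 0.5), capped by available taxa."""
    return min(2 + rng.binomial(3, 0.5), n_available)


def _sample_taxa_list(
    rng: np.random.Generator, abund: np.ndarray, taxa: list[str]
) -> list[str]:
    """Most-abundant-taxa list: Gumbel-perturbed abundance ranking.

    Equivalent to sampling an ordering from a Plackett-Luce model with
    weights proportional to abundance and keeping the top k — taxa with
    zero abundance can never appear.
    """
    pos = np.flatnonzero(abund > 0)
    if pos.size == 0:
        raise ValueError("cell with degenerate all-zero abundance")
    k = _list_length(rng, pos.size)
    scores = np.log(abund[pos]) + rng.gumbel(size=pos.size)
    top = pos[np.argsort(scores)[::-1][:k]]
    return [taxa[i] for i in sorted(top)]


def generate_historical_surveys(
    config: ScenarioConfig,
    grid: Grid,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Survey observations along synthetic transects through each cell.

    Each cell is crossed by west-east transects until ``obs_per_cell``
    observations exist: ~``point_fraction`` point observations spaced
    100-200 m apart, the rest line descriptions of ~260 m, each carrying a
    truncated most-abundant-taxa list sampled from the cell's historical
    composition.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    size = grid.cell_size_km
    rows = []
    for cell in range(grid.n_cells):
        abund = truth.hist_abund[cell]
        if not (abund > 0).any():
            raise ValueError(f"cell {cell}: degenerate all-zero abundance")
        ix, iy = cell % grid.n_x, cell // grid.n_x
        x0 = grid.origin[0] + ix * size
        y0 = grid.origin[1] + iy * size
        emitted = 0
        transect = 0
        while emitted < config.obs_per_cell:
            line_id = f"c{cell}_t{transect}"
            yline = y0 + rng.uniform(0.1, 0.9) * size
            x = x0 + rng.uniform(0.02, 0.08) * size
            seq = 0
            while emitted < config.obs_per_cell and x < x0 + 0.98 * size:
                taxa_list = _sample_taxa_list(rng, abund, truth.taxa)
                if rng.uniform() < config.point_fraction:
                    rows.append(
                        (f"o{cell}_{transect}_{seq}", line_id, seq, "point",
                         x, yline, np.nan, np.nan, taxa_list)
                    )
                    x += rng.uniform(0.100, 0.200)
                else:
                    length = np.clip(rng.normal(0.260, 0.030), 0.15, 0.40)
                    rows.append(
                        (f"o{cell}_{transect}_{seq}", line_id, seq, "line",
                         x, yline, min(x + length, x0 + size), yline, taxa_list)
                    )
                    x += length + rng.uniform(0.100, 0.200)
                seq += 1
                emitted += 1
            transect += 1
    return pd.DataFrame(
        rows,
        columns=["obs_id", "line_id", "seq", "kind", "x", "y", "x2", "y2", "taxa"],
    )


def generate_modern_plots(
    config: ScenarioConfig,
    grid: Grid,
    truth: GroundTruth,
    pool: TaxonPool,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Species-level basal areas for 400 m^2 plots scattered in each cell.

    Plot composition is Dirichlet-distributed around the cell's modern
    species abundance (taxon abundance split by fixed within-genus shares),
    scaled by a lognormal total basal area, so plots routinely contain minor
    species below the 5% relative-basal-area cut and congeneric species
    recorded at species level.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    size = grid.cell_size_km
    tax_pos = {t: i for i, t in enumerate(truth.taxa)}
    sp_names = pool.species
    sp_weights = np.array(
        [
            pool.species_share[sp] * 1.0  # taxon abundance applied per cell
            for sp in sp_names
        ]
    )
    tax_of_sp = np.array([tax_pos[pool.genus_map[sp]] for sp in sp_names])
    rows = []
    conc = 25.0  # Dirichlet concentration: sampling noise among plots
    for cell in range(grid.n_cells):
        abund_sp = truth.mod_abund[cell][tax_of_sp] * sp_weights
        if not (abund_sp > 0).any():
            raise ValueError(f"cell {cell}: degenerate all-zero abundance")
        abund_sp = abund_sp / abund_sp.sum()
        ix, iy = cell % grid.n_x, cell // grid.n_x
        x0 = grid.origin[0] + ix * size
        y0 = grid.origin[1] + iy * size
        for p in range(config.plots_per_cell):
            pid = f"p{cell}_{p}"
            px = x0 + rng.uniform(0.02, 0.98) * size
            py = y0 + rng.uniform(0.02, 0.98) * size
            comp = rng.dirichlet(np.maximum(conc * abund_sp, 1e-3))
            total_ba = rng.lognormal(np.log(28.0), 0.3)  # m^2/ha
            ba = comp * total_ba
            for s, b in zip(sp_names, ba):
                if b > 1e-3:
                    rows.append((pid, px, py, s, b))
    return pd.DataFrame(
        rows, columns=["plot_id", "x", "y", "species", "basal_area"]
    )


# -- climate and census --------------------------------------------------------


def generate_climate_and_census(
    config: ScenarioConfig,
    grid: Grid,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly climate series and census densities per cell.

    Temperature: latitude-dependent mean + seasonal cycle + planted linear
    trend (applied at monthly resolution, so the annual-mean slope equals
    the planted slope exactly) + optional Gaussian noise. Precipitation:
    gamma-distributed months around a seasonal mean with an optional planted
    trend. Census densities realize the planted population change with the
    peak census year varying across cells.
    """
    rng = np.random.default_rng(config.seed + 5) if rng is None else rng
    cents = grid.centroids()
    n_months = config.n_years * 12
    t_idx = np.arange(n_months)
    month = t_idx % 12
    year = config.start_year + t_idx // 12
    season_t = -12.0 * np.cos(2.0 * np.pi * (month + 0.5) / 12.0)
    season_p = 80.0 + 20.0 * np.sin(2.0 * np.pi * (month + 0.5) / 12.0)

    clim_rows = []
    for cell in range(grid.n_cells):
        lat = 45.0 + cents.loc[cell, "y"] / 111.0
        base = 5.0 - 0.3 * (lat - 45.0)
        trend = truth.temp_slope[cell] * (t_idx + 0.5) / 12.0
        noise = (
            config.climate_noise_sd * rng.standard_normal(n_months)
            if config.climate_noise_sd > 0
            else 0.0
        )
        tmean = base + season_t + trend + noise
        p_mean = np.maximum(
            season_p + truth.prcp_slope[cell] * (t_idx + 0.5) / 12.0, 1.0
        )
        shape = 4.0
        prcp = rng.gamma(shape, p_mean / shape)
        clim_rows.append(
            pd.DataFrame(
                {
                    "cell": cell,
                    "year": year,
                    "month": month + 1,
                    "tmean": tmean,
                    "prcp": prcp,
                    "latitude": lat,
                }
            )
        )
    climate = pd.concat(clim_rows, ignore_index=True)

    census_years = np.array([1871, 1951, 2001])
    cen_rows = []
    for cell in range(grid.n_cells):
        d0 = rng.uniform(0.5, 2.0)
        peak = rng.integers(3)
        dens = {1831: d0}
        for i, yr in enumerate(census_years):
            if i == peak:
                dens[yr] = d0 + truth.pop_change[cell]
            else:
                dens[yr] = d0 + truth.pop_change[cell] * rng.uniform(0.2, 0.9)
        for yr, d in dens.items():
            cen_rows.append((cell, yr, d))
    census = pd.DataFrame(cen_rows, columns=["cell", "year", "density"])
    return climate, census


# -- truth-level frequencies ---------------------------------------------------


def mention_probabilities(
    abund: np.ndarray, n_mc: int = 3000, seed: int = 12345
) -> np.ndarray:
    """Probability each taxon appears on a most-abundant-taxa list.

    Deterministic Monte-Carlo evaluation (fixed internal seed) of the same
    Plackett-Luce top-k list model used when sampling observations; identical
    abundance vectors always map to identical probabilities.
    """
    rng = np.random.default_rng(seed)
    abund = np.asarray(abund, dtype=float)
    pos = np.flatnonzero(abund > 0)
    if pos.size == 0:
        raise ValueError("degenerate all-zero abundance")
    k = np.minimum(2 + rng.binomial(3, 0.5, size=n_mc), pos.size)
    scores = np.log(abund[pos])[None, :] + rng.gumbel(size=(n_mc, pos.size))
    order = np.argsort(-scores, axis=1)
    hits = np.zeros(abund.size)
    ranks = np.empty_like(order)
    rows = np.arange(n_mc)[:, None]
    ranks[rows, order] = np.arange(pos.size)[None, :]
    inlist = ranks < k[:, None]
    hits[pos] = inlist.mean(axis=0)
    return hits


def true_frequency_tables(
    truth: GroundTruth, n_mc: int = 3000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sampling-free per-cell frequency tables for both periods.

    Applies the identical list-mention model to the true historical and
    modern compositions, so differences between the two tables reflect the
    planted compositional shift only — with no planted effects the tables
    are bit-identical and every downstream Delta index is exactly zero.
    """
    out = []
    for period, ab in (
        ("historical", truth.hist_abund),
        ("modern", truth.mod_abund),
    ):
        rows = []
        for cell in range(ab.shape[0]):
            probs = mention_probabilities(ab[cell], n_mc=n_mc)
            for t, pr in zip(truth.taxa, probs):
                rows.append((period, cell, t, pr, 1.0))
        out.append(
            pd.DataFrame(
                rows, columns=["period", "cell", "taxon", "frequency", "effort"]
            )
        )
    return out[0], out[1]


# -- top-level -----------------------------------------------------------------


def simulate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate the full virtual landscape for one scenario."""
    grid, cluster = generate_landscape(config)
    pool = generate_taxon_pool(config)
    truth = generate_ground_truth(config, grid, cluster, pool)
    observations = generate_historical_surveys(config, grid, truth)
    plots = generate_modern_plots(config, grid, truth, pool)
    climate, census = generate_climate_and_census(config, grid, truth)
    return Scenario(
        config=config,
        grid=grid,
        pool=pool,
        truth=truth,
        observations=observations,
        plots=plots,
        climate=climate,
        census=census,
    )


def write_scenario(scenario: Scenario, outdir) -> None:
    """Write the scenario's tables as plain CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_observations_csv(scenario.observations, outdir / "observations.csv")
    scenario.plots.to_csv(outdir / "plots.csv", index=False)
    scenario.climate.to_csv(outdir / "climate.csv", index=False)
    scenario.census.to_csv(outdir / "census.csv", index=False)
    scenario.pool.trait_table.to_csv(outdir / "traits.csv")
    scenario.pool.tolerance.to_csv(outdir / "tolerance.csv")
    np.savetxt(
        outdir / "temperature_raster.csv",
        scenario.pool.temperature_raster,
        delimiter=",",
        fmt="%.3f",
    )
    pd.DataFrame(
        {
            "cell": np.arange(scenario.grid.n_cells),
            "cluster": scenario.truth.cluster,
            "pop_change": scenario.truth.pop_change,
            "temp_slope": scenario.truth.temp_slope,
            "prcp_slope": scenario.truth.prcp_slope,
        }
    ).to_csv(outdir / "ground_truth.csv", index=False)
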