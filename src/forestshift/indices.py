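"""Taxon-level functional indices and community-weighted means.

Four taxon-level indices describe each tree taxon's affinities:

* **TTI** (taxon temperature index, degC) — a statistic (median by default)
  of annual temperature over the taxon's geographic range.
* **TDTI** / **TSTI** — drought and shade tolerance scores on the usual
  1 (low) to 5 (high) literature scale.
* **TDI** (taxon disturbance index) — an 11-trait point score: each trait is
  oriented so that larger means more disturbance-adapted, min–max scaled to
  [0, 1] across the species pool, and summed, giving a raw score in [0, 11].

Species-level indices are averaged to the (possibly genus-level) taxa used
by historical surveyors, then every index is min–max standardized to [0, 1]
across the taxon pool so the four community indices are directly comparable.
Community indices (CTI, CDTI, CSTI, CDI) are frequency-weighted means of the
standardized taxon values per grid cell and period; their temporal change
(modern minus historical) lies in [-1, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "INDEX_NAMES",
    "STAND_REPLACING_TRAITS",
    "PARTIAL_DISTURBANCE_TRAITS",
    "TDI_TRAITS",
    "compute_tti",
    "compute_tdi",
    "genus_average",
    "standardize_indices",
    "community_index",
    "delta_indices",
]

INDEX_NAMES = ("tti", "tdti", "tsti", "tdi")

# Traits primarily reflecting adaptation to stand-replacing disturbance.
STAND_REPLACING_TRAITS = (
    "shade_tolerance",
    "growth_rate",
    "longevity",
    "age_sexual_maturity",
    "vegetative_reproduction",
)
# Traits reflecting adaptation to both stand-replacing and partial disturbance.
PARTIAL_DISTURBANCE_TRAITS = (
    "fruiting_frequency",
    "seed_abundance",
    "seed_dispersal",
    "germination_substrate",
    "seedling_vigor",
    "response_to_release",
)
TDI_TRAITS = STAND_REPLACING_TRAITS + PARTIAL_DISTURBANCE_TRAITS


def compute_tti(
    range_mask: np.ndarray,
    temperature_raster: np.ndarray,
    statistic: str = "median",
) -> float:
    """Temperature-affinity index: a statistic of temperature over a range.

    Parameters
    ----------
    range_mask
        Boolean array, True where the taxon occurs; same shape as the raster.
    temperature_raster
        Annual-mean temperature per pixel (degC). NaN marks missing pixels.
    statistic
        One of ``median``, ``mean``, ``p10``, ``p90``. Percentiles use
        linear interpolation between order statistics.
    """
    mask = np.asarray(range_mask, dtype=bool)
    raster = np.asarray(temperature_raster, dtype=float)
    if mask.shape != raster.shape:
        raise ValueError("range mask and temperature raster shapes differ")
    if not mask.any():
        raise ValueError("empty range mask: TTI undefined")
    vals = raster[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("all in-range temperature pixels are missing")
    if statistic == "median":
        return float(np.median(vals))
    if statistic == "mean":
        return float(np.mean(vals))
    if statistic == "p10":
        return float(np.percentile(vals, 10, method="linear"))
    if statistic == "p90":
        return float(np.percentile(vals, 90, method="linear"))
    raise ValueError(f"unknown TTI statistic {statistic!r}")


def compute_tdi(
    trait_table: pd.DataFrame,
    orientations: dict[str, int] | pd.Series,
) -> pd.Series:
    """Raw disturbance-adaptation score in [0, 11] per species.

    Each of the 11 traits is multiplied by its orientation (+1 if larger raw
    values mean more disturbance-adapted, -1 otherwise), min–max scaled to
    [0, 1] across the species pool, and the scaled values are summed. A trait
    that is constant across the pool carries no information and contributes 0
    for every species (with a warning).

    Parameters
    ----------
    trait_table
        One row per species, columns = the 11 traits in :data:`TDI_TRAITS`
        (ordinal traits pre-encoded as numbers). Index = species ids.
    orientations
        Trait name -> +1/-1.
    """
    missing = [t for t in TDI_TRAITS if t not in trait_table.columns]
    if missing:
        raise ValueError(f"trait table missing traits: {missing}")
    if len(trait_table) < 2:
        raise ValueError("TDI requires at least 2 species")
    orientations = dict(orientations)
    unknown = [t for t in TDI_TRAITS if t not in orientations]
    if unknown:
        raise ValueError(f"no orientation declared for traits: {unknown}")

    tdi = pd.Series(0.0, index=trait_table.index)
    for trait in TDI_TRAITS:
        raw = trait_table[trait].astype(float)
        if raw.isna().any():
            raise ValueError(f"missing values in trait {trait!r}")
        oriented = raw * float(orientations[trait])
        span = oriented.max() - oriented.min()
        if span == 0:
            warnings.warn(
                f"trait {trait!r} is constant across species; contributes 0",
                stacklevel=2,
            )
            continue
        tdi += (oriented - oriented.min()) / span
    return tdi


def genus_average(
    species_indices: pd.DataFrame, genus_map: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Average species-level index values up to surveyor-level taxa.

    ``genus_map`` sends every species id to a taxon id (identity for species
    that were not grouped). Averages are unweighted arithmetic means across
    member species, matching the convention that each index is averaged over
    the main species of a genus before standardization.
    """
    genus_map = pd.Series(dict(genus_map))
    missing = species_indices.index.difference(genus_map.index)
    if len(missing):
        raise ValueError(f"species missing from genus map: {list(missing)}")
    taxon_of = genus_map.reindex(species_indices.index)
    out = species_indices.groupby(taxon_of).mean()
    out.index.name = "taxon"
    return out


def standardize_indices(taxon_indices: pd.DataFrame) -> pd.DataFrame:
    """Min–max scale each index column to [0, 1] across the taxon pool."""
    if len(taxon_indices) < 2:
        raise ValueError("standardization requires at least 2 taxa")
    out = {}
    for col in taxon_indices.columns:
        vals = taxon_indices[col].astype(float)
        span = vals.max() - vals.min()
        if span == 0:
            raise ValueError(
                f"index {col!r} constant across taxa: community index undefined"
            )
        out[col] = (vals - vals.min()) / span
    return pd.DataFrame(out, index=taxon_indices.index)


def community_index(
    freq: pd.DataFrame, std_indices: pd.DataFrame
) -> pd.DataFrame:
    """Frequency-weighted mean of each standardized index per cell.

    CI(cell) = sum_t f(cell,t) * index(t) / sum_t f(cell,t), with the
    denominator restricted to taxa that carry the index (all taxa here).
    Cells whose frequencies are all zero are excluded with a warning.

    Parameters
    ----------
    freq
        Tidy table with columns ``cell``, ``taxon``, ``frequency``.
    std_indices
        Standardized taxon index table (index = taxon, columns = indices).

    Returns
    -------
    DataFrame indexed by cell with one column per index.
    """
    unknown = set(freq["taxon"]) - set(std_indices.index)
    if unknown:
        raise ValueError(f"taxa without standardized indices: {sorted(unknown)}")
    wide = freq.pivot_table(
        index="cell", columns="taxon", values="frequency", fill_value=0.0
    )
    total = wide.sum(axis=1)
    dead = total[total <= 0].index
    if len(dead):
        warnings.warn(
            f"excluding {len(dead)} cell(s) with all-zero frequencies",
            stacklevel=2,
        )
        wide = wide.drop(index=dead)
        total = total.drop(index=dead)
    idx = std_indices.reindex(wide.columns)
    ci = wide.to_numpy() @ idx.to_numpy() / total.to_numpy()[:, None]
    return pd.DataFrame(ci, index=wide.index, columns=std_indices.columns)


def delta_indices(
    historical: pd.DataFrame, modern: pd.DataFrame
) -> pd.DataFrame:
    """Change in community indices: modern minus historical, shared cells only."""
    shared = historical.index.intersection(modern.index)
    if len(shared) == 0:
        raise ValueError("no cells present in both periods")
    delta = modern.loc[shared] - historical.loc[shared]
    delta.columns = [f"delta_{c}" for c in delta.columns]
    return delta
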