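"""From raw survey records and inventory plots to per-cell taxon frequencies.

Historical composition comes from early land-survey taxa lists of two
geometric kinds: point observations and short line descriptions. Each
observation receives a weight in meters — the line length for lines, the
mean distance to the previous and next observation for points — and a
taxon's frequency in a grid cell is the cumulative weight of observations
mentioning it divided by the cell's total weight.

Modern composition comes from 400 m^2 inventory plots with per-species basal
areas. Plots farther than 3 km from any historical observation are dropped,
species are grouped to the genus-level taxa historical surveyors recorded,
taxa below 5% of a plot's basal area are removed (so modern lists are
comparable in length to historical ones), and a taxon's frequency in a cell
is the share of plots where it is present.

Observation tables are tidy DataFrames with columns ``obs_id``, ``line_id``,
``seq`` (order along the survey line), ``kind`` (point|line), ``x``, ``y``
(point coordinate or line start, km), ``x2``, ``y2`` (line end; NaN for
points) and ``taxa`` (list of taxon ids). Plot tables are long DataFrames
with ``plot_id``, ``x``, ``y``, ``species``, ``basal_area``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import Grid

__all__ = [
    "assign_weights",
    "reference_points",
    "historical_frequencies",
    "filter_modern_plots",
    "group_genera",
    "apply_basal_area_filter",
    "modern_frequencies",
    "read_observations_csv",
    "write_observations_csv",
]

#: fallback spacing (m) for an isolated point observation with no neighbors
DEFAULT_POINT_SPACING_M = 150.0


def reference_points(observations: pd.DataFrame) -> pd.DataFrame:
    """Representative coordinate per observation: the point, or line midpoint."""
    x = observations["x"].to_numpy(float).copy()
    y = observations["y"].to_numpy(float).copy()
    is_line = observations["kind"].to_numpy() == "line"
    if is_line.any():
        x[is_line] = 0.5 * (x[is_line] + observations.loc[is_line, "x2"].to_numpy(float))
        y[is_line] = 0.5 * (y[is_line] + observations.loc[is_line, "y2"].to_numpy(float))
    return pd.DataFrame({"x": x, "y": y}, index=observations.index)


def assign_weights(
    observations: pd.DataFrame,
    default_spacing_m: float = DEFAULT_POINT_SPACING_M,
) -> pd.DataFrame:
    """Attach a sampling weight (meters) to every observation.

    Line observations weigh their own length. Point observations weigh the
    mean of the distances to the previous and next observation on the same
    survey line (neighbors are taken at their reference point, the midpoint
    for lines); an endpoint with a single neighbor takes that one distance.
    A point alone on its line has no neighbors and falls back to
    ``default_spacing_m``, flagged in the ``weight_fallback`` column.

    Observations must be ordered by ``seq`` within each ``line_id``; a
    duplicated or decreasing ``seq`` raises.
    """
    obs = observations.copy()
    refs = reference_points(obs)
    weights = np.empty(len(obs))
    fallback = np.zeros(len(obs), dtype=bool)
    pos_of = {idx: i for i, idx in enumerate(obs.index)}

    for _, group in obs.groupby("line_id", sort=False):
        seq = group["seq"].to_numpy()
        if np.any(np.diff(seq) <= 0):
            raise ValueError(
                f"survey line {group['line_id'].iloc[0]!r}: sequence indices "
                "must be strictly increasing"
            )
        g = group.sort_values("seq")
        rx = refs.loc[g.index, "x"].to_numpy()
        ry = refs.loc[g.index, "y"].to_numpy()
        # gaps between consecutive reference points, in meters
        gap = np.hypot(np.diff(rx), np.diff(ry)) * 1000.0
        for j, idx in enumerate(g.index):
            i = pos_of[idx]
            if g["kind"].iloc[j] == "line":
                length = (
                    np.hypot(
                        g["x2"].iloc[j] - g["x"].iloc[j],
                        g["y2"].iloc[j] - g["y"].iloc[j],
                    )
                    * 1000.0
                )
                if length <= 0:
                    raise ValueError(f"line observation {idx} has zero length")
                weights[i] = length
            elif len(g) == 1:
                weights[i] = default_spacing_m
                fallback[i] = True
            elif j == 0:
                weights[i] = gap[0]
            elif j == len(g) - 1:
                weights[i] = gap[-1]
            else:
                weights[i] = 0.5 * (gap[j - 1] + gap[j])
    obs["weight"] = weights
    obs["weight_fallback"] = fallback
    return obs


def _frequencies_from_mentions(
    cell: np.ndarray,
    weight: np.ndarray,
    taxa_lists: list[list[str]],
    taxa: list[str] | None,
    period: str,
) -> pd.DataFrame:
    if taxa is None:
        taxa = sorted({t for lst in taxa_lists for t in lst})
    effort = pd.Series(weight).groupby(cell).sum()
    effort = effort[effort.index >= 0]
    if effort.empty:
        raise ValueError("no observations fall inside the grid")
    mentioned = pd.DataFrame(
        [[t in lst for t in taxa] for lst in taxa_lists],
        columns=taxa,
        dtype=float,
    )
    mentioned = mentioned.mul(weight, axis=0)
    mentioned["cell"] = cell
    num = mentioned[mentioned["cell"] >= 0].groupby("cell").sum()
    freq = num.div(effort, axis=0)
    out = freq.reset_index().melt(
        id_vars="cell", var_name="taxon", value_name="frequency"
    )
    out["period"] = period
    out = out.merge(effort.rename("effort"), left_on="cell", right_index=True)
    return out[["period", "cell", "taxon", "frequency", "effort"]].sort_values(
        ["cell", "taxon"], ignore_index=True
    )


def historical_frequencies(
    weighted_observations: pd.DataFrame,
    grid: Grid,
    taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Weighted per-cell taxon frequencies from historical observations.

    frequency(cell, taxon) = sum of weights of the cell's observations that
    mention the taxon / total weight of the cell's observations. Points are
    assigned to their containing cell, lines to the cell of their midpoint.
    Cells without observations do not appear in the table.
    """
    if "weight" not in weighted_observations.columns:
        raise ValueError("observations must be weighted first (assign_weights)")
    refs = reference_points(weighted_observations)
    cell = grid.cell_id(refs["x"], refs["y"])
    taxa_lists = [list(t) for t in weighted_observations["taxa"]]
    if any(len(t) == 0 for t in taxa_lists):
        raise ValueError("observation with empty taxa list")
    return _frequencies_from_mentions(
        cell,
        weighted_observations["weight"].to_numpy(float),
        taxa_lists,
        taxa,
        period="historical",
    )


def filter_modern_plots(
    plots: pd.DataFrame,
    observations: pd.DataFrame,
    max_dist_km: float = 3.0,
) -> pd.DataFrame:
    """Keep plots within ``max_dist_km`` (inclusive) of a historical observation."""
    coords = plots[["plot_id", "x", "y"]].drop_duplicates("plot_id")
    refs = reference_points(observations)
    tree = cKDTree(np.column_stack([refs["x"], refs["y"]]))
    dist, _ = tree.query(np.column_stack([coords["x"], coords["y"]]))
    keep_ids = set(coords.loc[dist <= max_dist_km, "plot_id"])
    if not keep_ids:
        qs = np.percentile(dist, [0, 25, 50, 75, 100])
        raise ValueError(
            "no plot within "
            f"{max_dist_km} km of an observation; nearest-distance quartiles "
            f"(km): {np.round(qs, 2).tolist()}"
        )
    return plots[plots["plot_id"].isin(keep_ids)].reset_index(drop=True)


def group_genera(
    plots: pd.DataFrame, genus_map: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Sum basal areas of congeneric species into surveyor-level taxa."""
    genus_map = dict(genus_map)
    missing = set(plots["species"]) - set(genus_map)
    if missing:
        raise ValueError(f"species missing from genus map: {sorted(missing)}")
    out = plots.copy()
    out["taxon"] = out["species"].map(genus_map)
    keys = [c for c in ("plot_id", "x", "y") if c in out.columns]
    out = (
        out.groupby(keys + ["taxon"], as_index=False)["basal_area"].sum()
    )
    return out


def apply_basal_area_filter(
    plots: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Drop taxa below ``threshold`` of their plot's total basal area.

    The cut is strict (< 5% removed, exactly 5% kept), applied per plot after
    genus grouping. Used to harmonize modern taxa-list lengths with the
    historical surveyors' habit of listing only the most abundant taxa.
    """
    total = plots.groupby("plot_id")["basal_area"].transform("sum")
    if (total <= 0).any():
        raise ValueError("plot with non-positive total basal area")
    share = plots["basal_area"] / total
    return plots[share >= threshold].reset_index(drop=True)


def modern_frequencies(
    plots: pd.DataFrame,
    grid: Grid,
    taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell taxon frequencies from filtered plots: share of plots present.

    frequency(cell, taxon) = number of the cell's plots where the taxon is
    present / number of plots in the cell. Cells without plots are excluded.
    """
    coords = plots[["plot_id", "x", "y"]].drop_duplicates("plot_id")
    cell_of = pd.Series(
        grid.cell_id(coords["x"], coords["y"]), index=coords["plot_id"]
    )
    present = plots[plots["basal_area"] > 0]
    taxa_lists = (
        present.groupby("plot_id")["taxon"].agg(list).reindex(coords["plot_id"])
    )
    taxa_lists = [lst if isinstance(lst, list) else [] for lst in taxa_lists]
    out = _frequencies_from_mentions(
        cell_of.to_numpy(),
        np.ones(len(coords)),
        taxa_lists,
        taxa,
        period="modern",
    )
    return out


def write_observations_csv(observations: pd.DataFrame, path) -> None:
    """Write an observation table with taxa lists pipe-joined."""
    out = observations.copy()
    out["taxa"] = ["|".join(t) for t in out["taxa"]]
    out.to_csv(path, index=False)


def read_observations_csv(path) -> pd.DataFrame:
    obs = pd.read_csv(path)
    obs["taxa"] = [str(t).split("|") for t in obs["taxa"]]
    return obs
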