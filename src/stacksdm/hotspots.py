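"""Stacked richness maps, Jenks natural-breaks classification and habitat-change accounting.

Per-species binary suitability maps are stacked cell-wise into richness maps
(the count of species finding suitable habitat in a cell — high counts are
invasion hotspots), classified into categories by Fisher–Jenks natural breaks,
and compared between present and future scenarios as gain / loss / stable
categories with area-weighted net percentage change, by ecological group and
by spatial extent (pan-Arctic vs global).

Areas are spherical cell areas in km²; all category systems partition the
analysis mask exactly, so gain/loss/stable areas always re-sum to the mask
area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, area_layer_km2

# change-map category codes
STABLE_UNSUITABLE = 0
GAIN = 1
LOSS = 2
STABLE_SUITABLE = 3
CHANGE_LABELS = {
    STABLE_UNSUITABLE: "stable_unsuitable",
    GAIN: "gain",
    LOSS: "loss",
    STABLE_SUITABLE: "stable_suitable",
}


@dataclass
class RichnessMap:
    """Cell-wise count of species with suitable habitat."""

    grid: GridSpec
    counts: np.ndarray
    species_list: list[str]
    scenario: str
    group_filter: str = "all"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match grid")
        if self.counts.min() < 0 or self.counts.max() > len(self.species_list):
            raise ValueError("counts outside [0, n_species]")


@dataclass
class ChangeMap:
    """Per-cell gain/loss/stable categorization between two scenarios."""

    grid: GridSpec
    categories: np.ndarray
    subject: str  # species id, group name or "all"
    period: str  # "present->2050" or "present->2100"


@dataclass
class ChangeSummary:
    """Area accounting of habitat change within one spatial extent."""

    extent: str
    gain_km2: float
    loss_km2: float
    stable_suitable_km2: float
    stable_unsuitable_km2: float
    net_pct: float

    @property
    def present_km2(self) -> float:
        return self.stable_suitable_km2 + self.loss_km2

    @property
    def future_km2(self) -> float:
        return self.stable_suitable_km2 + self.gain_km2


def stack_richness(
    binaries: Mapping[str, np.ndarray],
    groups: Mapping[str, str],
    grid: GridSpec,
    scenario: str,
    group_filter: str = "all",
) -> RichnessMap:
    """Cell-wise sum of binary maps over the (group-filtered) species set."""
    species = sorted(
        sp for sp in binaries
        if group_filter == "all" or groups.get(sp) == group_filter
    )
    counts = np.zeros(grid.shape, dtype=int)
    for sp in species:
        b = np.asarray(binaries[sp])
        if b.shape != grid.shape:
            raise ValueError(f"binary map for {sp} does not match grid")
        counts += b.astype(int)
    return RichnessMap(grid, counts, species, scenario, group_filter)


# ---------------------------------------------------------------------------
# Fisher–Jenks natural breaks
# ---------------------------------------------------------------------------


def _weighted_jenks(values: np.ndarray, weights: np.ndarray, k: int) -> np.ndarray:
    """Exact Fisher–Jenks DP on distinct sorted values with weights.

    Minimizes total within-class weighted sum of squared deviations; returns
    the index (into ``values``) of the last member of each of the first k−1
    classes.
    """
    m = len(values)
    W = np.concatenate([[0.0], np.cumsum(weights)])
    WV = np.concatenate([[0.0], np.cumsum(weights * values)])
    WVV = np.concatenate([[0.0], np.cumsum(weights * values**2)])

    def cost(i: int, j: int) -> float:  # inclusive segment [i, j]
        w = W[j + 1] - W[i]
        wv = WV[j + 1] - WV[i]
        wvv = WVV[j + 1] - WVV[i]
        return wvv - wv * wv / w

    dp = np.full((k + 1, m), np.inf)
    back = np.zeros((k + 1, m), dtype=int)
    for j in range(m):
        dp[1, j] = cost(0, j)
    for c in range(2, k + 1):
        for j in range(c - 1, m):
            for i in range(c - 1, j + 1):
                cand = dp[c - 1, i - 1] + cost(i, j)
                if cand < dp[c, j] - 1e-12:
                    dp[c, j] = cand
                    back[c, j] = i
    # trace back class boundaries
    bounds = []
    j = m - 1
    for c in range(k, 1, -1):
        i = back[c, j]
        bounds.append(i - 1)  # last index of previous class
        j = i - 1
    return np.array(sorted(bounds), dtype=int)


def jenks_breaks(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Natural-breaks class boundaries: k−1 break values (class maxima).

    Classes minimize the total within-class sum of squared deviations (exact
    dynamic program, equivalent to exhaustive partition search).  If fewer than
    ``k`` distinct values exist, k is reduced with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("no finite values to classify")
    distinct, counts = np.unique(values, return_counts=True)
    if len(distinct) < k:
        warnings.warn(
            f"only {len(distinct)} distinct values; reducing k from {k}",
            stacklevel=2,
        )
        k = len(distinct)
        if k < 2:
            return np.empty(0)
    bounds = _weighted_jenks(distinct, counts.astype(float), k)
    return distinct[bounds]


def classify(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Class index per value: class c holds values ≤ breaks[c] (last class open)."""
    return np.searchsorted(np.asarray(breaks, dtype=float), np.asarray(values, dtype=float),
                           side="left")


def area_by_category(
    richness: RichnessMap, breaks: np.ndarray, include_zero: bool = False
) -> pd.DataFrame:
    """Total km² of suitable habitat per richness class.

    Zero-richness cells are excluded by default (the categories describe
    suitable habitat only).
    """
    areas = area_layer_km2(richness.grid)
    counts = richness.counts
    sel = counts > 0 if not include_zero else np.ones_like(counts, dtype=bool)
    cls = classify(counts[sel], breaks)
    vals = counts[sel].astype(float)
    rows = []
    n_classes = len(breaks) + 1
    for c in range(n_classes):
        hi = breaks[c] if c < len(breaks) else np.inf
        in_c = cls == c
        rows.append({
            "class": c,
            "max_richness": float(hi) if np.isfinite(hi) else float(vals.max(initial=0)),
            "area_km2": float(areas[sel][in_c].sum()),
            "n_cells": int(in_c.sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Change analysis
# ---------------------------------------------------------------------------


def change_map(
    binary_present: np.ndarray,
    binary_future: np.ndarray,
    grid: GridSpec,
    subject: str = "all",
    period: str = "present->2050",
) -> ChangeMap:
    """Per-cell transition categories: gain (0→1), loss (1→0), stable classes."""
    bp = np.asarray(binary_present).astype(bool)
    bf = np.asarray(binary_future).astype(bool)
    if bp.shape != bf.shape or bp.shape != grid.shape:
        raise ValueError("binary maps are not grid-compatible")
    cats = np.full(grid.shape, STABLE_UNSUITABLE, dtype=np.int8)
    cats[~bp & bf] = GAIN
    cats[bp & ~bf] = LOSS
    cats[bp & bf] = STABLE_SUITABLE
    return ChangeMap(grid, cats, subject, period)


def net_change_pct(
    binary_present: np.ndarray,
    binary_future: np.ndarray,
    extent_mask: np.ndarray,
    grid: GridSpec,
    extent: str = "global",
) -> ChangeSummary:
    """Area-weighted habitat change within an extent mask.

    net_pct = 100 · (A_future − A_present) / A_present, with A_future =
    A_present + gain − loss.  A zero present area is reported as NaN
    (undefined), never as a division error.
    """
    cm = change_map(binary_present, binary_future, grid).categories
    areas = area_layer_km2(grid)
    mask = np.asarray(extent_mask, dtype=bool)
    gain = float(areas[mask & (cm == GAIN)].sum())
    loss = float(areas[mask & (cm == LOSS)].sum())
    ss = float(areas[mask & (cm == STABLE_SUITABLE)].sum())
    su = float(areas[mask & (cm == STABLE_UNSUITABLE)].sum())
    a_present = ss + loss
    if a_present == 0:
        net = float("nan")
    else:
        net = 100.0 * (gain - loss) / a_present
    return ChangeSummary(extent, gain, loss, ss, su, net)


def group_summaries(
    binaries_by_scenario: Mapping[str, Mapping[str, np.ndarray]],
    groups: Mapping[str, str],
    extent_masks: Mapping[str, np.ndarray],
    grid: GridSpec,
    periods: Sequence[str] = ("2050", "2100"),
    aggregation: str = "union",
) -> pd.DataFrame:
    """Net habitat change per (group, extent, period) plus the all-species row.

    ``binaries_by_scenario`` maps scenario → {species → binary map}; species
    missing from a scenario are skipped.  Aggregation over a group's members is
    the *union* of their suitable cells by default (cumulative-risk semantics,
    matching stacked richness); ``aggregation="mean"`` instead averages the
    member species' individual net percentages.  Empty groups are omitted with
    a warning.
    """
    if aggregation not in ("union", "mean"):
        raise ValueError("aggregation must be 'union' or 'mean'")
    present = binaries_by_scenario["present"]
    group_names = sorted(set(groups.values())) + ["all"]
    rows = []
    for gname in group_names:
        members = sorted(
            sp for sp in present if gname == "all" or groups.get(sp) == gname
        )
        if not members:
            warnings.warn(f"no species in group {gname!r}; row omitted", stacklevel=2)
            continue
        for period in periods:
            future = binaries_by_scenario[period]
            for extent, mask in extent_masks.items():
                if aggregation == "union":
                    bp = np.any([present[sp].astype(bool) for sp in members], axis=0)
                    bf = np.any([future[sp].astype(bool) for sp in members], axis=0)
                    s = net_change_pct(bp, bf, mask, grid, extent)
                    rows.append({
                        "group": gname, "extent": extent, "period": f"present->{period}",
                        "gain_km2": s.gain_km2, "loss_km2": s.loss_km2,
                        "stable_km2": s.stable_suitable_km2, "net_pct": s.net_pct,
                        "n_species": len(members),
                    })
                else:
                    per = [
                        net_change_pct(present[sp], future[sp], mask, grid, extent)
                        for sp in members
                    ]
                    rows.append({
                        "group": gname, "extent": extent, "period": f"present->{period}",
                        "gain_km2": float(np.sum([s.gain_km2 for s in per])),
                        "loss_km2": float(np.sum([s.loss_km2 for s in per])),
                        "stable_km2": float(np.sum([s.stable_suitable_km2 for s in per])),
                        "net_pct": float(np.nanmean([s.net_pct for s in per])),
                        "n_species": len(members),
                    })
    return pd.DataFrame(rows)
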