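"""Depth-resolved alpha diversity, layer occupancy and beta-diversity partition.

Richness is counted per metre of depth from 0 to 4000 m: a species is present
at depth d when min_depth <= d <= max_depth.  The water column is partitioned
into five layers — shallow, mesophotic, rariphotic, mesopelagic, bathypelagic —
and pairwise compositional difference between layers is split into its
turnover component (Simpson dissimilarity, insensitive to richness
differences) and the nestedness fraction of the Sorensen dissimilarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import IUCN_GROUPS

logger = logging.getLogger("bathygap")

PROFILE_MAX_DEPTH = 4000


@dataclass(frozen=True)
class DepthLayer:
    """A depth stratum [lower_m, upper_m), closed above when ``closed_upper``."""

    name: str
    lower_m: float
    upper_m: float
    closed_upper: bool = False

    def contains_depth(self, d: float) -> bool:
        if self.closed_upper:
            return self.lower_m <= d <= self.upper_m
        return self.lower_m <= d < self.upper_m

    def intersects_range(self, min_depth: float, max_depth: float) -> bool:
        """Whether the closed species range [min, max] meets this layer."""
        if max_depth < self.lower_m:
            return False
        if self.closed_upper:
            return min_depth <= self.upper_m
        return min_depth < self.upper_m


#: Default layers; intervals are half-open except the deepest, closed at 4000 m
#: so a species reaching exactly 4000 m is still bathypelagic.
DEFAULT_LAYERS: tuple[DepthLayer, ...] = (
    DepthLayer("shallow", 0, 30),
    DepthLayer("mesophotic", 30, 150),
    DepthLayer("rariphotic", 150, 300),
    DepthLayer("mesopelagic", 300, 1000),
    DepthLayer("bathypelagic", 1000, 4000, closed_upper=True),
)

LAYER_NAMES = tuple(l.name for l in DEFAULT_LAYERS)


def validate_layers(layers: Sequence[DepthLayer]) -> None:
    """Layers must tile [0, top] contiguously without overlap."""
    if not layers:
        raise ValueError("no depth layers defined")
    prev_upper = 0.0
    for layer in layers:
        if layer.lower_m != prev_upper:
            raise ValueError(
                f"layer {layer.name!r} starts at {layer.lower_m}, expected {prev_upper}"
            )
        if layer.upper_m <= layer.lower_m:
            raise ValueError(f"layer {layer.name!r} has inverted bounds")
        prev_upper = layer.upper_m
    if not layers[-1].closed_upper:
        raise ValueError("deepest layer must be closed above")


# ---------------------------------------------------------------------------
# Alpha diversity profiles
# ---------------------------------------------------------------------------


def _interval_counts(
    mins: np.ndarray, maxs: np.ndarray, max_depth: int = PROFILE_MAX_DEPTH
) -> np.ndarray:
    """Count, at each integer depth 0..max_depth, ranges containing that depth."""
    grid = np.zeros(max_depth + 2, dtype=np.int64)
    start = np.ceil(mins).astype(int)
    end = np.floor(np.minimum(maxs, max_depth)).astype(int)
    ok = (start <= end) & (start <= max_depth) & (end >= 0)
    start = np.clip(start[ok], 0, max_depth)
    end = end[ok]
    np.add.at(grid, start, 1)
    np.add.at(grid, end + 1, -1)
    return np.cumsum(grid)[: max_depth + 1]


def richness_profile(
    species: pd.DataFrame,
    max_depth: int = PROFILE_MAX_DEPTH,
    stratifier: Optional[str] = None,
) -> pd.DataFrame:
    """Species richness at each metre of depth, optionally stratified.

    *stratifier* may be None, 'taxon_class', 'iucn_group' or any categorical
    column of the species table.  Returns a frame indexed by ``depth_m`` with
    one count column per stratum plus ``total``.
    """
    depths = np.arange(max_depth + 1)
    out = pd.DataFrame({"depth_m": depths})
    mins = species["min_depth_m"].to_numpy(dtype=float) if len(species) else np.empty(0)
    maxs = species["max_depth_m"].to_numpy(dtype=float) if len(species) else np.empty(0)
    out["total"] = _interval_counts(mins, maxs, max_depth)
    if stratifier is not None:
        for value, grp in species.groupby(stratifier, sort=True):
            out[str(value)] = _interval_counts(
                grp["min_depth_m"].to_numpy(dtype=float),
                grp["max_depth_m"].to_numpy(dtype=float),
                max_depth,
            )
    return out


def status_proportion_profile(
    species: pd.DataFrame, max_depth: int = PROFILE_MAX_DEPTH
) -> pd.DataFrame:
    """Per-depth proportions of THR/LC/DD/NE species.

    Proportions sum to 1 wherever at least one species is present; depths
    with no species are NaN.
    """
    prof = richness_profile(species, max_depth, stratifier="iucn_group")
    total = prof["total"].to_numpy().astype(float)
    out = pd.DataFrame({"depth_m": prof["depth_m"], "n_species": prof["total"]})
    with np.errstate(invalid="ignore", divide="ignore"):
        for group in IUCN_GROUPS:
            counts = prof[group].to_numpy() if group in prof else np.zeros_like(total)
            out[group] = np.where(total > 0, counts / np.where(total > 0, total, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# Layer occupancy
# ---------------------------------------------------------------------------


def layer_occupancy(
    species: pd.DataFrame, layers: Sequence[DepthLayer] = DEFAULT_LAYERS
) -> pd.DataFrame:
    """Boolean species x layers presence matrix (interval intersection)."""
    validate_layers(layers)
    data = {
        layer.name: [
            layer.intersects_range(mn, mx)
            for mn, mx in zip(species["min_depth_m"], species["max_depth_m"])
        ]
        for layer in layers
    }
    return pd.DataFrame(data, index=pd.Index(species["species_id"], name="species_id"))


def ascend_layer(
    min_depth: float, layers: Sequence[DepthLayer] = DEFAULT_LAYERS
) -> str:
    """The shallowest layer a species reaches (the layer holding its minimum depth).

    Species ascending to the shallow layer are depth generalists; all others
    are deep-endemic at their ascend layer.
    """
    for layer in layers:
        if layer.contains_depth(min_depth):
            return layer.name
    raise ValueError(f"min depth {min_depth} outside the layered water column")


def ascend_layers(
    species: pd.DataFrame, layers: Sequence[DepthLayer] = DEFAULT_LAYERS
) -> pd.Series:
    return pd.Series(
        [ascend_layer(mn, layers) for mn in species["min_depth_m"]],
        index=species.index,
        name="ascend_layer",
    )


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaComponents:
    """Pairwise beta-diversity partition between two species sets.

    a = shared species, b/c = species unique to each set;
    beta_sim = min(b,c)/(a+min(b,c))      (turnover, Simpson)
    beta_sor = (b+c)/(2a+b+c)             (total, Sorensen)
    beta_sne = beta_sor - beta_sim        (nestedness fraction)
    """

    a: int
    b: int
    c: int
    beta_sim: float
    beta_sne: float
    beta_sor: float


def beta_components(set_a: Iterable, set_b: Iterable) -> BetaComponents:
    """Partition the dissimilarity between two presence sets.

    The degenerate cases (both sets empty, or min(b,c)=a=0) define the
    affected component as 0 rather than NaN.
    """
    sa, sb = set(set_a), set(set_b)
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    m = min(b, c)
    beta_sim = m / (a + m) if (a + m) > 0 else 0.0
    denom = 2 * a + b + c
    beta_sor = (b + c) / denom if denom > 0 else 0.0
    return BetaComponents(a, b, c, beta_sim, beta_sor - beta_sim, beta_sor)


def pairwise_beta(
    occupancy: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Layer x layer turnover and nestedness matrices from an occupancy matrix.

    Both matrices are symmetric with a zero diagonal; neighbouring-layer
    values sit on the first off-diagonal.
    """
    layers = list(occupancy.columns)
    n = len(layers)
    turnover = np.zeros((n, n))
    nestedness = np.zeros((n, n))
    sets = {
        layer: set(occupancy.index[occupancy[layer].to_numpy(dtype=bool)])
        for layer in layers
    }
    for i in range(n):
        for j in range(i + 1, n):
            comp = beta_components(sets[layers[i]], sets[layers[j]])
            turnover[i, j] = turnover[j, i] = comp.beta_sim
            nestedness[i, j] = nestedness[j, i] = comp.beta_sne
    t = pd.DataFrame(turnover, index=layers, columns=layers)
    s = pd.DataFrame(nestedness, index=layers, columns=layers)
    return t, s
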