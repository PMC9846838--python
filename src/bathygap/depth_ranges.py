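"""Species bathymetric range construction.

Each occurrence is resolved to a positive depth through the 1-degree
bathymetric grid (depth = -elevation; land cells are dropped).  Species with
at least ``min_n`` resolved occurrences get a quantile range: the 1% and 99%
quantiles of their depth distribution, trimming extreme and sometimes
unrealistic records.  Habitat-specific rules then turn quantile ranges into
depth-range endpoints, and documented endpoints always take precedence — the
quantile machinery only fills what is missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import BathymetryLookup, OccurrenceRecord

logger = logging.getLogger("bathygap")

DEFAULT_Q_LOW = 0.01
DEFAULT_Q_HIGH = 0.99
DEFAULT_MIN_N = 20


@dataclass(frozen=True)
class QuantileRange:
    """Occurrence-quantile depth range for one species."""

    species_id: str
    n_occurrences: int
    d_low_m: float
    d_high_m: float


# ---------------------------------------------------------------------------
# Depth resolution
# ---------------------------------------------------------------------------


def resolve_depth(occ: OccurrenceRecord, bathy: BathymetryLookup) -> Optional[float]:
    """Positive depth of the cell containing *occ*, or None for land/unknown cells."""
    elev = bathy.elevation_at(occ.lon, occ.lat)
    if elev is None:
        logger.debug("occurrence %s at (%s, %s): cell missing from bathymetry",
                     occ.species_id, occ.lon, occ.lat)
        return None
    if elev >= 0:
        logger.debug("occurrence %s at (%s, %s): land cell (elevation %s)",
                     occ.species_id, occ.lon, occ.lat, elev)
        return None
    return -elev


def resolve_depths(occurrences: pd.DataFrame, bathy: BathymetryLookup) -> pd.DataFrame:
    """Vectorised depth resolution of an occurrence table.

    Returns the occurrences that resolve to ocean cells, with a ``depth_m``
    column; land-cell and unknown-cell records are dropped (counted in logs).
    """
    lon_cell = np.floor(occurrences["lon"].to_numpy()).astype(int)
    lat_cell = np.floor(occurrences["lat"].to_numpy()).astype(int)
    cells = dict(bathy.items())
    elev = np.array(
        [cells.get((lo, la), np.nan) for lo, la in zip(lon_cell, lat_cell)]
    )
    keep = ~np.isnan(elev) & (elev < 0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d occurrences on land or outside the bathymetry grid",
                    n_drop)
    out = occurrences.loc[keep].copy()
    out["depth_m"] = -elev[keep]
    return out


# ---------------------------------------------------------------------------
# Quantile ranges
# ---------------------------------------------------------------------------


def estimate_quantile_range(
    species_id: str,
    depths,
    q_low: float = DEFAULT_Q_LOW,
    q_high: float = DEFAULT_Q_HIGH,
    min_n: int = DEFAULT_MIN_N,
) -> Optional[QuantileRange]:
    """Quantile depth range, or None when fewer than *min_n* occurrences.

    Quantiles are linear-interpolation ('type 7') sample quantiles of the
    positive depths.
    """
    depths = np.asarray(depths, dtype=float)
    if (depths < 0).any():
        raise ValueError("depths must be non-negative")
    n = depths.size
    if n < min_n:
        return None
    lo, hi = np.quantile(depths, [q_low, q_high], method="linear")
    return QuantileRange(species_id, n, float(lo), float(hi))


# ---------------------------------------------------------------------------
# Habitat imputation rules
# ---------------------------------------------------------------------------

# Habitat rules: whether the surface (0 m) replaces the quantile minimum, and
# floor/ceiling constraints clamped onto the imputed endpoints.
_SURFACE_MIN_HABITATS = frozenset({"pelagic-oceanic", "benthopelagic"})
_MIN_FLOORS = {"bathydemersal": 200.0, "bathypelagic": 1000.0}
_MAX_CEILINGS = {"reef-associated": 200.0, "pelagic-neritic": 200.0}
_RULE_HABITATS = (
    frozenset({"demersal", "bathydemersal", "reef-associated", "pelagic-neritic",
               "bathypelagic"})
    | _SURFACE_MIN_HABITATS
)


def impute_range(habitat: str, qr: QuantileRange) -> Optional[tuple[float, float]]:
    """Depth range implied by a quantile range under the habitat's rule.

    Demersal-type habitats take (d_low, d_high); open-water habitats
    (pelagic-oceanic, benthopelagic) span from the surface to d_high.
    Constraints are then clamped on: bathydemersal min >= 200 m, bathypelagic
    min >= 1000 m, reef-associated and pelagic-neritic max <= 200 m.  If
    clamping inverts the interval, or the habitat has no rule, the species is
    unresolved (None), logged.
    """
    if habitat not in _RULE_HABITATS:
        logger.info("species %s: no imputation rule for habitat %r",
                    qr.species_id, habitat)
        return None
    mn = 0.0 if habitat in _SURFACE_MIN_HABITATS else qr.d_low_m
    mx = qr.d_high_m
    if habitat in _MIN_FLOORS:
        mn = max(mn, _MIN_FLOORS[habitat])
    if habitat in _MAX_CEILINGS:
        mx = min(mx, _MAX_CEILINGS[habitat])
    if mn > mx:
        logger.info("species %s: habitat constraint inverted range (%s > %s)",
                    qr.species_id, mn, mx)
        return None
    return (mn, mx)


# ---------------------------------------------------------------------------
# Full table
# ---------------------------------------------------------------------------


def build_depth_table(
    species: pd.DataFrame,
    occurrences: pd.DataFrame,
    bathy: BathymetryLookup,
    q_low: float = DEFAULT_Q_LOW,
    q_high: float = DEFAULT_Q_HIGH,
    min_n: int = DEFAULT_MIN_N,
    iucn: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Resolve every species' depth range.

    * both endpoints documented -> kept verbatim (``depth_source=documented``);
    * one or both endpoints missing -> the quantile+imputation estimate fills
      only the missing endpoint(s) (``mixed`` when one documented endpoint is
      retained, ``imputed`` when both are filled);
    * otherwise ``unresolved`` — such species are excluded downstream.

    Species absent from the IUCN table default to NE (not evaluated).
    """
    resolved = resolve_depths(occurrences, bathy)
    depths_by_sp = {
        sp: grp["depth_m"].to_numpy() for sp, grp in resolved.groupby("species_id")
    }

    iucn_map: dict[str, str] = {}
    if iucn is not None:
        iucn_map = dict(zip(iucn["species_id"], iucn["iucn_raw"]))

    rows = []
    n_unresolved = 0
    for rec in species.itertuples(index=False):
        doc_min = None if pd.isna(rec.min_depth_m) else float(rec.min_depth_m)
        doc_max = None if pd.isna(rec.max_depth_m) else float(rec.max_depth_m)
        mn, mx, source = doc_min, doc_max, "documented"
        if doc_min is None or doc_max is None:
            qr = estimate_quantile_range(
                rec.species_id,
                depths_by_sp.get(rec.species_id, np.empty(0)),
                q_low, q_high, min_n,
            )
            imputed = impute_range(rec.habitat, qr) if qr is not None else None
            if imputed is None:
                mn, mx, source = None, None, "unresolved"
            else:
                mn = doc_min if doc_min is not None else imputed[0]
                mx = doc_max if doc_max is not None else imputed[1]
                source = "imputed" if (doc_min is None and doc_max is None) else "mixed"
        if source != "unresolved" and mn > mx:
            mn, mx, source = None, None, "unresolved"
        if source == "unresolved":
            n_unresolved += 1
        raw = iucn_map.get(rec.species_id, "NE")
        rows.append(
            (rec.species_id, rec.taxon_class, rec.habitat, raw, mn, mx, source)
        )
    if n_unresolved:
        logger.info("depth table: %d of %d species unresolved",
                    n_unresolved, len(species))

    from .io_formats import iucn_group_of

    df = pd.DataFrame(
        rows,
        columns=["species_id", "taxon_class", "habitat", "iucn_raw",
                 "min_depth_m", "max_depth_m", "depth_source"],
    )
    df["iucn_group"] = df["iucn_raw"].map(iucn_group_of)
    return df[["species_id", "taxon_class", "habitat", "iucn_raw", "iucn_group",
               "min_depth_m", "max_depth_m", "depth_source"]]


def retained(depth_table: pd.DataFrame) -> pd.DataFrame:
    """Species with a resolved range (the downstream analysis population)."""
    return depth_table[depth_table["depth_source"] != "unresolved"].reset_index(drop=True)
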