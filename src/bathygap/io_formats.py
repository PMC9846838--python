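"""Typed readers and writers for every external artifact the pipeline touches.

All tabular inputs are plain comma-separated UTF-8 files with a mandatory
header row; reference sequences are FASTA with a ``>seq_id|species=Genus_species``
header dialect.  Every reader validates against an explicit schema and fails
hard (with the offending row or line) rather than silently coercing, so the
downstream modules only ever see well-typed records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("bathygap")

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

TAXON_CLASSES = ("Actinopterygii", "Chondrichthyes")

HABITATS = (
    "demersal",
    "bathydemersal",
    "reef-associated",
    "bathypelagic",
    "pelagic-oceanic",
    "benthopelagic",
    "pelagic-neritic",
    "other",
)

IUCN_RAW = ("LC", "NT", "VU", "EN", "CR", "DD", "NE")
IUCN_GROUPS = ("THR", "LC", "DD", "NE")

#: Red-list categories pooled into the threatened / near-threatened group.
_THR_RAW = frozenset({"NT", "VU", "EN", "CR"})

REGIONS = (
    "Atlantic",
    "Indian",
    "Pacific",
    "Polar",
    "Mediterranean-Black",
    "SE-Asia",
)

MARKERS = ("teleo", "MiFish-U", "MiFish-E")

DEPTH_SOURCES = ("documented", "imputed", "mixed", "unresolved")


def iucn_group_of(raw: str) -> str:
    """Collapse a raw red-list category into the four reported groups.

    NT, VU, EN and CR are pooled as THR; LC, DD and NE pass through.
    """
    if raw in _THR_RAW:
        return "THR"
    if raw in ("LC", "DD", "NE"):
        return raw
    raise ValueError(f"unknown IUCN category: {raw!r}")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


class FormatError(ValueError):
    """Raised when an input file violates its declared format or schema."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' resolved depth range plus its class/habitat/status labels."""

    species_id: str
    taxon_class: str
    habitat: str
    iucn_raw: str
    min_depth_m: Optional[float]
    max_depth_m: Optional[float]
    depth_source: str

    @property
    def iucn_group(self) -> str:
        return iucn_group_of(self.iucn_raw)

    def __post_init__(self) -> None:
        if self.taxon_class not in TAXON_CLASSES:
            raise ValueError(f"bad taxon_class {self.taxon_class!r}")
        if self.habitat not in HABITATS:
            raise ValueError(f"bad habitat {self.habitat!r}")
        if self.iucn_raw not in IUCN_RAW:
            raise ValueError(f"bad IUCN category {self.iucn_raw!r}")
        if self.depth_source not in DEPTH_SOURCES:
            raise ValueError(f"bad depth_source {self.depth_source!r}")
        if self.depth_source != "unresolved":
            if self.min_depth_m is None or self.max_depth_m is None:
                raise ValueError("resolved record lacks a depth endpoint")
            if self.min_depth_m < 0 or self.min_depth_m > self.max_depth_m:
                raise ValueError(
                    f"invalid depth range ({self.min_depth_m}, {self.max_depth_m})"
                )


@dataclass(frozen=True)
class OccurrenceRecord:
    """A georeferenced observation, optionally resolved to a positive depth."""

    species_id: str
    lon: float
    lat: float
    depth_m: Optional[float] = None

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon < 180.0):
            raise ValueError(f"lon {self.lon} outside [-180, 180)")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat {self.lat} outside [-90, 90]")
        if self.depth_m is not None and self.depth_m < 0:
            raise ValueError("depth_m must be non-negative when present")


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference barcode sequence tagged with the species it came from."""

    seq_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.seq_id!r}")
        bad = set(self.sequence) - set("ACGTRYSWKMBDHVN")
        if bad:
            raise ValueError(
                f"sequence {self.seq_id!r} contains non-IUPAC symbols {sorted(bad)}"
            )


class BathymetryLookup:
    """Elevation of each 1-degree grid cell, keyed by (floor(lon), floor(lat)).

    Elevations are negative below sea level (etopo-style); an occurrence at
    (lon, lat) resolves through the single cell containing it.
    """

    def __init__(self, cells: Mapping[tuple[int, int], float]):
        self._cells = dict(cells)

    def __len__(self) -> int:
        return len(self._cells)

    @staticmethod
    def cell_of(lon: float, lat: float) -> tuple[int, int]:
        return (math.floor(lon), math.floor(lat))

    def elevation_at(self, lon: float, lat: float) -> Optional[float]:
        """Elevation of the containing cell, or None when the cell is unknown."""
        return self._cells.get(self.cell_of(lon, lat))

    def items(self):
        return self._cells.items()

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self._cells.items())
        return pd.DataFrame(
            {
                "lon_cell": [k[0] for k, _ in rows],
                "lat_cell": [k[1] for k, _ in rows],
                "elevation_m": [v for _, v in rows],
            }
        )


@dataclass
class RegionChecklist:
    """Species membership in the study's fixed set of oceans and seas."""

    membership: dict[str, set[str]] = field(default_factory=dict)

    def regions_of(self, species_id: str) -> set[str]:
        return self.membership.get(species_id, set())

    def add(self, species_id: str, region: str) -> None:
        if region not in REGIONS:
            raise FormatError(f"unknown region {region!r}")
        self.membership.setdefault(species_id, set()).add(region)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_SPECIES_TAG = "species="


def _parse_fasta_header(description: str) -> tuple[str, str]:
    head, sep, rest = description.partition("|")
    if not sep or not rest.startswith(_SPECIES_TAG) or not rest[len(_SPECIES_TAG):]:
        raise FormatError(
            f"malformed FASTA header {'>' + description!r}: expected "
            "'>seq_id|species=Genus_species'"
        )
    return head.strip(), rest[len(_SPECIES_TAG):].strip()


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read reference sequences, normalising case and mapping U to T.

    Headers must follow the ``>seq_id|species=Genus_species`` dialect; a
    malformed header or an empty sequence is a hard error naming the line.
    """
    path = Path(path)
    records: list[ReferenceSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq_id, species_id = _parse_fasta_header(rec.description)
            seq = str(rec.seq).upper().replace("U", "T")
            records.append(ReferenceSequence(seq_id, species_id, seq))
        except (FormatError, ValueError) as exc:
            raise FormatError(
                f"{path}:{_header_line(path, rec.description)}: {exc}"
            ) from exc
    return records


def _header_line(path: Path, description: str) -> int:
    """Line number of the FASTA header matching *description* (for errors)."""
    target = ">" + description
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.rstrip("\n") == target:
                return i
    return 0


def write_fasta(records: Iterable[ReferenceSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}|species={rec.species_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str  # 'str' | 'float' | 'int'
    enum: Optional[tuple[str, ...]] = None
    nullable: bool = False


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[ColumnSpec, ...]


SPECIES_SCHEMA = TableSchema(
    "species",
    (
        ColumnSpec("species_id", "str"),
        ColumnSpec("taxon_class", "str", enum=TAXON_CLASSES),
        ColumnSpec("habitat", "str", enum=HABITATS),
        ColumnSpec("min_depth_m", "float", nullable=True),
        ColumnSpec("max_depth_m", "float", nullable=True),
    ),
)

IUCN_SCHEMA = TableSchema(
    "iucn",
    (
        ColumnSpec("species_id", "str"),
        ColumnSpec("iucn_raw", "str", enum=IUCN_RAW),
    ),
)

OCCURRENCE_SCHEMA = TableSchema(
    "occurrences",
    (
        ColumnSpec("species_id", "str"),
        ColumnSpec("lon", "float"),
        ColumnSpec("lat", "float"),
    ),
)

BATHYMETRY_SCHEMA = TableSchema(
    "bathymetry",
    (
        ColumnSpec("lon_cell", "int"),
        ColumnSpec("lat_cell", "int"),
        ColumnSpec("elevation_m", "float"),
    ),
)

CHECKLIST_SCHEMA = TableSchema(
    "checklist",
    (
        ColumnSpec("species_id", "str"),
        ColumnSpec("region", "str", enum=REGIONS),
    ),
)

CUSTOM_DB_SCHEMA = TableSchema(
    "custom_db",
    (
        ColumnSpec("species_id", "str"),
        ColumnSpec("marker", "str", enum=MARKERS),
    ),
)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against *schema*.

    Enum violations and unparseable numerics raise :class:`FormatError`
    naming the 1-based data row; extra columns are rejected so silently
    mis-labelled files cannot slip through.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc

    expected = [c.name for c in schema.columns]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )

    out = {}
    for col in schema.columns:
        raw = df[col.name]
        if col.dtype == "str":
            vals = raw.str.strip()
            if not col.nullable and (vals == "").any():
                row = int((vals == "").idxmax()) + 1
                raise FormatError(f"{path}: empty {col.name!r} at data row {row}")
            if col.enum is not None:
                bad = ~vals.isin(col.enum) & (vals != "")
                if bad.any():
                    row = int(bad.idxmax()) + 1
                    raise FormatError(
                        f"{path}: invalid {col.name!r} value {vals[bad.idxmax()]!r} "
                        f"at data row {row}"
                    )
            out[col.name] = vals
        else:
            blank = raw.str.strip() == ""
            if blank.any() and not col.nullable:
                row = int(blank.idxmax()) + 1
                raise FormatError(f"{path}: missing {col.name!r} at data row {row}")
            numeric = pd.to_numeric(raw.where(~blank, None), errors="coerce")
            bad = numeric.isna() & ~blank
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise FormatError(
                    f"{path}: non-numeric {col.name!r} value {raw[bad.idxmax()]!r} "
                    f"at data row {row}"
                )
            out[col.name] = numeric.astype("Int64") if col.dtype == "int" else numeric
    return pd.DataFrame(out)


def read_species_table(path: str | Path) -> pd.DataFrame:
    """Documented depth-range table (endpoints may be blank = undocumented)."""
    df = read_table(path, SPECIES_SCHEMA)
    both = df["min_depth_m"].notna() & df["max_depth_m"].notna()
    inverted = both & (df["min_depth_m"] > df["max_depth_m"])
    if inverted.any():
        row = int(inverted.idxmax()) + 1
        raise FormatError(f"{path}: min_depth_m > max_depth_m at data row {row}")
    neg = (df["min_depth_m"] < 0) | (df["max_depth_m"] < 0)
    if neg.fillna(False).any():
        row = int(neg.fillna(False).idxmax()) + 1
        raise FormatError(f"{path}: negative depth at data row {row}")
    if df["species_id"].duplicated().any():
        dup = df["species_id"][df["species_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate species_id {dup!r}")
    return df


def read_iucn_table(path: str | Path) -> pd.DataFrame:
    """IUCN status table; adds the pooled ``iucn_group`` column."""
    df = read_table(path, IUCN_SCHEMA)
    df["iucn_group"] = df["iucn_raw"].map(iucn_group_of)
    return df


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = read_table(path, OCCURRENCE_SCHEMA)
    bad = ~((df["lon"] >= -180) & (df["lon"] < 180) & (df["lat"].abs() <= 90))
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise FormatError(f"{path}: coordinates out of range at data row {row}")
    return df


def read_bathymetry(path: str | Path) -> BathymetryLookup:
    df = read_table(path, BATHYMETRY_SCHEMA)
    cells = {
        (int(lon), int(lat)): float(elev)
        for lon, lat, elev in zip(df["lon_cell"], df["lat_cell"], df["elevation_m"])
    }
    if len(cells) != len(df):
        raise FormatError(f"{path}: duplicate bathymetry cells")
    return BathymetryLookup(cells)


def read_checklists(path: str | Path) -> RegionChecklist:
    df = read_table(path, CHECKLIST_SCHEMA)
    cl = RegionChecklist()
    for sp, region in zip(df["species_id"], df["region"]):
        cl.add(sp, region)
    return cl


def read_custom_db(path: str | Path) -> set[tuple[str, str]]:
    """Species supplemented from a published custom database, per marker."""
    df = read_table(path, CUSTOM_DB_SCHEMA)
    return set(zip(df["species_id"], df["marker"]))


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Read back a depth table written by the build-depths stage."""
    df = pd.read_csv(path, dtype={"species_id": str})
    expected = ["species_id", "taxon_class", "habitat", "iucn_raw", "iucn_group",
                "min_depth_m", "max_depth_m", "depth_source"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected depth-table columns {expected}")
    bad = ~df["depth_source"].isin(DEPTH_SOURCES)
    if bad.any():
        raise FormatError(f"{path}: invalid depth_source at data row {int(bad.idxmax()) + 1}")
    return df


def read_amplification_table(path: str | Path) -> pd.DataFrame:
    """Read back a species_amplification.csv written by the pcr stage."""
    df = pd.read_csv(path, dtype={"species_id": str, "marker": str})
    expected = ["species_id", "marker", "amplified", "source",
                "cons_fwd_mismatches", "cons_rev_mismatches"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected amplification columns {expected}")
    df["amplified"] = df["amplified"].astype(bool)
    df["source"] = df["source"].fillna("")
    return df


def write_checklists(checklist: RegionChecklist, path: str | Path) -> None:
    rows = sorted(
        (sp, region)
        for sp, regions in checklist.membership.items()
        for region in regions
    )
    pd.DataFrame(rows, columns=["species_id", "region"]).to_csv(path, index=False)
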