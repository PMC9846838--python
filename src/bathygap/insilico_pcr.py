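"""Mismatch-tolerant in silico PCR on reference sequences.

Primer binding sites are located by IUPAC-aware Hamming matching on both
strands (a window position matches when the template base's nucleotide set
intersects the primer code's set, so N on either side matches everything).
A forward site and a downstream reverse-complemented reverse site whose
intervening insert falls within the marker's length bounds constitute a hit.
Only substitutions are counted; indels at the priming sites are not modelled.

Coordinates are 0-based half-open on the + strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import MARKERS, ReferenceSequence

# ---------------------------------------------------------------------------
# IUPAC machinery
# ---------------------------------------------------------------------------

#: bitmask per IUPAC code: A=1, C=2, G=4, T=8; degenerate codes OR their bases.
IUPAC_BITS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8, "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: concrete bases contained in each IUPAC code (used by the generator).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(b for b in "ACGT" if IUPAC_BITS[code] & IUPAC_BITS[b])
    for code in IUPAC_BITS
}

_ENCODE_TABLE = np.zeros(128, dtype=np.uint8)
for _code, _bits in IUPAC_BITS.items():
    _ENCODE_TABLE[ord(_code)] = _bits


def encode(seq: str) -> np.ndarray:
    """Encode an IUPAC string as a uint8 bitmask array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bits = _ENCODE_TABLE[arr]
    if (bits == 0).any():
        bad = seq[int(np.argmax(bits == 0))]
        raise ValueError(f"non-IUPAC symbol {bad!r} in sequence")
    return bits


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    try:
        return "".join(IUPAC_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC symbol {exc} in sequence") from exc


def count_mismatches(primer: str, window: str) -> int:
    """Hamming mismatches between a primer and an equal-length window.

    A position matches when the IUPAC sets intersect.
    """
    if len(primer) != len(window):
        raise ValueError(
            f"length mismatch: primer {len(primer)} vs window {len(window)}"
        )
    p = encode(primer)
    w = encode(window)
    return int(np.count_nonzero((p & w) == 0))


def find_primer_sites(
    seq: str, primer: str, max_mismatch: int
) -> list[tuple[int, int]]:
    """All windows of *seq* matching *primer* with <= max_mismatch mismatches.

    Returns (start, mismatches) pairs in ascending start order; semantics are
    those of a naive scan over every window.
    """
    if len(seq) < len(primer):
        return []
    s = encode(seq)
    p = encode(primer)
    windows = np.lib.stride_tricks.sliding_window_view(s, len(primer))
    mism = np.count_nonzero((windows & p) == 0, axis=1)
    starts = np.flatnonzero(mism <= max_mismatch)
    return [(int(i), int(mism[i])) for i in starts]


# ---------------------------------------------------------------------------
# Primer pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimerPair:
    """A metabarcoding marker: primer strings, mismatch cap, insert bounds.

    ``max_mismatch`` applies to each primer independently (a per-primer cap,
    not a summed budget); insert bounds apply to the region between the two
    priming sites, excluding both sites.
    """

    marker: str
    forward: str
    reverse: str
    max_mismatch: int = 3
    insert_min_bp: int = 0
    insert_max_bp: int = 10_000

    def __post_init__(self) -> None:
        for name, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if len(primer) < 10:
                raise ValueError(f"{name} primer shorter than 10 nt")
            encode(primer)  # alphabet check
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.insert_min_bp > self.insert_max_bp:
            raise ValueError("insert_min_bp > insert_max_bp")


#: The three 12S markers, with insert bounds bracketing the ~60 bp (teleo)
#: and ~170 bp (MiFish) barcode lengths.
DEFAULT_PRIMERS: dict[str, PrimerPair] = {
    "teleo": PrimerPair(
        "teleo",
        forward="ACACCGCCCGTCACTCT",
        reverse="CTTCCGGTACACTTACCATG",
        insert_min_bp=30,
        insert_max_bp=120,
    ),
    "MiFish-U": PrimerPair(
        "MiFish-U",
        forward="GTCGGTAAAACTCGTGCCAGC",
        reverse="CATAGTGGGGTATCTAATCCCAGTTTG",
        insert_min_bp=120,
        insert_max_bp=220,
    ),
    "MiFish-E": PrimerPair(
        "MiFish-E",
        forward="GTTGGTAAATCTCGTGCCAGC",
        reverse="CATAGTGGGGTATCTAATCCTAGTTTG",
        insert_min_bp=120,
        insert_max_bp=220,
    ),
}

#: Markers reported jointly (MiFish-U/E target the same locus).
MARKER_FAMILIES: dict[str, str] = {
    "teleo": "teleo",
    "MiFish-U": "MiFish",
    "MiFish-E": "MiFish",
}


# ---------------------------------------------------------------------------
# Amplicon search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmpliconHit:
    """One simulated amplification event, normalised to + strand coordinates.

    ``insert_sequence`` is reported in amplicon orientation (5'->3' from the
    forward primer), so a hit and its reverse-complement twin agree.
    """

    seq_id: str
    species_id: str
    marker: str
    strand: str  # '+' or '-'
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    fwd_mismatches: int
    rev_mismatches: int
    insert_sequence: str

    @property
    def insert_length_bp(self) -> int:
        return len(self.insert_sequence)


def _pair_sites(
    seq: str,
    fwd_sites: Sequence[tuple[int, int]],
    rev_sites: Sequence[tuple[int, int]],
    fwd_len: int,
    rev_len: int,
    pair: PrimerPair,
) -> list[tuple[int, int, int, int, str]]:
    """Pair forward sites with downstream reverse-complement sites.

    Returns (fwd_start, fwd_mm, rev_start, rev_mm, insert) tuples in the local
    coordinates of *seq*.
    """
    out = []
    for fs, fmm in fwd_sites:
        f_end = fs + fwd_len
        for rs, rmm in rev_sites:
            if rs < f_end:
                continue
            insert = seq[f_end:rs]
            if pair.insert_min_bp <= len(insert) <= pair.insert_max_bp:
                out.append((fs, fmm, rs, rmm, insert))
    return out


def run_insilico_pcr(record: ReferenceSequence, pair: PrimerPair) -> list[AmpliconHit]:
    """Locate every amplicon of *pair* on *record*, searching both strands.

    Hits found on the - strand are mapped back to + strand coordinates and
    deduplicated against + strand hits by (fwd_start, rev_start, strand).
    Zero hits is a valid outcome.
    """
    seq = record.sequence
    L = len(seq)
    fwd_len, rev_len = len(pair.forward), len(pair.reverse)
    rc_rev = reverse_complement(pair.reverse)

    hits: list[AmpliconHit] = []
    seen: set[tuple[int, int, str]] = set()

    # + strand: forward primer then reverse-complemented reverse primer.
    plus = _pair_sites(
        seq,
        find_primer_sites(seq, pair.forward, pair.max_mismatch),
        find_primer_sites(seq, rc_rev, pair.max_mismatch),
        fwd_len,
        rev_len,
        pair,
    )
    for fs, fmm, rs, rmm, insert in plus:
        key = (fs, rs, "+")
        if key not in seen:
            seen.add(key)
            hits.append(
                AmpliconHit(
                    record.seq_id, record.species_id, pair.marker, "+",
                    fs, fs + fwd_len, rs, rs + rev_len, fmm, rmm, insert,
                )
            )

    # - strand: same search on the reverse complement, mapped back.
    rc_seq = reverse_complement(seq)
    minus = _pair_sites(
        rc_seq,
        find_primer_sites(rc_seq, pair.forward, pair.max_mismatch),
        find_primer_sites(rc_seq, rc_rev, pair.max_mismatch),
        fwd_len,
        rev_len,
        pair,
    )
    for fs, fmm, rs, rmm, insert in minus:
        # interval [a, b) on rc maps to [L-b, L-a) on the + strand
        fwd_start, fwd_end = L - (fs + fwd_len), L - fs
        rev_start, rev_end = L - (rs + rev_len), L - rs
        key = (fwd_start, rev_start, "-")
        if key not in seen:
            seen.add(key)
            hits.append(
                AmpliconHit(
                    record.seq_id, record.species_id, pair.marker, "-",
                    fwd_start, fwd_end, rev_start, rev_end, fmm, rmm, insert,
                )
            )

    hits.sort(key=lambda h: (h.fwd_start, h.rev_start, h.strand))
    return hits


def run_insilico_pcr_many(
    records: Iterable[ReferenceSequence], pairs: Iterable[PrimerPair]
) -> list[AmpliconHit]:
    pairs = list(pairs)
    hits: list[AmpliconHit] = []
    for rec in records:
        for pair in pairs:
            hits.extend(run_insilico_pcr(rec, pair))
    return hits


# ---------------------------------------------------------------------------
# Per-species aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesAmplification:
    """Whether a species amplifies for a marker, and its conservative mismatches.

    When several individuals of a species amplify with different mismatch
    counts, the largest count per primer is kept (a conservative view of
    amplification success).  Species known only from a custom database have
    unknown mismatches and are excluded from mismatch profiles.
    """

    species_id: str
    marker: str
    amplified: bool
    source: Optional[str] = None  # 'in_silico' | 'custom_db'
    cons_fwd_mismatches: Optional[int] = None
    cons_rev_mismatches: Optional[int] = None


def _representative_hit(hits: Sequence[AmpliconHit]) -> AmpliconHit:
    """The hit that represents one sequence: minimal total mismatches,
    ties broken by smallest fwd_start then rev_start."""
    return min(
        hits,
        key=lambda h: (h.fwd_mismatches + h.rev_mismatches, h.fwd_start, h.rev_start),
    )


def aggregate_species(
    hits: Iterable[AmpliconHit],
    species_ids: Iterable[str],
    markers: Iterable[str] = MARKERS,
    custom_db: Optional[set[tuple[str, str]]] = None,
) -> list[SpeciesAmplification]:
    """Collapse per-sequence hits to one amplification verdict per (species, marker).

    Each sequence contributes its best (minimal-mismatch) hit; the species'
    conservative counts are the per-primer maxima across its sequences, the
    forward and reverse maxima taken independently.  Custom-database
    membership makes a species amplified even without an in silico hit.
    """
    custom_db = custom_db or set()
    markers = list(markers)
    by_key: dict[tuple[str, str], dict[str, list[AmpliconHit]]] = {}
    for h in hits:
        by_key.setdefault((h.species_id, h.marker), {}).setdefault(h.seq_id, []).append(h)

    out: list[SpeciesAmplification] = []
    for sp in species_ids:
        for marker in markers:
            per_seq = by_key.get((sp, marker))
            in_custom = (sp, marker) in custom_db
            if per_seq:
                reps = [_representative_hit(seq_hits) for seq_hits in per_seq.values()]
                out.append(
                    SpeciesAmplification(
                        sp, marker, True, "in_silico",
                        max(r.fwd_mismatches for r in reps),
                        max(r.rev_mismatches for r in reps),
                    )
                )
            elif in_custom:
                out.append(SpeciesAmplification(sp, marker, True, "custom_db"))
            else:
                out.append(SpeciesAmplification(sp, marker, False))
    return out
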