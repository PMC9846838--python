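"""Seeded synthetic inputs with known ground truth.

The generator emulates the statistical structure of the study system: a
shallow-biased distribution of species depth ranges (species richness is
highest near the surface), habitat labels consistent with each range,
red-list status, region membership, noisy occurrence records resolved
through a jointly-constructed bathymetric grid, and 12S reference sequences
whose primer binding sites carry a controlled number of substitutions.

Everything flows from a single seed; each sub-generator (truth, occurrences,
reference database) derives an independent stream from it, so regenerating
one artifact never perturbs the others.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .diversity import DEFAULT_LAYERS, ascend_layer
from .insilico_pcr import (
    DEFAULT_PRIMERS,
    IUPAC_SETS,
    MARKER_FAMILIES,
    PrimerPair,
    reverse_complement,
    run_insilico_pcr,
)
from .io_formats import (
    MARKERS,
    REGIONS,
    BathymetryLookup,
    ReferenceSequence,
    RegionChecklist,
)

logger = logging.getLogger("bathygap")

# ---------------------------------------------------------------------------
# Bathymetric grid used by the generator
# ---------------------------------------------------------------------------
# Occurrence depths and the 1-degree bathymetry are constructed jointly: each
# drawn depth is snapped to the centre of a synthetic grid cell whose
# elevation is exactly minus that depth.  The 64,800 cells of the global grid
# tile depths 0..18,200 m at ~0.28 m resolution, deep enough for any outlier
# the generator can produce (3 x 6000 + 100 m).

_N_LON, _N_LAT = 360, 180
_N_CELLS = _N_LON * _N_LAT
_DEPTH_CAP = 18_200.0
_CELL_DEPTH = _DEPTH_CAP / _N_CELLS


def _cell_depth(k: np.ndarray) -> np.ndarray:
    return (k + 0.5) * _CELL_DEPTH


def _depth_to_cell(depth: np.ndarray) -> np.ndarray:
    return np.clip(np.round(depth / _CELL_DEPTH - 0.5).astype(int), 0, _N_CELLS - 1)


# ---------------------------------------------------------------------------
# Configuration and truth records
# ---------------------------------------------------------------------------

_DEFAULT_COVERAGE = {
    "shallow": 0.5,
    "mesophotic": 0.25,
    "rariphotic": 0.25,
    "mesopelagic": 0.25,
    "bathypelagic": 0.25,
}

_IUCN_WEIGHTS = {
    "Actinopterygii": {
        "LC": 0.50, "NT": 0.05, "VU": 0.04, "EN": 0.03, "CR": 0.02,
        "DD": 0.16, "NE": 0.20,
    },
    # the chondrichthyan source data only contains evaluated species: no NE
    "Chondrichthyes": {
        "LC": 0.35, "NT": 0.12, "VU": 0.18, "EN": 0.12, "CR": 0.08,
        "DD": 0.15, "NE": 0.0,
    },
}

_HABITAT_WEIGHTS = {
    "demersal": 0.45,
    "benthopelagic": 0.15,
    "pelagic-oceanic": 0.10,
    "bathydemersal": 0.10,
    "reef-associated": 0.10,
    "pelagic-neritic": 0.05,
    "bathypelagic": 0.05,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic model; see docs for the rationale of defaults."""

    n_actinopterygii: int = 1000
    n_chondrichthyes: int = 100
    #: probability a species' minimum depth lies in the first 30 m
    shallow_bias: float = 0.7
    #: log-scale parameters of the lognormal range-width model (metres)
    range_width_log_mean: float = math.log(150.0)
    range_width_log_sd: float = 1.0
    occurrences_per_species: int = 100
    #: probability an occurrence depth is drawn far outside the true range
    outlier_rate: float = 0.01
    #: per ascend-layer probability that a species has a reference sequence
    coverage_prob: dict = field(default_factory=lambda: dict(_DEFAULT_COVERAGE))
    #: categorical over 0..3 injected substitutions per primer
    mismatch_prob: tuple = (0.1, 0.7, 0.15, 0.05)
    #: number of 3'-terminal primer positions protected from substitution
    exclude_3prime: int = 2
    markers: tuple = MARKERS
    #: probability both documented endpoints are present (FishBase-like)
    documented_fraction: float = 0.84
    #: probability an uncovered MiFish species is in the custom database
    custom_db_prob: float = 0.0
    #: probability a fully uncovered species still emits a primer-free decoy
    decoy_prob: float = 0.5
    background_len: int = 150
    force_habitat: Optional[str] = None
    force_ascend_layer: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_actinopterygii + self.n_chondrichthyes <= 0:
            raise ValueError("n_species must be positive")
        if self.n_actinopterygii < 0 or self.n_chondrichthyes < 0:
            raise ValueError("species counts must be non-negative")
        for name, p in [
            ("shallow_bias", self.shallow_bias),
            ("outlier_rate", self.outlier_rate),
            ("documented_fraction", self.documented_fraction),
            ("custom_db_prob", self.custom_db_prob),
            ("decoy_prob", self.decoy_prob),
            *[(f"coverage_prob[{k}]", v) for k, v in self.coverage_prob.items()],
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        if abs(sum(self.mismatch_prob) - 1.0) > 1e-9 or min(self.mismatch_prob) < 0:
            raise ValueError("mismatch_prob must be a categorical over 0..3")
        if self.occurrences_per_species <= 0:
            raise ValueError("occurrences_per_species must be positive")
        if self.exclude_3prime < 0:
            raise ValueError("exclude_3prime must be >= 0")


@dataclass
class TruthSpecies:
    """Ground truth for one synthetic species."""

    species_id: str
    taxon_class: str
    habitat: str
    iucn_raw: str
    true_min_depth_m: float
    true_max_depth_m: float
    regions: frozenset
    covered_by: dict  # marker -> bool (has an amplifiable reference sequence)
    injected_mismatches: dict  # (marker, 'forward'|'reverse') -> int in 0..3
    documented: str  # 'both' | 'min_only' | 'max_only' | 'none'
    custom_db_markers: frozenset = frozenset()


_LAYER_BOUNDS = {l.name: (l.lower_m, l.upper_m) for l in DEFAULT_LAYERS}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _draw_range(rng: np.random.Generator, cfg: GeneratorConfig) -> tuple[float, float]:
    if cfg.force_ascend_layer is not None:
        lo, hi = _LAYER_BOUNDS[cfg.force_ascend_layer]
        hi = min(hi, 3000.0)  # keep deep minima inside the layered column
        mn = rng.uniform(lo, hi)
    elif cfg.force_habitat == "bathypelagic":
        mn = rng.uniform(1000.0, 3000.0)
    elif cfg.force_habitat == "bathydemersal":
        mn = rng.uniform(200.0, 2500.0)
    elif cfg.force_habitat in ("reef-associated", "pelagic-neritic"):
        mn = rng.uniform(0.0, 150.0)
    elif cfg.force_habitat in ("pelagic-oceanic", "benthopelagic"):
        mn = 0.0
    elif rng.random() < cfg.shallow_bias:
        mn = rng.uniform(0.0, 30.0)
    else:
        mn = rng.uniform(30.0, 2500.0)
    width = rng.lognormal(cfg.range_width_log_mean, cfg.range_width_log_sd)
    mx = min(mn + width, 6000.0)
    if cfg.force_habitat in ("reef-associated", "pelagic-neritic"):
        mx = min(mx, 200.0)
    return mn, mx


def _draw_habitat(
    rng: np.random.Generator, cfg: GeneratorConfig, mn: float, mx: float
) -> tuple[str, float]:
    """Pick a habitat consistent with the range; open-water habitats reach 0 m."""
    if cfg.force_habitat is not None:
        habitat = cfg.force_habitat
    else:
        eligible = ["demersal"]
        if mn >= 200:
            eligible.append("bathydemersal")
        if mn >= 1000:
            eligible.append("bathypelagic")
        if mx <= 200:
            eligible += ["reef-associated", "pelagic-neritic"]
        if mn < 30 and cfg.force_ascend_layer in (None, "shallow"):
            eligible += ["pelagic-oceanic", "benthopelagic"]
        weights = np.array([_HABITAT_WEIGHTS[h] for h in eligible])
        habitat = str(rng.choice(eligible, p=weights / weights.sum()))
    if habitat in ("pelagic-oceanic", "benthopelagic"):
        mn = 0.0
    return habitat, mn


def generate_truth(cfg: GeneratorConfig) -> list[TruthSpecies]:
    """Draw the synthetic species pool; deterministic for a fixed seed."""
    cfg.validate()
    rng = _rng(cfg.seed, 0)
    for layer in cfg.coverage_prob:
        if layer not in _LAYER_BOUNDS:
            raise ValueError(f"coverage_prob stratum {layer!r} is not a depth layer")

    species: list[TruthSpecies] = []
    plan = [("Actinopterygii", "act", cfg.n_actinopterygii),
            ("Chondrichthyes", "cho", cfg.n_chondrichthyes)]
    for taxon_class, prefix, n in plan:
        iucn_cats = list(_IUCN_WEIGHTS[taxon_class])
        iucn_w = np.array([_IUCN_WEIGHTS[taxon_class][c] for c in iucn_cats])
        iucn_w = iucn_w / iucn_w.sum()
        for i in range(n):
            mn, mx = _draw_range(rng, cfg)
            habitat, mn = _draw_habitat(rng, cfg, mn, mx)
            iucn_raw = str(rng.choice(iucn_cats, p=iucn_w))
            n_regions = int(rng.integers(1, 4))
            regions = frozenset(rng.choice(REGIONS, n_regions, replace=False))
            stratum = ascend_layer(min(mn, 3999.9))
            p_cov = cfg.coverage_prob[stratum]
            covered = {m: bool(rng.random() < p_cov) for m in cfg.markers}
            injected = {}
            for m, cov in covered.items():
                if cov:
                    injected[(m, "forward")] = int(rng.choice(4, p=cfg.mismatch_prob))
                    injected[(m, "reverse")] = int(rng.choice(4, p=cfg.mismatch_prob))
            u = rng.random()
            if u < cfg.documented_fraction:
                documented = "both"
            elif u < cfg.documented_fraction + (1 - cfg.documented_fraction) * 0.25:
                documented = "min_only"
            elif u < cfg.documented_fraction + (1 - cfg.documented_fraction) * 0.5:
                documented = "max_only"
            else:
                documented = "none"
            custom = frozenset(
                m for m in cfg.markers
                if m.startswith("MiFish") and not covered[m]
                and rng.random() < cfg.custom_db_prob
            )
            species.append(
                TruthSpecies(
                    f"{prefix}{i:05d}", taxon_class, habitat, iucn_raw,
                    mn, mx, regions, covered, injected, documented, custom,
                )
            )
    return species


# ---------------------------------------------------------------------------
# Occurrences + bathymetry
# ---------------------------------------------------------------------------


def generate_occurrences(
    truth: Sequence[TruthSpecies], cfg: GeneratorConfig
) -> tuple[pd.DataFrame, BathymetryLookup]:
    """Noisy occurrences and the matching bathymetric grid.

    Depths are uniform on the true range with probability 1 - outlier_rate,
    otherwise uniform on [0, 3 x true_max + 100].  Each depth is snapped to
    the centre of a synthetic grid cell (resolution ~0.28 m, clamped inside
    the true range for non-outliers) whose elevation is exactly -depth, so
    resolving an occurrence through the grid returns its depth.
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    cfg.validate()
    rng = _rng(cfg.seed, 1)
    n = cfg.occurrences_per_species

    sp_ids: list[str] = []
    all_k: list[np.ndarray] = []
    for sp in truth:
        is_outlier = rng.random(n) < cfg.outlier_rate
        d = rng.uniform(sp.true_min_depth_m, sp.true_max_depth_m, n)
        d_out = rng.uniform(0.0, 3.0 * sp.true_max_depth_m + 100.0, n)
        k = _depth_to_cell(np.where(is_outlier, d_out, d))
        # keep non-outlier depths inside the true range after snapping
        k_lo = int(np.ceil(sp.true_min_depth_m / _CELL_DEPTH - 0.5))
        k_hi = int(np.floor(sp.true_max_depth_m / _CELL_DEPTH - 0.5))
        if k_lo <= k_hi:
            k = np.where(is_outlier, k, np.clip(k, k_lo, k_hi))
        sp_ids.extend([sp.species_id] * n)
        all_k.append(k)

    k = np.concatenate(all_k)
    lon = (k % _N_LON) - 180 + rng.random(k.size) * 0.999
    lat = (k // _N_LON) - 90 + rng.random(k.size) * 0.999
    occurrences = pd.DataFrame({"species_id": sp_ids, "lon": lon, "lat": lat})

    used = np.unique(k)
    cells = {
        (int(kk % _N_LON) - 180, int(kk // _N_LON) - 90): -float(_cell_depth(kk))
        for kk in used
    }
    return occurrences, BathymetryLookup(cells)


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, length))


def mutate_primer_site(
    primer: str, n_mismatches: int, exclude_3prime: int, rng: np.random.Generator
) -> str:
    """Substitute exactly *n_mismatches* positions of a primer's binding site.

    Positions are chosen uniformly among those more than *exclude_3prime*
    bases from the 3' end (terminal mismatches are especially detrimental to
    amplification, so the generator never places them there), and each
    substituted base is drawn outside the IUPAC set of the primer code, which
    guarantees the position counts as a mismatch.
    """
    mutable = [
        i for i in range(len(primer) - exclude_3prime)
        if len(IUPAC_SETS[primer[i]]) < 4
    ]
    if n_mismatches > len(mutable):
        raise ValueError(
            f"cannot place {n_mismatches} mismatches on a {len(primer)} nt primer "
            f"with {exclude_3prime} protected 3' positions"
        )
    site = list(primer)
    for i in rng.choice(mutable, n_mismatches, replace=False):
        options = sorted(set("ACGT") - IUPAC_SETS[primer[i]])
        site[i] = str(rng.choice(options))
    return "".join(site)


def _verify_construction(
    seq: ReferenceSequence,
    marker: str,
    injected: tuple[int, int],
    pairs: Mapping[str, PrimerPair],
) -> bool:
    """Accept a candidate only if amplification matches the construction.

    The intended marker must yield exactly one hit carrying the injected
    mismatch counts, and no marker of a different family may amplify at all.
    (Markers of the same family target the same locus with near-identical
    primers, so cross-amplification within a family is legitimate.)
    """
    fam = MARKER_FAMILIES.get(marker, marker)
    for m, pair in pairs.items():
        hits = run_insilico_pcr(seq, pair)
        if m == marker:
            if len(hits) != 1:
                return False
            h = hits[0]
            if (h.fwd_mismatches, h.rev_mismatches) != injected or h.strand != "+":
                return False
        elif MARKER_FAMILIES.get(m, m) != fam and hits:
            return False
    return True


def generate_reference_db(
    truth: Sequence[TruthSpecies],
    primer_pairs: Mapping[str, PrimerPair],
    cfg: GeneratorConfig,
) -> list[ReferenceSequence]:
    """Reference sequences with controlled primer-site substitutions.

    Each covered (species, marker) yields one sequence: random background,
    the forward priming site carrying its injected substitutions, an insert
    of length drawn within the marker's bounds, the reverse-complemented
    reverse site with its substitutions, then background.  Fully uncovered
    species may emit a primer-free decoy.  Candidates whose random parts
    collide with any primer are rejected and redrawn.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 2)
    records: list[ReferenceSequence] = []
    for sp in truth:
        emitted = False
        for marker in cfg.markers:
            if not sp.covered_by.get(marker, False):
                continue
            pair = primer_pairs[marker]
            fmm = sp.injected_mismatches[(marker, "forward")]
            rmm = sp.injected_mismatches[(marker, "reverse")]
            for attempt in range(50):
                insert_len = int(rng.integers(pair.insert_min_bp, pair.insert_max_bp + 1))
                seq = (
                    _random_seq(rng, cfg.background_len)
                    + mutate_primer_site(pair.forward, fmm, cfg.exclude_3prime, rng)
                    + _random_seq(rng, insert_len)
                    + reverse_complement(
                        mutate_primer_site(pair.reverse, rmm, cfg.exclude_3prime, rng)
                    )
                    + _random_seq(rng, cfg.background_len)
                )
                rec = ReferenceSequence(f"{sp.species_id}_{marker}", sp.species_id, seq)
                if _verify_construction(rec, marker, (fmm, rmm), primer_pairs):
                    records.append(rec)
                    emitted = True
                    break
            else:
                raise RuntimeError(
                    f"could not construct a clean sequence for "
                    f"{sp.species_id}/{marker} after 50 attempts"
                )
        if not emitted and rng.random() < cfg.decoy_prob:
            for attempt in range(50):
                rec = ReferenceSequence(
                    f"{sp.species_id}_decoy", sp.species_id,
                    _random_seq(rng, 2 * cfg.background_len + 100),
                )
                if all(not run_insilico_pcr(rec, p) for p in primer_pairs.values()):
                    records.append(rec)
                    break
            else:
                raise RuntimeError(f"could not construct a decoy for {sp.species_id}")
    return records


# ---------------------------------------------------------------------------
# Tabular views + full input bundle
# ---------------------------------------------------------------------------


def truth_species_table(truth: Sequence[TruthSpecies]) -> pd.DataFrame:
    """Documented-range table: endpoints blanked out where undocumented."""
    rows = []
    for sp in truth:
        mn = sp.true_min_depth_m if sp.documented in ("both", "min_only") else np.nan
        mx = sp.true_max_depth_m if sp.documented in ("both", "max_only") else np.nan
        rows.append((sp.species_id, sp.taxon_class, sp.habitat, mn, mx))
    return pd.DataFrame(
        rows, columns=["species_id", "taxon_class", "habitat",
                       "min_depth_m", "max_depth_m"]
    )


def truth_iucn_table(truth: Sequence[TruthSpecies]) -> pd.DataFrame:
    return pd.DataFrame(
        [(sp.species_id, sp.iucn_raw) for sp in truth],
        columns=["species_id", "iucn_raw"],
    )


def truth_checklist(truth: Sequence[TruthSpecies]) -> RegionChecklist:
    cl = RegionChecklist()
    for sp in truth:
        for region in sp.regions:
            cl.add(sp.species_id, region)
    return cl


def truth_custom_db(truth: Sequence[TruthSpecies]) -> set[tuple[str, str]]:
    return {(sp.species_id, m) for sp in truth for m in sp.custom_db_markers}


def write_inputs(
    truth: Sequence[TruthSpecies],
    cfg: GeneratorConfig,
    out_dir,
    primer_pairs: Optional[Mapping[str, PrimerPair]] = None,
) -> dict:
    """Generate and write every pipeline input under *out_dir*; returns paths."""
    from pathlib import Path

    from .io_formats import write_checklists, write_fasta

    primer_pairs = primer_pairs or DEFAULT_PRIMERS
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    occurrences, bathy = generate_occurrences(truth, cfg)
    refs = generate_reference_db(truth, primer_pairs, cfg)

    paths = {
        "species": out_dir / "species.csv",
        "occurrences": out_dir / "occurrences.csv",
        "bathymetry": out_dir / "bathymetry.csv",
        "iucn": out_dir / "iucn.csv",
        "checklists": out_dir / "checklists.csv",
        "fasta": out_dir / "reference.fasta",
        "custom_db": out_dir / "custom_db.csv",
    }
    truth_species_table(truth).to_csv(paths["species"], index=False)
    occurrences.to_csv(paths["occurrences"], index=False)
    bathy.to_frame().to_csv(paths["bathymetry"], index=False)
    truth_iucn_table(truth).to_csv(paths["iucn"], index=False)
    write_checklists(truth_checklist(truth), paths["checklists"])
    write_fasta(refs, paths["fasta"])
    pd.DataFrame(
        sorted(truth_custom_db(truth)), columns=["species_id", "marker"]
    ).to_csv(paths["custom_db"], index=False)
    return {k: str(v) for k, v in paths.items()}
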