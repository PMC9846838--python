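"""Genetic reference-database coverage statistics over depth, region and status.

Joins the resolved species depth ranges with the per-species amplification
verdicts to produce: coverage profiles by depth (optionally stratified by
taxon class, red-list group or ocean checklist), coverage by ascend layer
(depth generalists versus deep-endemics), and per-depth mismatch-count
profiles for each primer.  ``run_pipeline`` chains every stage of the
analysis and writes the complete report bundle.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import depth_ranges, diversity, insilico_pcr, io_formats
from .diversity import DEFAULT_LAYERS, DepthLayer, PROFILE_MAX_DEPTH, _interval_counts
from .insilico_pcr import SpeciesAmplification
from .io_formats import MARKERS, RegionChecklist

logger = logging.getLogger("bathygap")


def amplification_frame(amps: Iterable[SpeciesAmplification]) -> pd.DataFrame:
    """Tabular view of per-species amplification verdicts."""
    return pd.DataFrame(
        [
            (a.species_id, a.marker, a.amplified, a.source or "",
             a.cons_fwd_mismatches, a.cons_rev_mismatches)
            for a in amps
        ],
        columns=["species_id", "marker", "amplified", "source",
                 "cons_fwd_mismatches", "cons_rev_mismatches"],
    )


def _covered_ids(amp: pd.DataFrame, marker: str) -> set[str]:
    sel = amp[(amp["marker"] == marker) & amp["amplified"]]
    return set(sel["species_id"])


def _profile_block(
    species: pd.DataFrame, covered: set[str], max_depth: int
) -> pd.DataFrame:
    mins = species["min_depth_m"].to_numpy(dtype=float)
    maxs = species["max_depth_m"].to_numpy(dtype=float)
    n_all = _interval_counts(mins, maxs, max_depth)
    mask = species["species_id"].isin(covered).to_numpy()
    n_cov = _interval_counts(mins[mask], maxs[mask], max_depth)
    with np.errstate(invalid="ignore"):
        prop = np.where(n_all > 0, n_cov / np.where(n_all > 0, n_all, 1), np.nan)
    return pd.DataFrame(
        {
            "depth_m": np.arange(max_depth + 1),
            "n_species": n_all,
            "n_covered": n_cov,
            "proportion": prop,
        }
    )


def coverage_by_depth(
    species: pd.DataFrame,
    amplifications: pd.DataFrame,
    markers: Sequence[str] = MARKERS,
    stratifier: Optional[str] = None,
    checklist: Optional[RegionChecklist] = None,
    max_depth: int = PROFILE_MAX_DEPTH,
) -> pd.DataFrame:
    """Per-metre coverage profile for each marker.

    *stratifier* may be a species-table column ('taxon_class', 'iucn_group')
    or 'region', in which case *checklist* supplies the (possibly
    multi-valued) region membership and a species counts in every region it
    belongs to.  Depths where no species occurs have NaN proportion.
    """
    if stratifier == "region":
        if checklist is None:
            raise ValueError("region stratification requires a checklist")
        rows = [
            (sp, region)
            for sp in species["species_id"]
            for region in sorted(checklist.regions_of(sp))
        ]
        membership = pd.DataFrame(rows, columns=["species_id", "region"])
        expanded = species.merge(membership, on="species_id")
        groups = list(expanded.groupby("region", sort=True))
    elif stratifier is not None:
        groups = list(species.groupby(stratifier, sort=True))
    else:
        groups = [("all", species)]

    blocks = []
    for marker in markers:
        covered = _covered_ids(amplifications, marker)
        for value, grp in groups:
            block = _profile_block(grp, covered, max_depth)
            block.insert(0, "stratum", str(value))
            block.insert(0, "marker", marker)
            blocks.append(block)
    if not blocks:
        return pd.DataFrame(
            columns=["marker", "stratum", "depth_m", "n_species", "n_covered",
                     "proportion"]
        )
    return pd.concat(blocks, ignore_index=True)


def coverage_by_ascend_layer(
    species: pd.DataFrame,
    amplifications: pd.DataFrame,
    markers: Sequence[str] = MARKERS,
    layers: Sequence[DepthLayer] = DEFAULT_LAYERS,
) -> pd.DataFrame:
    """Coverage per ascend-layer class (shallow reachers vs deep-endemics).

    Every retained species is counted in exactly one row per marker: the
    layer containing its minimum depth.
    """
    asc = diversity.ascend_layers(species, layers)
    rows = []
    for marker in markers:
        covered = _covered_ids(amplifications, marker)
        for layer in layers:
            in_layer = species.loc[asc == layer.name, "species_id"]
            n = len(in_layer)
            n_cov = int(in_layer.isin(covered).sum())
            rows.append(
                (marker, layer.name, n, n_cov, n_cov / n if n else np.nan)
            )
    return pd.DataFrame(
        rows, columns=["marker", "ascend_layer", "n_species", "n_covered", "proportion"]
    )


def mismatch_profile(
    species: pd.DataFrame,
    amplifications: pd.DataFrame,
    markers: Sequence[str] = MARKERS,
    max_depth: int = PROFILE_MAX_DEPTH,
) -> pd.DataFrame:
    """Per-depth proportions of covered species with 0-3 conservative mismatches.

    Only species amplified in silico contribute (custom-database species have
    unknown mismatch counts); proportions at each depth sum to 1 over the
    species present there.
    """
    blocks = []
    for marker in markers:
        amp = amplifications[
            (amplifications["marker"] == marker)
            & amplifications["amplified"]
            & (amplifications["source"] == "in_silico")
        ]
        merged = species.merge(
            amp[["species_id", "cons_fwd_mismatches", "cons_rev_mismatches"]],
            on="species_id",
        )
        mins = merged["min_depth_m"].to_numpy(dtype=float)
        maxs = merged["max_depth_m"].to_numpy(dtype=float)
        n_known = _interval_counts(mins, maxs, max_depth)
        for end, col in (("forward", "cons_fwd_mismatches"),
                         ("reverse", "cons_rev_mismatches")):
            counts = merged[col].to_numpy()
            block = pd.DataFrame(
                {"depth_m": np.arange(max_depth + 1), "n_known": n_known}
            )
            with np.errstate(invalid="ignore"):
                for k in range(4):
                    sel = counts == k
                    n_k = _interval_counts(mins[sel], maxs[sel], max_depth)
                    block[f"p{k}"] = np.where(
                        n_known > 0, n_k / np.where(n_known > 0, n_known, 1), np.nan
                    )
            block.insert(0, "primer_end", end)
            block.insert(0, "marker", marker)
            blocks.append(block)
    if not blocks:
        return pd.DataFrame(
            columns=["marker", "primer_end", "depth_m", "n_known",
                     "p0", "p1", "p2", "p3"]
        )
    return pd.concat(blocks, ignore_index=True)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _write_beta(per_class: dict[str, tuple[pd.DataFrame, pd.DataFrame]], out_dir: Path):
    for which, idx in (("beta_turnover", 0), ("beta_nestedness", 1)):
        frames = []
        for taxon_class, mats in sorted(per_class.items()):
            mat = mats[idx].copy()
            mat.insert(0, "layer", mat.index)
            mat.insert(0, "taxon_class", taxon_class)
            frames.append(mat.reset_index(drop=True))
        pd.concat(frames, ignore_index=True).to_csv(out_dir / f"{which}.csv", index=False)


def write_diversity_outputs(
    kept: pd.DataFrame, layers: Sequence[DepthLayer], out_dir: Path
) -> None:
    """Richness, status-proportion, occupancy and beta-partition CSVs."""
    out_dir = Path(out_dir)
    diversity.richness_profile(kept, stratifier="taxon_class").to_csv(
        out_dir / "richness_profile.csv", index=False
    )
    status_blocks = []
    beta_per_class: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    occ_blocks = []
    for taxon_class, grp in kept.groupby("taxon_class", sort=True):
        sp_block = diversity.status_proportion_profile(grp)
        sp_block.insert(0, "taxon_class", taxon_class)
        status_blocks.append(sp_block)
        occupancy = diversity.layer_occupancy(grp, layers)
        occ = occupancy.reset_index()
        occ.insert(0, "taxon_class", taxon_class)
        occ_blocks.append(occ)
        beta_per_class[taxon_class] = diversity.pairwise_beta(occupancy)
    if status_blocks:
        pd.concat(status_blocks, ignore_index=True).to_csv(
            out_dir / "status_proportions.csv", index=False
        )
        pd.concat(occ_blocks, ignore_index=True).to_csv(
            out_dir / "occupancy.csv", index=False
        )
        _write_beta(beta_per_class, out_dir)


def write_pcr_outputs(
    refs, pairs: dict, retained_ids, custom_db: set, out_dir: Path
) -> pd.DataFrame:
    """Run in silico PCR, write hits.csv / species_amplification.csv."""
    out_dir = Path(out_dir)
    hits = insilico_pcr.run_insilico_pcr_many(refs, pairs.values())
    hits_df = pd.DataFrame(
        [
            (h.seq_id, h.species_id, h.marker, h.strand,
             h.fwd_start, h.fwd_end, h.rev_start, h.rev_end,
             h.fwd_mismatches, h.rev_mismatches,
             h.insert_length_bp, h.insert_sequence)
            for h in hits
        ],
        # coordinates are 0-based half-open on the + strand
        columns=["seq_id", "species_id", "marker", "strand",
                 "fwd_start", "fwd_end", "rev_start", "rev_end",
                 "fwd_mismatches", "rev_mismatches",
                 "insert_length_bp", "insert_sequence"],
    )
    hits_df.to_csv(out_dir / "hits.csv", index=False)
    amps = insilico_pcr.aggregate_species(hits, retained_ids, list(pairs), custom_db)
    amp_df = amplification_frame(amps)
    amp_df.to_csv(out_dir / "species_amplification.csv", index=False)
    return amp_df


def write_coverage_outputs(
    kept: pd.DataFrame,
    amp_df: pd.DataFrame,
    checklist: RegionChecklist,
    markers: Sequence[str],
    layers: Sequence[DepthLayer],
    out_dir: Path,
) -> None:
    out_dir = Path(out_dir)
    coverage_by_depth(kept, amp_df, markers, stratifier="taxon_class").to_csv(
        out_dir / "coverage_by_depth.csv", index=False
    )
    coverage_by_depth(
        kept, amp_df, markers, stratifier="region", checklist=checklist
    ).to_csv(out_dir / "coverage_by_region.csv", index=False)
    coverage_by_depth(kept, amp_df, markers, stratifier="iucn_group").to_csv(
        out_dir / "coverage_by_iucn.csv", index=False
    )
    coverage_by_ascend_layer(kept, amp_df, markers, layers).to_csv(
        out_dir / "ascend_coverage.csv", index=False
    )
    mismatch_profile(kept, amp_df, markers).to_csv(
        out_dir / "mismatch_profile.csv", index=False
    )


def run_pipeline(config) -> dict:
    """Run every stage — simulate/load, depth ranges, diversity, PCR, coverage.

    *config* is a :class:`bathygap.cli.RunConfig`.  Writes the full report
    bundle under ``config.out_dir`` and returns the run summary (also written
    as ``run_summary.json``).  Idempotent for a fixed seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = config.primer_pairs()

    if config.simulate:
        from . import synthetic_data

        gen_cfg = config.generator_config()
        truth = synthetic_data.generate_truth(gen_cfg)
        input_paths = synthetic_data.write_inputs(
            truth, gen_cfg, out_dir / "inputs", pairs
        )
    else:
        input_paths = dict(config.inputs)

    species = io_formats.read_species_table(input_paths["species"])
    iucn = io_formats.read_iucn_table(input_paths["iucn"])
    occurrences = io_formats.read_occurrences(input_paths["occurrences"])
    bathy = io_formats.read_bathymetry(input_paths["bathymetry"])
    checklist = io_formats.read_checklists(input_paths["checklists"])
    refs = io_formats.read_fasta(input_paths["fasta"])
    custom_db = (
        io_formats.read_custom_db(input_paths["custom_db"])
        if input_paths.get("custom_db")
        else set()
    )

    # --- depth ranges -----------------------------------------------------
    depth_table = depth_ranges.build_depth_table(
        species, occurrences, bathy,
        q_low=config.q_low, q_high=config.q_high, min_n=config.min_n, iucn=iucn,
    )
    depth_table.to_csv(out_dir / "depth_table.csv", index=False)
    kept = depth_ranges.retained(depth_table)
    if kept.empty:
        logger.warning("no species with a resolved depth range; outputs are empty")

    layers = config.depth_layers()
    markers = list(pairs)
    write_diversity_outputs(kept, layers, out_dir)
    amp_df = write_pcr_outputs(refs, pairs, kept["species_id"], custom_db, out_dir)
    write_coverage_outputs(kept, amp_df, checklist, markers, layers, out_dir)

    # --- summary ------------------------------------------------------------
    summary: dict = {
        "n_species_input": int(len(species)),
        "n_species_retained": int(len(kept)),
        "n_species_unresolved": int((depth_table["depth_source"] == "unresolved").sum()),
        "n_reference_sequences": int(len(refs)),
        "n_amplified_pairs": int(amp_df["amplified"].sum()),
        "coverage": {},
    }
    for marker in markers:
        covered = _covered_ids(amp_df, marker)
        per_class = {}
        for taxon_class, grp in kept.groupby("taxon_class", sort=True):
            n = len(grp)
            n_cov = int(grp["species_id"].isin(covered).sum())
            per_class[taxon_class] = {
                "n_species": n,
                "n_covered": n_cov,
                "percent": round(100.0 * n_cov / n, 2) if n else None,
            }
        summary["coverage"][marker] = per_class
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
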