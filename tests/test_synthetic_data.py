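import numpy as np
import pandas as pd
import pytest

from bathygap.depth_ranges import resolve_depths
from bathygap.insilico_pcr import (
    DEFAULT_PRIMERS,
    MARKER_FAMILIES,
    PrimerPair,
    aggregate_species,
    count_mismatches,
    run_insilico_pcr,
    run_insilico_pcr_many,
)
from bathygap.synthetic_data import (
    GeneratorConfig,
    TruthSpecies,
    generate_occurrences,
    generate_reference_db,
    generate_truth,
    mutate_primer_site,
    truth_species_table,
    write_inputs,
)
from conftest import truth_range_frame


def _one_species(mn=100.0, mx=200.0, covered=None, injected=None):
    return TruthSpecies(
        "sp0", "Actinopterygii", "demersal", "LC", mn, mx,
        frozenset({"Atlantic"}), covered or {}, injected or {}, "both",
    )


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def test_generator_is_deterministic():
    cfg = GeneratorConfig(n_actinopterygii=30, n_chondrichthyes=5, seed=7)
    t1, t2 = generate_truth(cfg), generate_truth(cfg)
    assert t1 == t2
    occ1, b1 = generate_occurrences(t1, cfg)
    occ2, b2 = generate_occurrences(t2, cfg)
    pd.testing.assert_frame_equal(occ1, occ2)
    assert dict(b1.items()) == dict(b2.items())
    assert generate_reference_db(t1, DEFAULT_PRIMERS, cfg) == generate_reference_db(
        t2, DEFAULT_PRIMERS, cfg
    )


def test_different_seeds_differ():
    a = generate_truth(GeneratorConfig(n_actinopterygii=30, seed=1))
    b = generate_truth(GeneratorConfig(n_actinopterygii=30, seed=2))
    assert a != b


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(n_actinopterygii=0, n_chondrichthyes=0).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(outlier_rate=1.5).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(mismatch_prob=(0.5, 0.5, 0.5, 0.5)).validate()
    with pytest.raises(ValueError):
        generate_truth(GeneratorConfig(coverage_prob={"abyss": 0.5}))


# ---------------------------------------------------------------------------
# truth statistics
# ---------------------------------------------------------------------------


def test_truth_counts_and_vocabulary():
    cfg = GeneratorConfig(n_actinopterygii=50, n_chondrichthyes=10, seed=3)
    truth = generate_truth(cfg)
    classes = [sp.taxon_class for sp in truth]
    assert classes.count("Actinopterygii") == 50
    assert classes.count("Chondrichthyes") == 10
    assert len({sp.species_id for sp in truth}) == 60
    for sp in truth:
        assert 0.0 <= sp.true_min_depth_m <= sp.true_max_depth_m <= 6000.0


def test_force_habitat_bathypelagic_respects_floor():
    cfg = GeneratorConfig(n_actinopterygii=50, force_habitat="bathypelagic", seed=5)
    truth = generate_truth(cfg)
    assert all(sp.habitat == "bathypelagic" for sp in truth)
    assert all(sp.true_min_depth_m >= 1000.0 for sp in truth)


def test_force_ascend_layer():
    from bathygap.diversity import ascend_layer

    cfg = GeneratorConfig(n_actinopterygii=80, force_ascend_layer="mesopelagic", seed=5)
    truth = generate_truth(cfg)
    assert all(ascend_layer(sp.true_min_depth_m) == "mesopelagic" for sp in truth)


def test_shallow_bias_statistic():
    # P(min depth < 30) = shallow_bias; check a 3-sigma binomial band at n=10000
    cfg = GeneratorConfig(n_actinopterygii=10_000, n_chondrichthyes=0,
                          shallow_bias=0.7, seed=19)
    truth = generate_truth(cfg)
    n_shallow = sum(sp.true_min_depth_m < 30.0 for sp in truth)
    sd = (10_000 * 0.7 * 0.3) ** 0.5
    assert abs(n_shallow - 7000) < 3 * sd


def test_documented_blanks_in_species_table():
    cfg = GeneratorConfig(n_actinopterygii=400, n_chondrichthyes=0,
                          documented_fraction=0.5, seed=23)
    table = truth_species_table(generate_truth(cfg))
    n_both = (table["min_depth_m"].notna() & table["max_depth_m"].notna()).sum()
    sd = (400 * 0.25) ** 0.5
    assert abs(n_both - 200) < 3 * sd
    assert (table["min_depth_m"].isna() | table["max_depth_m"].isna()).any()


# ---------------------------------------------------------------------------
# occurrences + bathymetry
# ---------------------------------------------------------------------------


def test_occurrences_resolve_to_their_drawn_depths():
    cfg = GeneratorConfig(occurrences_per_species=200, outlier_rate=0.0, seed=29)
    truth = [_one_species(100.0, 200.0)]
    occ, bathy = generate_occurrences(truth, cfg)
    resolved = resolve_depths(occ, bathy)
    assert len(resolved) == 200  # every cell is ocean
    assert (resolved["depth_m"] >= 100.0).all()
    assert (resolved["depth_m"] <= 200.0).all()


def test_outlier_count_matches_rate():
    cfg = GeneratorConfig(occurrences_per_species=1000, outlier_rate=0.01, seed=31)
    truth = [_one_species(100.0, 200.0)]
    occ, bathy = generate_occurrences(truth, cfg)
    d = resolve_depths(occ, bathy)["depth_m"]
    out_of_range = ((d < 100.0) | (d > 200.0)).sum()
    # ~10 outliers are injected; some land inside the true range by chance
    sd = (1000 * 0.01 * 0.99) ** 0.5
    assert 0 < out_of_range <= 10 + 3 * sd


def test_occurrence_coordinates_are_valid():
    cfg = GeneratorConfig(occurrences_per_species=50, seed=37)
    truth = [_one_species(0.0, 5500.0)]
    occ, _ = generate_occurrences(truth, cfg)
    assert ((occ["lon"] >= -180) & (occ["lon"] < 180)).all()
    assert (occ["lat"].abs() <= 90).all()


# ---------------------------------------------------------------------------
# reference sequences
# ---------------------------------------------------------------------------


def test_mutate_primer_site_semantics(rng):
    primer = DEFAULT_PRIMERS["teleo"].forward
    site = mutate_primer_site(primer, 3, 2, rng)
    assert count_mismatches(primer, site) == 3
    assert site[-2:] == primer[-2:]  # protected 3' positions untouched
    assert mutate_primer_site(primer, 0, 2, rng) == primer
    with pytest.raises(ValueError):
        mutate_primer_site("ACGTACGTACGT", 11, 2, rng)


def test_injected_mismatches_surface_in_hits(rng):
    pairs = {"teleo": PrimerPair(  # pin the insert length to 60 bp
        "teleo", DEFAULT_PRIMERS["teleo"].forward, DEFAULT_PRIMERS["teleo"].reverse,
        insert_min_bp=60, insert_max_bp=60,
    )}
    cfg = GeneratorConfig(markers=("teleo",), seed=41)
    truth = [_one_species(
        covered={"teleo": True},
        injected={("teleo", "forward"): 0, ("teleo", "reverse"): 0},
    )]
    (rec,) = generate_reference_db(truth, pairs, cfg)
    (hit,) = run_insilico_pcr(rec, pairs["teleo"])
    assert (hit.fwd_mismatches, hit.rev_mismatches) == (0, 0)
    assert hit.insert_length_bp == 60


def test_three_mismatches_amplify_only_at_full_cap():
    pairs = dict(DEFAULT_PRIMERS)
    cfg = GeneratorConfig(markers=("teleo",), seed=43)
    truth = [_one_species(
        covered={"teleo": True},
        injected={("teleo", "forward"): 3, ("teleo", "reverse"): 3},
    )]
    (rec,) = generate_reference_db(truth, pairs, cfg)
    (hit,) = run_insilico_pcr(rec, pairs["teleo"])
    assert (hit.fwd_mismatches, hit.rev_mismatches) == (3, 3)
    stricter = PrimerPair(
        "teleo", pairs["teleo"].forward, pairs["teleo"].reverse, max_mismatch=2,
        insert_min_bp=pairs["teleo"].insert_min_bp,
        insert_max_bp=pairs["teleo"].insert_max_bp,
    )
    assert run_insilico_pcr(rec, stricter) == []


def test_decoys_never_amplify():
    cfg = GeneratorConfig(decoy_prob=1.0, markers=("teleo",), seed=47)
    truth = [_one_species(covered={"teleo": False})]
    (rec,) = generate_reference_db(truth, DEFAULT_PRIMERS, cfg)
    assert rec.seq_id.endswith("_decoy")
    for pair in DEFAULT_PRIMERS.values():
        assert run_insilico_pcr(rec, pair) == []


def test_full_knowledge_coverage_recovery(small_truth):
    """Aggregating PCR over the generated reference db recovers covered_by
    exactly for teleo and at the family level for MiFish-U/E."""
    cfg, truth = small_truth
    refs = generate_reference_db(truth, DEFAULT_PRIMERS, cfg)
    hits = run_insilico_pcr_many(refs, DEFAULT_PRIMERS.values())
    amps = aggregate_species(hits, [sp.species_id for sp in truth])
    amp_by = {(a.species_id, a.marker): a.amplified for a in amps}
    for sp in truth:
        assert amp_by[(sp.species_id, "teleo")] == sp.covered_by["teleo"]
        got_fam = amp_by[(sp.species_id, "MiFish-U")] or amp_by[(sp.species_id, "MiFish-E")]
        want_fam = sp.covered_by["MiFish-U"] or sp.covered_by["MiFish-E"]
        assert got_fam == want_fam


def test_write_inputs_bundle(tmp_path, small_truth):
    cfg, truth = small_truth
    paths = write_inputs(truth, cfg, tmp_path / "inputs", DEFAULT_PRIMERS)
    from bathygap import io_formats

    species = io_formats.read_species_table(paths["species"])
    assert len(species) == len(truth)
    occ = io_formats.read_occurrences(paths["occurrences"])
    assert len(occ) == len(truth) * cfg.occurrences_per_species
    io_formats.read_bathymetry(paths["bathymetry"])
    io_formats.read_iucn_table(paths["iucn"])
    io_formats.read_checklists(paths["checklists"])
    io_formats.read_custom_db(paths["custom_db"])
    refs = io_formats.read_fasta(paths["fasta"])
    assert {r.species_id for r in refs} <= {sp.species_id for sp in truth}


def test_truth_range_frame_helper(small_truth):
    _, truth = small_truth
    df = truth_range_frame(truth)
    assert (df["min_depth_m"] <= df["max_depth_m"]).all()
    assert set(df["iucn_group"]) <= {"THR", "LC", "DD", "NE"}
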