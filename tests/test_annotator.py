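import itertools
import json

import numpy as np
import pytest

from cysloop import (AnchorError, MotifPlan, MotifReport, TranscriptomeSpec,
                     anchor_regions, annotate, classify_selectivity,
                     classify_subunit, cys_loop_span, default_profile,
                     make_synthetic_transcriptome, pharmacology_flags,
                     prime_numbering, random_motif_plan)
from cysloop import scaffold
from cysloop.annotate import class_from_features, selectivity_from_primes
from conftest import random_dna


def _protein_for(plan, seed=0, divergence=0.05):
    spec = TranscriptomeSpec(n_genes=1, include_actin=False,
                             motif_plan={"g00": plan}, rng_seed=seed,
                             divergence=divergence)
    truth = make_synthetic_transcriptome(spec)
    return truth.transcript("g00").protein, truth.expected["g00"]


# ---------------------------------------------------------------------------
# Anchoring

def test_reference_anchors_to_itself():
    prof = default_profile()
    regions = anchor_regions(prof.sequence, prof)
    assert regions.intervals == prof.regions
    assert regions.tm_count() == 4


def test_planted_regions_recovered():
    protein, expected = _protein_for(MotifPlan(), divergence=0.0)
    regions = anchor_regions(protein)
    assert regions.intervals == expected["regions"]
    # mutated at 5% divergence the map is still collinear
    protein2, expected2 = _protein_for(MotifPlan(cys_loop_gap=14), seed=3)
    regions2 = anchor_regions(protein2)
    assert regions2.intervals["cys_loop"] == expected2["regions"]["cys_loop"]
    assert regions2.intervals["tm2"] == expected2["regions"]["tm2"]


def test_achbp_like_has_no_tm_regions():
    protein, _ = _protein_for(MotifPlan(tm_count=0, cys_loop_gap=16))
    regions = anchor_regions(protein)
    assert regions.tm_count() == 0
    assert "loop_C" in regions.intervals
    assert "loop_A" in regions.intervals


def test_random_protein_is_unanchorable(rng):
    junk = "".join("ACDEFGHIKLNPQRSTVWY"[i]
                   for i in rng.integers(0, 19, 350))
    with pytest.raises(AnchorError):
        anchor_regions(junk)
    assert annotate(junk, id="junk").class_call == "ambiguous"


def test_nterm_extension_shifts_regions_uniformly():
    protein, _ = _protein_for(MotifPlan(), seed=5)
    base = anchor_regions(protein)
    extended = anchor_regions("GSTNQ" + protein)
    for name, (s, e) in base.intervals.items():
        assert extended.intervals[name] == (s + 5, e + 5)


# ---------------------------------------------------------------------------
# Cys-loop span and loop C

@pytest.mark.parametrize("gap", [12, 13, 14, 16])
def test_cys_loop_span_recovers_planted_gap(gap):
    plan = MotifPlan(cys_loop_gap=gap, tm_count=4)
    protein, _ = _protein_for(plan, seed=gap)
    regions = anchor_regions(protein)
    assert cys_loop_span(protein, regions) == gap


def test_cysteine_free_protein_has_no_span():
    prof = default_profile()
    protein = prof.sequence.replace("C", "S")
    regions = anchor_regions(protein, prof)
    assert cys_loop_span(protein, regions) is None


# ---------------------------------------------------------------------------
# Prime numbering and selectivity

def test_prime_numbering_par_motif():
    protein, _ = _protein_for(MotifPlan(), seed=11)
    regions = anchor_regions(protein)
    pm = prime_numbering(protein, regions)
    assert pm.residue(-2) == "P"
    assert pm.residue(-1) == "A"
    assert pm.residue(0) == "R"
    # contiguity: residue at k' sits at pos(0') + k
    pos0 = pm.positions[0][1]
    for k, (res, pos) in pm.positions.items():
        assert pos == pos0 + k
        assert protein[pos] == res


def test_prime_map_matches_plan():
    overrides = {-2: "S", -1: "E", 0: "Q", 2: "S", 13: "V", 20: "E"}
    protein, expected = _protein_for(
        MotifPlan(tm2_prime_residues=overrides), seed=13)
    pm = prime_numbering(protein, anchor_regions(protein))
    assert pm.residues() == expected["tm2_primes"]


@pytest.mark.parametrize("primes,expected", [
    ({-2: "P", -1: "A", 0: "R", 20: "S"}, "anion"),     # PAR subunit
    ({-2: "S", -1: "E", 0: "Q", 20: "E"}, "cation"),    # nACh filters
    ({-2: "S", -1: "K", 0: "R", 20: "S"}, "atypical"),  # basic -1'
    ({-2: "P", -1: "A", 0: "K", 20: "S"}, "anion"),     # K at 0' accepted
])
def test_selectivity_rules(primes, expected):
    assert selectivity_from_primes(primes)[0] == expected


def test_lysine_at_zero_prime_warns():
    sel, warns = selectivity_from_primes({-1: "A", 0: "K"})
    assert sel == "anion" and warns


# ---------------------------------------------------------------------------
# Pharmacology flags

def test_pharmacology_flags_on_reference():
    prof = default_profile()
    protein = prof.sequence
    regions = anchor_regions(protein, prof)
    pm = prime_numbering(protein, regions)
    flags = pharmacology_flags(pm, regions, protein)
    assert flags == {"dieldrin_site": True, "fipronil_site": True,
                     "picrotoxin_site": True, "ivermectin_site": True}


def test_dieldrin_resistance_mutation_clears_flags():
    """The 2' alanine-to-serine substitution abolishes the dieldrin site."""
    protein, _ = _protein_for(MotifPlan(tm2_prime_residues={2: "S"}), seed=17)
    rep = annotate(protein)
    assert rep.flags["dieldrin_site"] is False
    assert rep.flags["fipronil_site"] is False
    assert rep.flags["picrotoxin_site"] is False  # picrotoxin needs A2' too
    assert rep.flags["ivermectin_site"] is True   # TM3 glycine untouched


def test_ivermectin_needs_tm3_glycine():
    prof = default_profile()
    seq = list(prof.sequence)
    seq[scaffold.TM3_G_POS] = "A"
    protein = "".join(seq)
    rep = annotate(protein)
    assert rep.flags["ivermectin_site"] is False
    assert rep.flags["dieldrin_site"] is True


# ---------------------------------------------------------------------------
# Classification

def test_classify_planted_archetypes():
    cases = [
        (MotifPlan(), "anion_subunit"),
        (MotifPlan(vicinal_cc=True,
                   tm2_prime_residues={-2: "S", -1: "E", 0: "Q", 20: "E"}),
         "alpha_nACh"),
        (MotifPlan(vicinal_cc=False,
                   tm2_prime_residues={-2: "S", -1: "E", 0: "Q", 20: "E"}),
         "non_alpha_nACh"),
        (MotifPlan(tm_count=0, cys_loop_gap=16), "AChBP_like"),
        (MotifPlan(tm2_prime_residues={-1: "K", 20: "S"}), "ambiguous"),
    ]
    for seed, (plan, expected_class) in enumerate(cases):
        protein, _ = _protein_for(plan, seed=seed)
        assert annotate(protein).class_call == expected_class


def test_rule_table_is_total():
    """Every feature combination maps to exactly one class call."""
    for tm, cc, sel in itertools.product(
            (0, 4), (False, True), ("anion", "cation", "atypical", None)):
        call = class_from_features(tm, cc, sel)
        assert call in {"alpha_nACh", "non_alpha_nACh", "AChBP_like",
                        "anion_subunit", "cation_subunit", "ambiguous"}
    # and the field's classification rules in particular
    assert class_from_features(4, True, "cation") == "alpha_nACh"
    assert class_from_features(4, False, "cation") == "non_alpha_nACh"
    assert class_from_features(0, False, None) == "AChBP_like"
    assert class_from_features(4, False, "anion") == "anion_subunit"


def test_par_motif_implies_not_cation():
    for seed in range(6):
        plan = random_motif_plan(np.random.default_rng(seed))
        if plan.tm_count == 0:
            continue
        protein, _ = _protein_for(plan, seed=seed)
        rep = annotate(protein)
        if rep.par_motif:
            assert rep.selectivity != "cation"


# ---------------------------------------------------------------------------
# Composite recovery and serialization

def test_planted_report_fields_recovered(rng):
    """Batch recovery of every planted motif field over random plans."""
    for k in range(15):
        plan = random_motif_plan(rng)
        protein, expected = _protein_for(plan, seed=1000 + k)
        rep = annotate(protein, id=f"p{k}")
        got = {
            "cys_loop_gap": rep.cys_loop_gap,
            "vicinal_cc_loop_c": rep.vicinal_cc_loop_c,
            "second_cys_loop": rep.second_cys_loop,
            "tm_count": rep.tm_count,
            "class_call": rep.class_call,
            "par_motif": rep.par_motif,
            "selectivity": rep.selectivity,
            "flags": rep.flags or None,
        }
        want = {key: expected[key] for key in got}
        if expected["tm_count"] == 0:
            got["flags"] = None
        assert got == want, f"plan {k}: {plan}"


def test_second_cys_loop_detection():
    protein, _ = _protein_for(MotifPlan(second_cys_loop=True), seed=23)
    rep = annotate(protein)
    assert rep.second_cys_loop is True
    assert rep.vicinal_cc_loop_c is False
    both, _ = _protein_for(MotifPlan(second_cys_loop=True, vicinal_cc=True),
                           seed=24)
    rep2 = annotate(both)
    assert rep2.second_cys_loop is True
    assert rep2.vicinal_cc_loop_c is True


def test_report_round_trips_through_json():
    protein, _ = _protein_for(MotifPlan(vicinal_cc=True), seed=29)
    rep = annotate(protein, id="x")
    back = MotifReport.from_dict(json.loads(rep.to_json()))
    assert back == rep
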