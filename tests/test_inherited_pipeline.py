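"""Inherited-variant calling: mode filters, compound hets, classification."""

from __future__ import annotations

import copy

import pytest

from pretermasd import inherited_pipeline as ip
from pretermasd.cohort_io import HET, HOM_ALT, HOM_REF, GenePanelEntry
from pretermasd.dnv_pipeline import apply_qc_cascade, build_parent_carrier_index, detect_candidates
from pretermasd.inherited_pipeline import (
    call_inherited,
    classify_dominant,
    extract_panel_variants,
    filter_inherited,
    scan_compound_het,
)

from conftest import make_record

PANEL = [
    GenePanelEntry("DOM1", "dominant"),
    GenePanelEntry("REC1", "recessive"),
    GenePanelEntry("UNK1", "unannotated"),
]
MODES = {"DOM1": "dominant", "REC1": "recessive"}


def _dom(pos=1000, **kw):
    kw.setdefault("gene", "DOM1")
    kw.setdefault("mother_gt", HET)
    kw.setdefault("popmax_af", 0.0005)
    return make_record(pos=pos, **kw)


def _rec(pos=2000, **kw):
    kw.setdefault("gene", "REC1")
    kw.setdefault("child_gt", HOM_ALT)
    kw.setdefault("mother_gt", HET)
    kw.setdefault("father_gt", HET)
    kw.setdefault("popmax_af", 0.005)
    return make_record(pos=pos, **kw)


def test_extract_drops_non_panel_and_unannotated_genes():
    records = {
        "c": [
            make_record(gene="ELSEWHERE"),
            make_record(pos=2, gene="UNK1"),
            make_record(pos=3, gene="DOM1"),
            make_record(pos=4, gene=None),
        ]
    }
    kept, n_unannotated = extract_panel_variants(records, PANEL)
    assert [r.gene for r in kept["c"]] == ["DOM1"]
    assert n_unannotated == 1


@pytest.mark.parametrize(
    "gene,af,expected_kept",
    [
        ("DOM1", 0.0005, True),
        ("DOM1", 0.005, False),  # above the dominant threshold
        ("REC1", 0.005, True),  # below the recessive threshold
        ("REC1", 0.02, False),
    ],
)
def test_af_thresholds_by_mode(gene, af, expected_kept):
    if gene == "DOM1":
        rec = _dom(popmax_af=af)
    else:
        rec = _rec(popmax_af=af)
    calls = filter_inherited({"c": [rec]}, MODES)
    assert bool(calls) == expected_kept


def test_genotype_mode_consistency():
    # dominant: child het with a carrier parent; hom-alt child is inconsistent
    assert filter_inherited({"c": [_dom()]}, MODES)
    assert not filter_inherited({"c": [_dom(child_gt=HOM_ALT)]}, MODES)
    # de novo configuration is not inherited
    assert not filter_inherited({"c": [_dom(mother_gt=HOM_REF)]}, MODES)
    # recessive hom-alt needs both parents carriers
    assert filter_inherited({"c": [_rec()]}, MODES)
    assert not filter_inherited({"c": [_rec(father_gt=HOM_REF)]}, MODES)


def test_quality_applies_to_transmitting_parent():
    bad_mother = _dom(gq={"child": 50, "mother": 19, "father": 50})
    assert not filter_inherited({"c": [bad_mother]}, MODES)
    # non-transmitting parent quality is irrelevant
    bad_father = _dom(gq={"child": 50, "mother": 50, "father": 5})
    assert filter_inherited({"c": [bad_father]}, MODES)


def test_compound_het_pairing_by_transmission():
    maternal = _rec(pos=100, child_gt=HET, mother_gt=HET, father_gt=HOM_REF)
    paternal = _rec(pos=200, child_gt=HET, mother_gt=HOM_REF, father_gt=HET)
    calls = scan_compound_het(filter_inherited({"c": [maternal, paternal]}, MODES))
    assert len(calls) == 2
    partners = {c.variant_id: c.compound_het_partner for c in calls}
    assert partners[maternal.variant_id] == paternal.variant_id
    assert partners[paternal.variant_id] == maternal.variant_id


def test_cis_hets_do_not_pair():
    a = _rec(pos=100, child_gt=HET, mother_gt=HET, father_gt=HOM_REF)
    b = _rec(pos=200, child_gt=HET, mother_gt=HET, father_gt=HOM_REF)
    assert scan_compound_het(filter_inherited({"c": [a, b]}, MODES)) == []


def test_single_het_and_unphaseable_dropped():
    single = _rec(pos=100, child_gt=HET, mother_gt=HET, father_gt=HOM_REF)
    assert scan_compound_het(filter_inherited({"c": [single]}, MODES)) == []
    ambiguous = _rec(pos=300, child_gt=HET, mother_gt=HET, father_gt=HET)
    paternal = _rec(pos=400, child_gt=HET, mother_gt=HOM_REF, father_gt=HET)
    calls = filter_inherited({"c": [ambiguous, paternal]}, MODES)
    assert any(c.unphaseable for c in calls)
    assert scan_compound_het(calls) == []


@pytest.mark.parametrize(
    "kw,damaging",
    [
        (dict(cadd=25.0), True),
        (dict(cadd=20.0), True),  # inclusive boundary
        (dict(cadd=19.9), False),
        (dict(sift="D"), True),
        (dict(sift="T"), False),
        (dict(polyphen="P"), True),
        (dict(polyphen="D"), True),
        (dict(polyphen="B"), False),
        (dict(phylop=2.0), True),
        (dict(revel=0.5), True),
        (dict(revel=0.49), False),
        (dict(), False),  # all scores missing
    ],
)
def test_damaging_missense_composite_rule(kw, damaging):
    rec = _dom(consequence_terms=frozenset({"missense_variant"}), **kw)
    call = classify_dominant(filter_inherited({"c": [rec]}, MODES)[0])
    assert ("damaging_missense" in call.classes) == damaging


def test_damaging_missense_requires_missense_term():
    rec = _dom(consequence_terms=frozenset({"synonymous_variant"}), cadd=30.0)
    call = classify_dominant(filter_inherited({"c": [rec]}, MODES)[0])
    assert "damaging_missense" not in call.classes


def test_lof_shared_terms():
    rec = _dom(consequence_terms=frozenset({"stop_gained"}))
    call = classify_dominant(filter_inherited({"c": [rec]}, MODES)[0])
    assert "lof" in call.classes


def test_brute_force_equivalence_small_cohort(small_cohort):
    """The pipeline recovers exactly the planted inherited variants."""
    calls = call_inherited(small_cohort.records_by_child, small_cohort.panel)
    got_dom = {(c.child_id, c.variant_id) for c in calls if c.mode == "dominant"}
    got_rec = {(c.child_id, c.variant_id) for c in calls
               if c.mode == "recessive" and not c.is_het_candidate}
    got_chet = {(c.child_id, c.variant_id) for c in calls if c.compound_het_partner}
    truth = small_cohort.truth.inherited_ids
    exp_dom = {(ch, v) for ch, d in truth.items() for v in d["dominant"]}
    exp_rec = {(ch, v) for ch, d in truth.items() for v in d["recessive"]}
    exp_chet = {(ch, v) for ch, d in truth.items() for v in d["compound_het"]}
    assert got_dom == exp_dom
    assert got_rec == exp_rec
    assert got_chet == exp_chet


def test_disjoint_with_de_novo_calls(small_cohort):
    """No (child, variant) appears in both the de novo and inherited outputs."""
    co = small_cohort
    sex = dict(zip(co.pedigree["person_id"], co.pedigree["sex"]))
    candidates = detect_candidates(co.records_by_child, child_sex=sex)
    dnv_calls, _ = apply_qc_cascade(
        candidates, build_parent_carrier_index(co.records_by_child), co.regions, sd_k=None
    )
    dnv_keys = {(c.child_id, c.variant_id) for c in dnv_calls if c.passed}
    inh_keys = {
        (c.child_id, c.variant_id)
        for c in call_inherited(co.records_by_child, co.panel)
    }
    assert not dnv_keys & inh_keys


def test_parental_swap_symmetry(small_cohort):
    """Swapping mother/father labels cohort-wide leaves the recessive call
    count unchanged (transmitted_from flips)."""
    original = call_inherited(small_cohort.records_by_child, small_cohort.panel)
    swapped_records = {}
    for child, records in small_cohort.records_by_child.items():
        swapped = []
        for rec in records:
            r = copy.copy(rec)
            r.mother_gt, r.father_gt = rec.father_gt, rec.mother_gt
            r.gq = {**rec.gq, "mother": rec.gq.get("father", 99), "father": rec.gq.get("mother", 99)}
            r.dp = {**rec.dp, "mother": rec.dp.get("father", 99), "father": rec.dp.get("mother", 99)}
            swapped.append(r)
        swapped_records[child] = swapped
    swapped_calls = call_inherited(swapped_records, small_cohort.panel)
    for mode in ("dominant", "recessive"):
        assert sum(c.mode == mode for c in original) == sum(c.mode == mode for c in swapped_calls)
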