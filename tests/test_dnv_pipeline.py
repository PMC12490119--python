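"""De novo detection and QC cascade, checked against brute-force rule logic."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pretermasd import dnv_pipeline as dp
from pretermasd.cohort_io import HET, HOM_ALT, HOM_REF, MISSING, RegionSet
from pretermasd.dnv_pipeline import (
    DeNovoCall,
    apply_qc_cascade,
    build_parent_carrier_index,
    classify_call,
    detect_candidates,
    event_rates,
    per_child_class_counts,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# candidate detection


def test_canonical_de_novo_is_candidate():
    rec = make_record(child_ad=(5, 5))
    calls = detect_candidates({"F1_C0": [rec]})
    assert len(calls) == 1 and calls[0].ab == 0.5


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(father_gt=HET),  # inherited
        dict(mother_gt=HOM_ALT),
        dict(mother_gt=MISSING),
        dict(child_gt=HOM_REF),
        dict(child_gt=HOM_ALT),  # autosomal hom-alt child cannot be de novo
        dict(child_ad=(9, 3)),  # AB exactly 0.25 fails the strict threshold
        dict(child_ad=(0, 0)),  # AB undefined
    ],
)
def test_non_candidates(kwargs):
    rec = make_record(**kwargs)
    assert detect_candidates({"F1_C0": [rec]}) == []


def test_ab_threshold_is_strict():
    at = make_record(child_ad=(9, 3))  # 0.25 exactly
    above = make_record(pos=2000, child_ad=(8, 3))  # ~0.273
    calls = detect_candidates({"F1_C0": [at, above]})
    assert [c.record.pos for c in calls] == [2000]


def test_hemizygous_male_x_needs_only_mother_hom_ref():
    rec = make_record(chrom="chrX", child_gt=HOM_ALT, father_gt=HOM_ALT, child_ad=(0, 20))
    assert detect_candidates({"F1_C0": [rec]}, child_sex={"F1_C0": "male"})
    # same genotype in a female child is not a candidate
    assert not detect_candidates({"F1_C0": [rec]}, child_sex={"F1_C0": "female"})


def test_consensus_hook_intersects_external_calls():
    rec = make_record()
    keep = {("F1_C0", rec.variant_id)}
    assert detect_candidates({"F1_C0": [rec]}, confirm_ids=keep)
    assert not detect_candidates({"F1_C0": [rec]}, confirm_ids=set())


# ---------------------------------------------------------------------------
# brute-force oracle for the cascade


def brute_force_cascade(calls, parent_index, regions, qc_scope="trio"):
    """Independent re-evaluation of every QC rule on every candidate."""
    fams = {}
    for c in calls:
        fams.setdefault(c.variant_id, set()).add(c.record.family_id)
    verdicts = []
    members = ("child", "mother", "father") if qc_scope == "trio" else ("child",)
    for c in calls:
        r = c.record
        failed = []
        if min(r.gq.get(m, 99) for m in members) < 20:
            failed.append("gq")
        if min(r.dp.get(m, 99) for m in members) < 10:
            failed.append("dp")
        if (r.popmax_af or 0.0) > 0.001:
            failed.append("af")
        if "A" * 10 in r.ref or "A" * 10 in r.alt or "T" * 10 in r.ref or "T" * 10 in r.alt:
            failed.append("homopolymer")
        if regions is not None and regions.contains(r.chrom, r.pos - 1):
            failed.append("region")
        if parent_index.get(c.variant_id, set()) - {r.family_id}:
            failed.append("other_family_parent")
        if len(fams[c.variant_id]) > 3:
            failed.append("recurrent_children")
        if r.n_alt_alleles_at_site > 3:
            failed.append("multiallelic")
        verdicts.append(failed)
    return verdicts


def _random_candidates(rng, n=60):
    """Candidates with randomized filter-relevant fields, some shared across
    families to exercise the cohort-level rules."""
    calls, parent_records = [], {}
    shared = [("chr2", 50_000 + i, "A", "C") for i in range(6)]
    for i in range(n):
        fam = f"F{i % 12}"
        child = f"{fam}_C{i % 2}"
        if rng.random() < 0.3:
            chrom, pos, ref, alt = shared[int(rng.integers(len(shared)))]
        else:
            chrom, pos, ref, alt = "chr1", 1000 + i * 7, "A", "G"
        rec = make_record(
            child_id=child, family_id=fam, chrom=chrom, pos=pos, ref=ref,
            alt="T" * 10 if rng.random() < 0.1 else alt,
            gq={m: int(rng.integers(15, 60)) for m in ("child", "mother", "father")},
            dp={m: int(rng.integers(5, 40)) for m in ("child", "mother", "father")},
            popmax_af=None if rng.random() < 0.4 else float(rng.uniform(0, 0.003)),
            n_alt_alleles_at_site=int(rng.integers(1, 6)),
        )
        calls.append(DeNovoCall(record=rec, child_id=child, ab=0.5))
        if rng.random() < 0.15:  # some variants also sit in an unrelated parent
            parent_records.setdefault(rec.variant_id, set()).add(f"OTHER{i}")
    return calls, parent_records


def test_cascade_matches_brute_force(rng):
    """On a randomized candidate set, the cascade's rejection lists equal an
    independent re-check of every rule against every record."""
    regions = RegionSet([("chr1", 1100, 1200)])
    calls, parent_index = _random_candidates(rng)
    processed, _ = apply_qc_cascade(list(calls), parent_index, regions, sd_k=None)
    expected = brute_force_cascade(calls, parent_index, regions)
    assert len(processed) == len(calls)
    for call, exp in zip(processed, expected):
        assert call.rejected_by == exp


def test_audit_conservation(rng):
    """Candidates = passed + sum of first-filter rejections."""
    calls, parent_index = _random_candidates(rng, n=80)
    processed, summary = apply_qc_cascade(list(calls), parent_index, None, sd_k=None)
    n_passed = sum(c.passed for c in processed)
    assert n_passed + sum(summary.filter_counts.values()) == len(calls)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_relaxing_thresholds_never_shrinks_passing_set(seed):
    rng = np.random.default_rng(seed)
    calls, parent_index = _random_candidates(rng, n=40)
    strict, _ = apply_qc_cascade(list(calls), parent_index, None, sd_k=None)
    passing_strict = {(c.child_id, c.variant_id) for c in strict if c.passed}
    for relax in (
        dict(min_gq=10), dict(min_dp=5), dict(max_af=0.01),
        dict(max_families=10), dict(max_alt=10),
    ):
        loose, _ = apply_qc_cascade(list(calls), parent_index, None, sd_k=None, **relax)
        passing_loose = {(c.child_id, c.variant_id) for c in loose if c.passed}
        assert passing_strict <= passing_loose


def test_family_recurrence_boundary():
    """Candidates in children of exactly 3 families pass; 4 families fail."""
    def candidates(n_fams, pos):
        return [
            DeNovoCall(record=make_record(child_id=f"F{i}_C0", family_id=f"F{i}", pos=pos),
                       child_id=f"F{i}_C0", ab=0.5)
            for i in range(n_fams)
        ]

    three, _ = apply_qc_cascade(candidates(3, 5000), {}, None, sd_k=None)
    assert all(c.passed for c in three)
    four, _ = apply_qc_cascade(candidates(4, 5000), {}, None, sd_k=None)
    assert all(c.rejected_by == ["recurrent_children"] for c in four)


def test_other_family_parent_filter_uses_cross_family_carriers():
    rec = make_record()
    call = DeNovoCall(record=rec, child_id="F1_C0", ab=0.5)
    # carrier parent in the candidate's own family does not reject
    own, _ = apply_qc_cascade([call], {rec.variant_id: {"F1"}}, None, sd_k=None)
    assert own[0].passed
    call2 = DeNovoCall(record=make_record(), child_id="F1_C0", ab=0.5)
    other, _ = apply_qc_cascade([call2], {rec.variant_id: {"F9"}}, None, sd_k=None)
    assert other[0].rejected_by == ["other_family_parent"]


def test_outlier_children_excluded_two_sided():
    calls = []
    for i in range(30):
        child = f"F{i}_C0"
        for j in range(5):
            calls.append(DeNovoCall(record=make_record(child_id=child, family_id=f"F{i}",
                                                       pos=10_000 + 100 * i + j),
                                    child_id=child, ab=0.5))
    for j in range(60):  # one child with an extreme count
        calls.append(DeNovoCall(record=make_record(child_id="F99_C0", family_id="F99",
                                                   pos=90_000 + j),
                                child_id="F99_C0", ab=0.5))
    kept, summary = apply_qc_cascade(calls, {}, None)
    assert summary.excluded_children == ["F99_C0"]
    assert all(c.child_id != "F99_C0" for c in kept)


def test_parent_carrier_index(small_cohort):
    index = build_parent_carrier_index(small_cohort.records_by_child)
    # every inherited variant's family is indexed under that variant
    for child, classes in small_cohort.truth.inherited_ids.items():
        fam = child.split("_")[0]
        for vid in classes["dominant"]:
            assert fam in index[vid]


# ---------------------------------------------------------------------------
# classification and rates


@pytest.mark.parametrize(
    "terms,lof",
    [
        ({"stop_gained"}, True),
        ({"frameshift_variant"}, True),
        ({"splice_acceptor_variant"}, True),
        ({"missense_variant"}, False),
        ({"synonymous_variant", "stop_lost"}, True),
    ],
)
def test_lof_classification(terms, lof):
    call = DeNovoCall(record=make_record(consequence_terms=frozenset(terms), is_exonic=True,
                                         gene="NDD0001"),
                      child_id="F1_C0", ab=0.5)
    classify_call(call, {"NDD0001": "dominant"})
    assert ("lof" in call.classes) == lof
    assert "ndd_gene" in call.classes
    assert ("lof_ndd" in call.classes) == lof


def test_lof_ndd_requires_both():
    call = DeNovoCall(record=make_record(consequence_terms=frozenset({"stop_gained"}),
                                         gene="NOT_IN_PANEL"),
                      child_id="F1_C0", ab=0.5)
    classify_call(call, {"NDD0001": "dominant"})
    assert call.classes == {"lof"}


def test_event_rates_arithmetic():
    import pandas as pd

    calls = []
    for child, n in (("c1", 2), ("c2", 4), ("c3", 6)):
        for j in range(n):
            calls.append(DeNovoCall(record=make_record(child_id=child, family_id=child,
                                                       pos=1000 + 50 * j),
                                    child_id=child, ab=0.5))
    cohort = pd.DataFrame({"person_id": ["c1", "c2", "c3"], "group": ["g"] * 3})
    summary = event_rates(calls, cohort)
    assert summary.group_means["g"] == pytest.approx(4.0)
    assert summary.group_ses["g"] == pytest.approx(2.0 / np.sqrt(3))


def test_event_rates_counts_zero_children():
    import pandas as pd

    calls = [DeNovoCall(record=make_record(child_id="c1", family_id="c1"), child_id="c1", ab=0.5)]
    cohort = pd.DataFrame({"person_id": ["c1", "c2"], "group": ["g", "g"]})
    summary = event_rates(calls, cohort)
    assert summary.group_means["g"] == pytest.approx(0.5)


def test_planted_artifacts_rejected_by_intended_filter(small_cohort):
    """Every planted artifact is rejected by exactly the filter it spoofs;
    no clean planted de novo is rejected."""
    co = small_cohort
    sex = dict(zip(co.pedigree["person_id"], co.pedigree["sex"]))
    candidates = detect_candidates(co.records_by_child, child_sex=sex)
    index = build_parent_carrier_index(co.records_by_child)
    calls, _ = apply_qc_cascade(candidates, index, co.regions, sd_k=None)
    by_key = {(c.child_id, c.variant_id): c for c in calls}
    for art in co.truth.artifacts:
        call = by_key[(art["child_id"], art["variant_id"])]
        assert call.rejected_by and call.rejected_by[0] == art["expected_filter"]
    for child, vids in co.truth.true_dnv_ids.items():
        for vid in vids:
            assert by_key[(child, vid)].passed
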