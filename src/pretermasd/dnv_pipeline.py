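"""De novo variant detection and the quality-control cascade.

A candidate de novo variant (DNV) is a Mendelian violation: the child
carries an allele present in neither parent. Candidates are detected from
trio genotypes and allele balance, then passed through an ordered cascade of
eight rejection filters (genotype quality, depth, population allele
frequency, homopolymer alleles, excluded regions, cross-family parental
presence, recurrence across families, multiallelic excess), and finally
children with outlying DNV counts are dropped entirely.

Filter order is fixed so per-filter audit counts are reproducible; a call's
``rejected_by`` lists every failing filter in cascade order, and audit
counts attribute each rejection to the first failing filter.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenePanelEntry,
    RegionSet,
    TrioVariantRecord,
    panel_mode_map,
)

logger = logging.getLogger(__name__)

#: Sequence Ontology consequence terms counted as loss-of-function.
LOF_TERMS = frozenset(
    ["frameshift", "splice_acceptor", "splice_donor", "start_lost", "stop_gained", "stop_lost"]
)

FILTER_ORDER = (
    "gq",
    "dp",
    "af",
    "homopolymer",
    "region",
    "other_family_parent",
    "recurrent_children",
    "multiallelic",
)

MIN_GQ = 20
MIN_DP = 10
MAX_POPMAX_AF = 0.001
HOMOPOLYMER_RUN = 10
MAX_FAMILIES_WITH_CANDIDATE = 3
MAX_ALT_ALLELES = 3
AB_THRESHOLD = 0.25

_HOMOPOLYMER_RE = re.compile(r"A{%d}|T{%d}" % (HOMOPOLYMER_RUN, HOMOPOLYMER_RUN))


@dataclass
class DeNovoCall:
    record: TrioVariantRecord
    child_id: str
    ab: float
    rejected_by: list[str] = field(default_factory=list)
    classes: set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.rejected_by

    @property
    def variant_id(self) -> str:
        return self.record.variant_id


@dataclass
class DNVSummary:
    per_child_counts: dict[str, int]
    group_means: dict[str, float]
    group_ses: dict[str, float]
    group_ns: dict[str, int]
    excluded_children: list[str] = field(default_factory=list)
    filter_counts: dict[str, int] = field(default_factory=dict)


def is_male_x(record: TrioVariantRecord, child_sex: str | None, par_regions: RegionSet | None = None) -> bool:
    """True for a male genotype on the non-pseudoautosomal X (hemizygous)."""
    if child_sex != "male" or record.chrom not in ("X", "chrX"):
        return False
    if par_regions is not None and par_regions.contains(record.chrom, record.pos - 1):
        return False
    return True


def detect_candidates(
    records_by_child: Mapping[str, Sequence[TrioVariantRecord]],
    child_sex: Mapping[str, str] | None = None,
    par_regions: RegionSet | None = None,
    confirm_ids: set[str] | None = None,
) -> list[DeNovoCall]:
    """Detect candidate de novo variants from trio genotypes.

    A candidate requires child het (or hom-alt on the hemizygous male X),
    both parents hom-ref (mother only on the male X), and child allele
    balance strictly above 0.25. Records with missing or carrier parent
    genotypes, or undefined allele balance (zero informative depth), are
    not candidates.

    ``confirm_ids`` optionally intersects with an external caller's
    (child_id, variant_id) set, mirroring two-caller consensus calling;
    when None, the rule set above is the single caller.
    """
    child_sex = child_sex or {}
    calls: list[DeNovoCall] = []
    for child, records in records_by_child.items():
        for rec in records:
            hemi = is_male_x(rec, child_sex.get(child), par_regions)
            if hemi:
                if rec.child_gt not in (HET, HOM_ALT):
                    continue
                if rec.mother_gt != HOM_REF:
                    continue
            else:
                if rec.child_gt != HET:
                    continue
                if rec.mother_gt != HOM_REF or rec.father_gt != HOM_REF:
                    continue
            ab = rec.allele_balance
            if ab is None:
                logger.debug("candidate %s in %s dropped: allele balance undefined", rec.variant_id, child)
                continue
            if not ab > AB_THRESHOLD:
                continue
            if confirm_ids is not None and (child, rec.variant_id) not in confirm_ids:
                continue
            calls.append(DeNovoCall(record=rec, child_id=child, ab=ab))
    return calls


def has_homopolymer_allele(record: TrioVariantRecord) -> bool:
    """Run of >= 10 consecutive A or T within the REF or ALT allele string."""
    return bool(_HOMOPOLYMER_RE.search(record.ref) or _HOMOPOLYMER_RE.search(record.alt))


def build_parent_carrier_index(
    records_by_child: Mapping[str, Sequence[TrioVariantRecord]],
) -> dict[str, set[str]]:
    """variant_id -> set of family_ids with a non-hom-ref parent genotype."""
    index: dict[str, set[str]] = defaultdict(set)
    for records in records_by_child.values():
        for rec in records:
            for gt in (rec.mother_gt, rec.father_gt):
                if gt in (HET, HOM_ALT):
                    index[rec.variant_id].add(rec.family_id)
    return dict(index)


def apply_qc_cascade(
    calls: Sequence[DeNovoCall],
    parent_carrier_families: Mapping[str, set[str]] | None = None,
    regions: RegionSet | None = None,
    sd_k: float = 3.0,
    qc_scope: str = "trio",
    all_children: Iterable[str] | None = None,
    min_gq: int = MIN_GQ,
    min_dp: int = MIN_DP,
    max_af: float = MAX_POPMAX_AF,
    max_families: int = MAX_FAMILIES_WITH_CANDIDATE,
    max_alt: int = MAX_ALT_ALLELES,
) -> tuple[list[DeNovoCall], DNVSummary]:
    """Apply the ordered QC cascade and outlier exclusion to candidates.

    Filters, in order: (1) GQ >= 20, (2) DP >= 10 (both over the whole trio
    by default, or child only with ``qc_scope='child'``), (3) population
    allele frequency <= 0.001 (absent frequency counts as 0, i.e. novel),
    (4) no run of >= 10 A or T in REF/ALT, (5) not inside the excluded
    region set, (6) not carried by a parent of another family, (7) not a
    candidate in children of more than three distinct families, (8) at most
    3 ALT alleles at the site. Afterwards, children whose passing count
    lies beyond ``sd_k`` standard deviations from the cohort mean (either
    side) are excluded entirely.

    Returns the calls (with ``rejected_by`` populated; excluded children's
    calls removed) and an audit summary whose per-filter counts attribute
    each rejected call to its first failing filter.
    """
    if qc_scope not in ("trio", "child"):
        raise ValueError("qc_scope must be 'trio' or 'child'")
    parent_carrier_families = parent_carrier_families or {}

    # family recurrence among candidates is a cohort-level property
    families_with_candidate: dict[str, set[str]] = defaultdict(set)
    for call in calls:
        families_with_candidate[call.variant_id].add(call.record.family_id)

    members = ("child", "mother", "father") if qc_scope == "trio" else ("child",)
    for call in calls:
        rec = call.record
        rejected: list[str] = []
        gq_vals = [rec.gq.get(m) for m in members]
        if any(v is not None and v < min_gq for v in gq_vals):
            rejected.append("gq")
        dp_vals = [rec.dp.get(m) for m in members]
        if any(v is not None and v < min_dp for v in dp_vals):
            rejected.append("dp")
        af = rec.popmax_af if rec.popmax_af is not None else 0.0
        if af > max_af:
            rejected.append("af")
        if has_homopolymer_allele(rec):
            rejected.append("homopolymer")
        if regions is not None and regions.contains(rec.chrom, rec.pos - 1):
            rejected.append("region")
        other = parent_carrier_families.get(call.variant_id, set()) - {rec.family_id}
        if other:
            rejected.append("other_family_parent")
        if len(families_with_candidate[call.variant_id]) > max_families:
            rejected.append("recurrent_children")
        if rec.n_alt_alleles_at_site > max_alt:
            rejected.append("multiallelic")
        call.rejected_by = rejected

    filter_counts = Counter(call.rejected_by[0] for call in calls if call.rejected_by)

    # outlier exclusion on per-child passing counts (children with zero
    # passing calls participate with count 0 when the cohort is supplied)
    counts: Counter[str] = Counter(call.child_id for call in calls if call.passed)
    if all_children is not None:
        for child in all_children:
            counts.setdefault(child, 0)
    else:
        for call in calls:
            counts.setdefault(call.child_id, 0)
    excluded: list[str] = []
    if len(counts) >= 2 and sd_k is not None:
        values = np.array(list(counts.values()), dtype=float)
        mean, sd = values.mean(), values.std(ddof=1)
        if sd > 0:
            lo, hi = mean - sd_k * sd, mean + sd_k * sd
            excluded = sorted(c for c, n in counts.items() if n < lo or n > hi)
    kept = [call for call in calls if call.child_id not in set(excluded)]
    per_child = {c: n for c, n in counts.items() if c not in set(excluded)}
    summary = DNVSummary(
        per_child_counts=per_child,
        group_means={},
        group_ses={},
        group_ns={},
        excluded_children=excluded,
        filter_counts=dict(filter_counts),
    )
    return kept, summary


def classify_call(call: DeNovoCall, panel: Sequence[GenePanelEntry] | Mapping[str, str]) -> DeNovoCall:
    """Attach variant classes: exonic, lof, ndd_gene, lof_ndd.

    A call is LOF when any of its consequence terms (with an optional
    ``_variant`` suffix stripped) is one of the six loss-of-function
    Sequence Ontology terms; ndd_gene when its gene is in the panel; and
    lof_ndd when both hold.
    """
    modes = panel if isinstance(panel, Mapping) else panel_mode_map(panel)
    rec = call.record
    classes = set()
    if rec.is_exonic:
        classes.add("exonic")
    terms = {t.removesuffix("_variant") for t in rec.consequence_terms}
    if terms & LOF_TERMS:
        classes.add("lof")
    if rec.gene is not None and rec.gene in modes:
        classes.add("ndd_gene")
    if "lof" in classes and "ndd_gene" in classes:
        classes.add("lof_ndd")
    call.classes = classes
    return call


def per_child_class_counts(
    calls: Sequence[DeNovoCall],
    children: Iterable[str],
    class_filter: str | None = None,
) -> pd.Series:
    """Passing-call count per child, restricted to one class when given."""
    counts = Counter(
        call.child_id
        for call in calls
        if call.passed and (class_filter is None or class_filter in call.classes)
    )
    children = list(children)
    return pd.Series([counts.get(c, 0) for c in children], index=children, dtype=int, name="count")


def event_rates(
    calls: Sequence[DeNovoCall],
    cohort: pd.DataFrame,
    group_col: str = "group",
    class_filter: str | None = None,
) -> DNVSummary:
    """Per-group mean DNV count per child with its standard error (sd/sqrt n).

    ``cohort`` needs person_id and the grouping column; every child in the
    cohort contributes a count (zero when it has no passing calls).
    """
    counts = per_child_class_counts(calls, cohort["person_id"], class_filter)
    means, ses, ns = {}, {}, {}
    for group, sub in cohort.groupby(group_col):
        vals = counts.loc[sub["person_id"]].to_numpy(dtype=float)
        if len(vals) == 0:
            logger.warning("group %s is empty; rate reported as missing", group)
            means[group] = math.nan
            ses[group] = math.nan
            ns[group] = 0
            continue
        means[group] = float(vals.mean())
        ses[group] = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
        ns[group] = int(len(vals))
    return DNVSummary(
        per_child_counts=counts.to_dict(),
        group_means=means,
        group_ses=ses,
        group_ns=ns,
    )
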