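"""Rare inherited variant identification in NDD panel genes.

Variants in genes with an annotated dominant or recessive inheritance mode
are filtered by mode-specific allele-frequency thresholds, genotype
quality, and genotype-mode consistency, then classified. Recessive-gene
heterozygotes are screened for compound heterozygosity by transmission
phasing: two hets in the same recessive gene in one child, one inherited
from each parent.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .cohort_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    GenePanelEntry,
    TrioVariantRecord,
    panel_mode_map,
)
from .dnv_pipeline import LOF_TERMS, MIN_DP, MIN_GQ

logger = logging.getLogger(__name__)

#: mode-specific population allele-frequency ceilings
AF_THRESHOLD = {"dominant": 0.001, "recessive": 0.01}

CADD_DAMAGING = 20.0
PHYLOP_DAMAGING = 2.0
REVEL_DAMAGING = 0.5


@dataclass
class InheritedCall:
    record: TrioVariantRecord
    child_id: str
    mode: str  # dominant | recessive
    transmitted_from: str  # mother | father | both
    classes: set[str] = field(default_factory=set)
    compound_het_partner: str | None = None
    unphaseable: bool = False
    is_het_candidate: bool = False  # recessive-gene het awaiting the compound scan

    @property
    def variant_id(self) -> str:
        return self.record.variant_id


def extract_panel_variants(
    records_by_child: Mapping[str, Sequence[TrioVariantRecord]],
    panel: Sequence[GenePanelEntry],
) -> tuple[dict[str, list[TrioVariantRecord]], int]:
    """Keep records in panel genes with a usable inheritance mode.

    Returns the filtered per-child records and the count of records dropped
    because their panel gene has no dominant/recessive annotation.
    """
    modes = panel_mode_map(panel)
    out: dict[str, list[TrioVariantRecord]] = {}
    n_unannotated = 0
    for child, records in records_by_child.items():
        kept = []
        for rec in records:
            mode = modes.get(rec.gene) if rec.gene is not None else None
            if mode in ("dominant", "recessive"):
                kept.append(rec)
            elif mode == "unannotated":
                n_unannotated += 1
        out[child] = kept
    if n_unannotated:
        logger.info("dropped %d records in panel genes without inheritance annotation", n_unannotated)
    return out, n_unannotated


def _carrier(gt: str) -> bool:
    return gt in (HET, HOM_ALT)


def filter_inherited(
    records_by_child: Mapping[str, Sequence[TrioVariantRecord]],
    panel: Sequence[GenePanelEntry] | Mapping[str, str],
) -> list[InheritedCall]:
    """Mode-aware rarity, quality, and genotype-consistency filtering.

    Dominant genes: allele frequency <= 0.001, child het with at least one
    carrier parent. Recessive genes: allele frequency <= 0.01, child
    hom-alt with both parents carriers, or child het with a single carrier
    parent (kept as a compound-het candidate; both parents het leaves the
    origin unphaseable). GQ >= 20 and DP >= 10 are required in the child
    and every transmitting parent. A het child with two hom-ref parents is
    a de novo configuration, not an inherited call.
    """
    modes = panel if isinstance(panel, Mapping) else panel_mode_map(panel)
    calls: list[InheritedCall] = []
    for child, records in records_by_child.items():
        for rec in records:
            mode = modes.get(rec.gene) if rec.gene is not None else None
            if mode not in ("dominant", "recessive"):
                continue
            af = rec.popmax_af if rec.popmax_af is not None else 0.0
            if af > AF_THRESHOLD[mode]:
                continue
            mother_c, father_c = _carrier(rec.mother_gt), _carrier(rec.father_gt)
            call: InheritedCall | None = None
            if mode == "dominant":
                if rec.child_gt == HET and (mother_c or father_c):
                    origin = "both" if (mother_c and father_c) else ("mother" if mother_c else "father")
                    call = InheritedCall(rec, child, mode, origin)
            else:  # recessive
                if rec.child_gt == HOM_ALT and mother_c and father_c:
                    call = InheritedCall(rec, child, mode, "both")
                elif rec.child_gt == HET and (mother_c or father_c):
                    if mother_c and father_c:
                        call = InheritedCall(rec, child, mode, "both", unphaseable=True,
                                             is_het_candidate=True)
                    else:
                        origin = "mother" if mother_c else "father"
                        call = InheritedCall(rec, child, mode, origin, is_het_candidate=True)
            if call is None:
                continue
            if not _passes_quality(rec, call.transmitted_from):
                continue
            calls.append(call)
    return calls


def _passes_quality(rec: TrioVariantRecord, transmitted_from: str) -> bool:
    members = ["child"]
    if transmitted_from == "both":
        members += ["mother", "father"]
    else:
        members.append(transmitted_from)
    for m in members:
        gq, dp = rec.gq.get(m), rec.dp.get(m)
        if gq is not None and gq < MIN_GQ:
            return False
        if dp is not None and dp < MIN_DP:
            return False
    return True


def scan_compound_het(calls: Sequence[InheritedCall]) -> list[InheritedCall]:
    """Resolve recessive-gene het candidates into compound-het pairs.

    Hets in the same recessive gene of one child with opposite parental
    origin are flagged as partners; unphaseable hets (both parents het) are
    excluded from pairing; unpartnered hets are dropped from the recessive
    call set. Dominant calls and recessive hom-alt calls pass through.
    """
    by_gene: dict[tuple[str, str], list[InheritedCall]] = defaultdict(list)
    out: list[InheritedCall] = []
    for call in calls:
        if call.mode == "recessive" and call.is_het_candidate:
            by_gene[(call.child_id, call.record.gene or "")].append(call)
        else:
            out.append(call)
    for group in by_gene.values():
        maternal = [c for c in group if not c.unphaseable and c.transmitted_from == "mother"]
        paternal = [c for c in group if not c.unphaseable and c.transmitted_from == "father"]
        if maternal and paternal:
            for c in maternal:
                c.compound_het_partner = paternal[0].variant_id
            for c in paternal:
                c.compound_het_partner = maternal[0].variant_id
            out.extend(maternal + paternal)
        # cis pairs, singletons, and unphaseable hets drop out here
    return out


def _is_missense(rec: TrioVariantRecord) -> bool:
    return any("missense" in t for t in rec.consequence_terms)


def classify_dominant(call: InheritedCall) -> InheritedCall:
    """Classify a dominant-gene call as LOF and/or damaging missense.

    Damaging missense requires a missense consequence plus at least one of
    CADD >= 20, SIFT D, PolyPhen in {P, D}, PhyloP >= 2.0, or REVEL >= 0.5;
    a missing score never satisfies its condition.
    """
    if call.mode != "dominant":
        return call
    rec = call.record
    classes = set()
    terms = {t.removesuffix("_variant") for t in rec.consequence_terms}
    if terms & LOF_TERMS:
        classes.add("lof")
    if _is_missense(rec):
        damaging = (
            (rec.cadd is not None and rec.cadd >= CADD_DAMAGING)
            or rec.sift == "D"
            or rec.polyphen in ("P", "D")
            or (rec.phylop is not None and rec.phylop >= PHYLOP_DAMAGING)
            or (rec.revel is not None and rec.revel >= REVEL_DAMAGING)
        )
        if damaging:
            classes.add("damaging_missense")
    call.classes = classes
    return call


def call_inherited(
    records_by_child: Mapping[str, Sequence[TrioVariantRecord]],
    panel: Sequence[GenePanelEntry],
) -> list[InheritedCall]:
    """Full inherited-variant pipeline: extract, filter, compound scan, classify."""
    panel_records, _ = extract_panel_variants(records_by_child, panel)
    calls = filter_inherited(panel_records, panel)
    calls = scan_compound_het(calls)
    return [classify_dominant(c) for c in calls]
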