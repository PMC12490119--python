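"""Synthetic family-cohort generator.

Generates multi-child families with trio genotypes, gestational age with
the four preterm strata, ASD status from a logistic liability (sex,
preterm birth, polygenic score, optional preterm x PRS interaction, plus a
family-shared random intercept that induces genuine within-family
correlation for the clustered models), per-child de novo variant counts
from a Poisson model with a configurable ASD-preterm rate ratio, nine
diagnostic categories with ASD- and prematurity-dependent prevalence,
quantitative measures, inherited variants in a dominant/recessive gene
panel, and per-SNP polygenic weights with binomial genotypes.

Known candidate-level sequencing artifacts can be planted on top of the
clean truth set, each violating exactly one QC filter, so the rejection
cascade can be audited filter by filter.

Defaults reflect the cohort this generator emulates: a genome-sequenced
ASD family collection with roughly 10% preterm births, a 3:1 male excess
among cases, and about 76 rare de novo variants per child of which ~3.7%
are exonic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import cohort_io
from .cohort_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    DiagnosticProfile,
    GenePanelEntry,
    RegionSet,
    TrioVariantRecord,
)

logger = logging.getLogger(__name__)

ARTIFACT_TYPES = (
    "low_gq",
    "low_dp",
    "common_af",
    "homopolymer",
    "region",
    "cross_family",
    "recurrent_child",
    "multiallelic_excess",
)

#: QC filter each artifact type must be rejected by
ARTIFACT_EXPECTED_FILTER = {
    "low_gq": "gq",
    "low_dp": "dp",
    "common_af": "af",
    "homopolymer": "homopolymer",
    "region": "region",
    "cross_family": "other_family_parent",
    "recurrent_child": "recurrent_children",
    "multiallelic_excess": "multiallelic",
}

_STRATUM_GA = {
    "extremely": (22, 27),
    "very": (28, 31),
    "moderate": (32, 33),
    "late": (34, 36),
}

_BASES = np.array(["A", "C", "G", "T"])

#: excluded intervals standing in for centromeres / low-complexity regions
DEFAULT_EXCLUDED_REGIONS = [
    ("chr1", 121_000_000, 125_000_000),
    ("chr9", 43_000_000, 45_500_000),
    ("chr16", 35_000_000, 38_000_000),
]


@dataclass
class SimConfig:
    """Generative parameters of the synthetic cohort.

    Effect sizes are on the log-odds (liability) or log-rate scale;
    ``burden_rate_ratio_asd_preterm`` multiplies the de novo rate for
    children who are both ASD and preterm. ``lof_fraction`` and
    ``ndd_fraction`` are conditional on a variant being exonic.
    """

    n_families: int = 300
    children_per_family: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.35, 3: 0.15}
    )
    preterm_rate: float = 0.10
    stratum_probs: tuple[float, float, float, float] = (0.08, 0.12, 0.14, 0.66)
    unknown_ga_rate: float = 0.06  # preterm births with missing gestational age
    term_ga_missing_rate: float = 0.10
    sex_ratio: float = 0.5  # male fraction at birth
    baseline_dnv_rate: float = 75.9
    exonic_fraction: float = 0.037
    lof_fraction: float = 0.061  # P(LOF | exonic)
    ndd_fraction: float = 0.10  # P(panel gene | exonic)
    burden_rate_ratio_asd_preterm: float = 1.5
    baseline_asd_logodds: float = -0.6
    prs_effect_logOR: float = 0.35
    preterm_effect_logOR: float = 0.9
    male_effect_logOR: float = 1.1
    interaction_logOR: float = 0.0
    family_intercept_sd: float = 0.5
    category_base_prevs: tuple[float, ...] = (0.12, 0.25, 0.10, 0.10, 0.08, 0.12, 0.08, 0.10, 0.12)
    category_preterm_logOR: tuple[float, ...] = (0.3, 0.4, 0.2, 0.7, 0.8, 0.5, 0.5, 0.5, 0.2)
    category_asd_logOR: tuple[float, ...] = (1.2, 1.5, 0.8, 0.5, 0.4, 0.8, 0.6, 0.5, 0.8)
    inherited_dominant_rate: float = 43.0
    inherited_recessive_rate: float = 0.76
    compound_het_rate: float = 0.0  # none observed in the emulated cohort
    n_prs_snps: int = 200
    prs_weight_sd: float = 0.1
    artifact_rates: Mapping[str, float] = field(
        default_factory=lambda: {t: 0.02 for t in ARTIFACT_TYPES}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        probs = list(self.children_per_family.values())
        if not np.isclose(sum(probs), 1.0) or min(probs) < 0:
            raise ValueError("children_per_family probabilities must be a distribution")
        if not np.isclose(sum(self.stratum_probs), 1.0) or min(self.stratum_probs) < 0:
            raise ValueError("stratum_probs must sum to 1")
        for name in ("preterm_rate", "sex_ratio", "unknown_ga_rate", "term_ga_missing_rate",
                     "exonic_fraction", "lof_fraction", "ndd_fraction", "compound_het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for p in self.category_base_prevs:
            if not 0.0 < p < 1.0:
                raise ValueError("category_base_prevs must lie strictly in (0, 1)")
        for name, rate in self.artifact_rates.items():
            if name not in ARTIFACT_TYPES:
                raise ValueError(f"unknown artifact type {name!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"artifact rate {name} must lie in [0, 1]")
        if self.baseline_dnv_rate < 0 or self.inherited_dominant_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the cohort."""

    true_dnv_ids: dict[str, list[str]] = field(default_factory=dict)
    dnv_classes: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    inherited_ids: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    artifacts: list[dict] = field(default_factory=list)
    liability: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


@dataclass
class SyntheticCohort:
    config: SimConfig
    people: pd.DataFrame  # one row per person (children and parents)
    profiles: list[DiagnosticProfile]
    records_by_child: dict[str, list[TrioVariantRecord]]
    panel: list[GenePanelEntry]
    regions: RegionSet
    pedigree: pd.DataFrame
    prs_weights: pd.DataFrame
    dosages: pd.DataFrame
    variants_meta: pd.DataFrame
    truth: SimTruth

    @property
    def children(self) -> pd.DataFrame:
        return self.people[self.people["role"].isin(["proband", "sibling"])].reset_index(drop=True)


def _make_panel(rng: np.random.Generator) -> list[GenePanelEntry]:
    entries = []
    for i in range(60):
        entries.append(GenePanelEntry(f"NDD{i:04d}", "dominant", "panel"))
    for i in range(60, 110):
        entries.append(GenePanelEntry(f"NDD{i:04d}", "recessive", "panel"))
    for i in range(110, 120):
        entries.append(GenePanelEntry(f"NDD{i:04d}", "unannotated", "panel"))
    return entries


class _PositionAllocator:
    """Hands out unique genomic positions outside the excluded regions."""

    def __init__(self, regions: RegionSet):
        self._regions = regions
        self._chroms = [f"chr{i}" for i in range(1, 23)]
        self._next = 10_000
        self._i = 0

    def take(self, inside_region: bool = False) -> tuple[str, int]:
        if inside_region:
            chrom, start, end = DEFAULT_EXCLUDED_REGIONS[self._i % len(DEFAULT_EXCLUDED_REGIONS)]
            pos = start + 1 + (self._next % (end - start - 2))
            self._next += 97
            self._i += 1
            return chrom, pos + 1  # 1-based, inside [start, end)
        while True:
            chrom = self._chroms[self._i % len(self._chroms)]
            pos0 = self._next
            self._i += 1
            self._next += 137
            if not self._regions.contains(chrom, pos0):
                return chrom, pos0 + 1


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def simulate_people(config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the person-level cohort (no variant records).

    Returns (people, pedigree, truth, prs_weights, dosages, variants_meta).
    """
    truth = SimTruth()
    sizes = sorted(config.children_per_family)
    size_p = np.array([config.children_per_family[s] for s in sizes], dtype=float)

    rows, ped_rows = [], []
    child_ids: list[str] = []
    for f in range(config.n_families):
        fam = f"F{f:05d}"
        mother, father = f"{fam}_M", f"{fam}_F"
        for pid, sex, role in ((mother, "female", "mother"), (father, "male", "father")):
            rows.append({"person_id": pid, "family_id": fam, "sex": sex, "role": role,
                         "asd": False, "gestational_age_weeks": np.nan, "preterm": False,
                         "preterm_stratum": "term"})
            ped_rows.append({"family_id": fam, "person_id": pid, "father_id": "0",
                             "mother_id": "0", "sex": sex, "role": role})
        n_children = int(rng.choice(sizes, p=size_p))
        for c in range(n_children):
            pid = f"{fam}_C{c}"
            child_ids.append(pid)
            sex = "male" if rng.random() < config.sex_ratio else "female"
            preterm = rng.random() < config.preterm_rate
            ga: float = np.nan
            stratum = "term"
            if preterm:
                if rng.random() < config.unknown_ga_rate:
                    stratum = "unknown_ga"
                else:
                    stratum = str(rng.choice(list(_STRATUM_GA), p=np.asarray(config.stratum_probs)))
                    lo, hi = _STRATUM_GA[stratum]
                    ga = float(rng.integers(lo, hi + 1))
            else:
                if rng.random() >= config.term_ga_missing_rate:
                    ga = float(rng.integers(37, 42))
            rows.append({"person_id": pid, "family_id": fam, "sex": sex,
                         "role": "proband" if c == 0 else "sibling",
                         "asd": False, "gestational_age_weeks": ga, "preterm": preterm,
                         "preterm_stratum": stratum})
            ped_rows.append({"family_id": fam, "person_id": pid, "father_id": father,
                             "mother_id": mother, "sex": sex, "role": "proband" if c == 0 else "sibling"})

    people = pd.DataFrame(rows)
    pedigree = pd.DataFrame(ped_rows)

    # polygenic score: binomial genotypes at independent SNPs, weighted
    # per-allele average, standardized over the children
    mafs = rng.uniform(0.05, 0.5, size=config.n_prs_snps)
    weights = rng.normal(0.0, config.prs_weight_sd, size=config.n_prs_snps)
    vids, refs, alts = [], [], []
    for j in range(config.n_prs_snps):
        ref, alt = _snv_alleles(rng)
        vids.append(f"rsS{j:06d}")
        refs.append(ref)
        alts.append(alt)
    variants_meta = pd.DataFrame({"variant_id": vids, "ref": refs, "alt": alts, "maf": mafs})
    prs_weights = pd.DataFrame({"variant_id": vids, "effect_allele": alts, "weight": weights})
    geno = rng.binomial(2, mafs, size=(len(child_ids), config.n_prs_snps)).astype(float)
    dosages = pd.DataFrame(geno, index=child_ids, columns=vids)
    raw = (geno * weights).sum(axis=1) / (2.0 * config.n_prs_snps)
    prs_z = (raw - raw.mean()) / raw.std(ddof=0) if raw.std(ddof=0) > 0 else raw * 0.0

    people = people.set_index("person_id", drop=False)
    people["prs_z"] = np.nan
    people.loc[child_ids, "prs_z"] = prs_z

    # ASD liability with family-shared random intercept
    fam_intercept = {f"F{f:05d}": rng.normal(0.0, config.family_intercept_sd)
                     for f in range(config.n_families)}
    is_child = people["role"].isin(["proband", "sibling"])
    for pid in child_ids:
        row = people.loc[pid]
        eta = (
            config.baseline_asd_logodds
            + config.male_effect_logOR * (row["sex"] == "male")
            + config.preterm_effect_logOR * bool(row["preterm"])
            + config.prs_effect_logOR * row["prs_z"]
            + config.interaction_logOR * bool(row["preterm"]) * row["prs_z"]
            + fam_intercept[row["family_id"]]
        )
        asd = bool(rng.random() < expit(eta))
        people.loc[pid, "asd"] = asd
        truth.liability[pid] = {"eta": float(eta), "family_intercept": fam_intercept[row["family_id"]],
                                "prs_z": float(row["prs_z"])}

    # de novo counts: Poisson with an ASD-preterm rate ratio
    log_rr = np.log(config.burden_rate_ratio_asd_preterm)
    for pid in child_ids:
        row = people.loc[pid]
        lam = config.baseline_dnv_rate * np.exp(log_rr * (bool(row["asd"]) and bool(row["preterm"])))
        people.loc[pid, "dnv_count"] = rng.poisson(lam)
    people["dnv_count"] = people["dnv_count"].fillna(0).astype(int)

    # diagnostic categories, ages, quantitative measures, birth features
    cats = cohort_io.CATEGORIES
    for i, cat in enumerate(cats):
        base = logit(config.category_base_prevs[i])
        eta = (
            base
            + config.category_asd_logOR[i] * people["asd"].astype(float)
            + config.category_preterm_logOR[i] * people["preterm"].astype(float)
        )
        draws = rng.random(len(people)) < expit(eta)
        n_specific = np.where(draws, 1 + rng.poisson(0.6, size=len(people)), 0)
        people[f"cat_{cat}"] = np.where(is_child, n_specific, 0)
    people["multimorbidity"] = sum(
        (people[f"cat_{c}"] >= 1).astype(int) for c in cats
    )
    people["age"] = np.where(is_child, rng.integers(2, 18, size=len(people)),
                             rng.integers(25, 55, size=len(people)))
    asd_f = people["asd"].astype(float)
    pre_f = people["preterm"].astype(float)
    n = len(people)
    people["scq"] = rng.normal(12, 5, n) + 8 * asd_f + 2 * pre_f
    people["rbsr"] = rng.normal(15, 8, n) + 10 * asd_f + 3 * pre_f
    people["dcdq"] = rng.normal(55, 10, n) - 8 * asd_f - 4 * pre_f
    people["cbcl_1_5"] = rng.normal(50, 10, n) + 6 * asd_f + 2 * pre_f
    people["cbcl_6_18"] = rng.normal(50, 10, n) + 6 * asd_f + 2 * pre_f
    people["fsiq"] = rng.normal(100, 15, n) - 8 * asd_f - 4 * pre_f
    people["birth_complications"] = (
        rng.random(n) < expit(logit(0.08) + 1.2 * pre_f + 0.2 * asd_f)
    ).astype(int)
    people["insufficient_oxygen"] = (
        rng.random(n) < expit(logit(0.05) + 1.0 * pre_f + 0.2 * asd_f)
    ).astype(int)
    people.loc[~is_child, ["birth_complications", "insufficient_oxygen"]] = 0

    people["group"] = np.select(
        [people["asd"] & people["preterm"], people["asd"] & ~people["preterm"],
         ~people["asd"] & people["preterm"]],
        ["asd_preterm", "asd_term", "nonasd_preterm"],
        default="nonasd_term",
    )
    return people.reset_index(drop=True), pedigree, truth, prs_weights, dosages, variants_meta


def _clean_candidate(
    rng: np.random.Generator,
    alloc: _PositionAllocator,
    child_id: str,
    family_id: str,
    **overrides,
) -> TrioVariantRecord:
    """A de novo candidate that passes every filter unless overridden."""
    chrom, pos = overrides.pop("chrom", None), overrides.pop("pos", None)
    if chrom is None:
        chrom, pos = alloc.take(inside_region=overrides.pop("inside_region", False))
    ref, alt = overrides.pop("ref", None), overrides.pop("alt", None)
    if ref is None:
        ref, alt = _snv_alleles(rng)
    dp_child = int(rng.integers(20, 41))
    alt_reads = int(rng.integers(int(0.4 * dp_child), int(0.6 * dp_child) + 1))
    base = dict(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        child_id=child_id,
        family_id=family_id,
        child_gt=HET,
        mother_gt=HOM_REF,
        father_gt=HOM_REF,
        child_ad=(dp_child - alt_reads, alt_reads),
        gq={m: int(rng.integers(30, 80)) for m in ("child", "mother", "father")},
        dp={"child": dp_child, "mother": int(rng.integers(15, 41)), "father": int(rng.integers(15, 41))},
        popmax_af=float(rng.uniform(0, 0.0008)) if rng.random() < 0.5 else None,
        consequence_terms=frozenset({"intron_variant"}),
        gene=None,
        is_exonic=False,
        n_alt_alleles_at_site=1,
    )
    base.update(overrides)
    return TrioVariantRecord(**base)


def _annotate_dnv(rec: TrioVariantRecord, config: SimConfig, panel: list[GenePanelEntry],
                  rng: np.random.Generator) -> tuple[TrioVariantRecord, list[str]]:
    """Assign exonic / LOF / gene annotations to one true DNV."""
    classes: list[str] = []
    if rng.random() < config.exonic_fraction:
        rec.is_exonic = True
        classes.append("exonic")
        if rng.random() < config.ndd_fraction:
            rec.gene = str(rng.choice([e.gene for e in panel]))
            classes.append("ndd_gene")
        else:
            rec.gene = f"GENE{int(rng.integers(0, 2000)):05d}"
        if rng.random() < config.lof_fraction:
            term = str(rng.choice(["stop_gained", "frameshift_variant", "splice_donor_variant",
                                   "splice_acceptor_variant", "start_lost", "stop_lost"]))
            rec.consequence_terms = frozenset({term})
            classes.append("lof")
            if "ndd_gene" in classes:
                classes.append("lof_ndd")
        else:
            rec.consequence_terms = frozenset(
                {"missense_variant" if rng.random() < 0.7 else "synonymous_variant"}
            )
            rec.cadd = float(np.clip(rng.normal(15, 8), 0, 45))
    return rec, classes


def simulate_cohort(config: SimConfig, emit_variants: bool = True) -> SyntheticCohort:
    """Generate a full synthetic cohort from a validated configuration.

    With ``emit_variants`` the per-child Poisson DNV counts are realized as
    trio variant records (plus inherited-variant records and any configured
    artifacts); without it only the person-level tables are produced, which
    is all the statistical recovery analyses need.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = RegionSet(DEFAULT_EXCLUDED_REGIONS)
    panel = _make_panel(rng)
    dominant = [e for e in panel if e.inheritance == "dominant"]
    recessive = [e for e in panel if e.inheritance == "recessive"]

    people, pedigree, truth, prs_weights, dosages, variants_meta = simulate_people(config, rng)
    children = people[people["role"].isin(["proband", "sibling"])]
    records_by_child: dict[str, list[TrioVariantRecord]] = {
        pid: [] for pid in children["person_id"]
    }

    if emit_variants:
        alloc = _PositionAllocator(regions)
        for row in children.itertuples(index=False):
            pid, fam = row.person_id, row.family_id
            truth.true_dnv_ids[pid] = []
            truth.dnv_classes[pid] = {"exonic": [], "lof": [], "ndd_gene": [], "lof_ndd": []}
            for _ in range(int(row.dnv_count)):
                rec = _clean_candidate(rng, alloc, pid, fam)
                rec, classes = _annotate_dnv(rec, config, panel, rng)
                records_by_child[pid].append(rec)
                truth.true_dnv_ids[pid].append(rec.variant_id)
                for cl in classes:
                    truth.dnv_classes[pid][cl].append(rec.variant_id)

            # inherited variants in panel genes
            truth.inherited_ids[pid] = {"dominant": [], "recessive": [], "compound_het": []}
            n_dom = rng.poisson(config.inherited_dominant_rate)
            for _ in range(n_dom):
                gene = str(rng.choice([e.gene for e in dominant]))
                parent = "mother" if rng.random() < 0.5 else "father"
                rec = _clean_candidate(
                    rng, alloc, pid, fam,
                    gene=gene, is_exonic=True,
                    popmax_af=float(rng.uniform(0, 0.001)),
                    mother_gt=HET if parent == "mother" else HOM_REF,
                    father_gt=HET if parent == "father" else HOM_REF,
                )
                u = rng.random()
                if u < 0.05:
                    rec.consequence_terms = frozenset({"stop_gained"})
                elif u < 0.55:
                    rec.consequence_terms = frozenset({"missense_variant"})
                    if rng.random() < 0.5:
                        rec.cadd = float(rng.uniform(20, 40))
                    else:
                        rec.cadd = float(rng.uniform(0, 19))
                else:
                    rec.consequence_terms = frozenset({"synonymous_variant"})
                records_by_child[pid].append(rec)
                truth.inherited_ids[pid]["dominant"].append(rec.variant_id)
            n_rec = rng.poisson(config.inherited_recessive_rate)
            for _ in range(n_rec):
                gene = str(rng.choice([e.gene for e in recessive]))
                rec = _clean_candidate(
                    rng, alloc, pid, fam,
                    gene=gene, is_exonic=True,
                    popmax_af=float(rng.uniform(0, 0.01)),
                    child_gt=HOM_ALT, mother_gt=HET, father_gt=HET,
                    consequence_terms=frozenset({"missense_variant"}),
                )
                records_by_child[pid].append(rec)
                truth.inherited_ids[pid]["recessive"].append(rec.variant_id)
            if rng.random() < config.compound_het_rate:
                gene = str(rng.choice([e.gene for e in recessive]))
                pair = []
                for parent in ("mother", "father"):
                    rec = _clean_candidate(
                        rng, alloc, pid, fam,
                        gene=gene, is_exonic=True,
                        popmax_af=float(rng.uniform(0, 0.01)),
                        mother_gt=HET if parent == "mother" else HOM_REF,
                        father_gt=HET if parent == "father" else HOM_REF,
                        consequence_terms=frozenset({"missense_variant"}),
                    )
                    records_by_child[pid].append(rec)
                    pair.append(rec.variant_id)
                truth.inherited_ids[pid]["compound_het"].extend(pair)

        plant_artifacts(records_by_child, config, truth, rng, alloc, pedigree)

    profiles = [
        DiagnosticProfile(
            person_id=row.person_id,
            specific_counts={c: int(getattr(row, f"cat_{c}")) for c in cohort_io.CATEGORIES},
        )
        for row in children.itertuples(index=False)
    ]
    return SyntheticCohort(
        config=config,
        people=people,
        profiles=profiles,
        records_by_child=records_by_child,
        panel=panel,
        regions=regions,
        pedigree=pedigree,
        prs_weights=prs_weights,
        dosages=dosages,
        variants_meta=variants_meta,
        truth=truth,
    )


def plant_artifacts(
    records_by_child: dict[str, list[TrioVariantRecord]],
    config: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator,
    alloc: _PositionAllocator,
    pedigree: pd.DataFrame,
) -> None:
    """Inject candidate records that each violate exactly one QC filter.

    Every artifact is a perfectly good de novo candidate except for the one
    property its type spoofs; the expected rejecting filter is recorded in
    the truth set so the cascade's per-filter audit can be verified.
    """
    children = list(records_by_child)
    fam_of = dict(zip(pedigree["person_id"], pedigree["family_id"]))
    n_children = len(children)
    for atype in ARTIFACT_TYPES:
        rate = config.artifact_rates.get(atype, 0.0)
        n_plant = rng.poisson(rate * n_children)
        for _ in range(n_plant):
            child = str(rng.choice(children))
            fam = fam_of[child]
            expected = ARTIFACT_EXPECTED_FILTER[atype]
            if atype == "low_gq":
                rec = _clean_candidate(rng, alloc, child, fam)
                member = str(rng.choice(["child", "mother", "father"]))
                rec.gq[member] = int(rng.integers(0, 20))
                _add_artifact(records_by_child, truth, rec, expected)
            elif atype == "low_dp":
                rec = _clean_candidate(rng, alloc, child, fam)
                member = str(rng.choice(["mother", "father"]))
                rec.dp[member] = int(rng.integers(1, 10))
                _add_artifact(records_by_child, truth, rec, expected)
            elif atype == "common_af":
                rec = _clean_candidate(rng, alloc, child, fam,
                                       popmax_af=float(rng.uniform(0.002, 0.05)))
                _add_artifact(records_by_child, truth, rec, expected)
            elif atype == "homopolymer":
                run = "A" * 10 if rng.random() < 0.5 else "T" * 10
                rec = _clean_candidate(rng, alloc, child, fam, ref="C", alt="C" + run)
                _add_artifact(records_by_child, truth, rec, expected)
            elif atype == "region":
                rec = _clean_candidate(rng, alloc, child, fam, inside_region=True)
                _add_artifact(records_by_child, truth, rec, expected)
            elif atype == "cross_family":
                rec = _clean_candidate(rng, alloc, child, fam)
                others = [c for c in children if fam_of[c] != fam]
                if not others:
                    continue
                other = str(rng.choice(others))
                parent = "mother" if rng.random() < 0.5 else "father"
                companion = _clean_candidate(
                    rng, alloc, other, fam_of[other],
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alt,
                    popmax_af=rec.popmax_af,  # site-level INFO must agree
                    child_gt=HOM_REF,
                    mother_gt=HET if parent == "mother" else HOM_REF,
                    father_gt=HET if parent == "father" else HOM_REF,
                )
                records_by_child[other].append(companion)
                _add_artifact(records_by_child, truth, rec, expected)
            elif atype == "recurrent_child":
                fams = list(dict.fromkeys(fam_of[c] for c in children))
                if len(fams) < 4:
                    continue
                chosen_fams = rng.choice(fams, size=4, replace=False)
                chrom, pos = alloc.take()
                ref, alt = _snv_alleles(rng)
                af = float(rng.uniform(0, 0.0008)) if rng.random() < 0.5 else None
                for cf in chosen_fams:
                    carriers = [c for c in children if fam_of[c] == cf]
                    carrier = str(rng.choice(carriers))
                    rec = _clean_candidate(rng, alloc, carrier, cf,
                                           chrom=chrom, pos=pos, ref=ref, alt=alt,
                                           popmax_af=af)
                    _add_artifact(records_by_child, truth, rec, expected)
            elif atype == "multiallelic_excess":
                rec = _clean_candidate(rng, alloc, child, fam, n_alt_alleles_at_site=4)
                _add_artifact(records_by_child, truth, rec, expected)


def _add_artifact(records_by_child, truth: SimTruth, rec: TrioVariantRecord, expected: str) -> None:
    records_by_child[rec.child_id].append(rec)
    truth.artifacts.append(
        {"child_id": rec.child_id, "variant_id": rec.variant_id, "expected_filter": expected}
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the cohort in the standard on-disk formats plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_io.write_pedigree(cohort.pedigree, outdir / "pedigree.tsv")
    cohort_io.write_gene_panel(cohort.panel, outdir / "panel.tsv")
    cohort.regions.to_bed(outdir / "regions.bed")
    cohort_io.write_prs_weights(cohort.prs_weights, outdir / "prs_weights.tsv")
    cohort.variants_meta.to_csv(outdir / "prs_variants.tsv", sep="\t", index=False)
    cohort.dosages.to_csv(outdir / "prs_dosages.tsv", sep="\t")
    pheno = cohort.children.copy()
    pheno["asd"] = np.where(pheno["asd"], "yes", "no")
    cols = ["person_id", "family_id", "sex", "role", "asd", "gestational_age_weeks", "preterm"]
    cols += [f"cat_{c}" for c in cohort_io.CATEGORIES]
    cols += ["scq", "rbsr", "dcdq", "cbcl_1_5", "cbcl_6_18", "fsiq"]
    pheno[cols].to_csv(outdir / "phenotypes.csv", index=False)
    cohort_io.write_trio_vcf(cohort.records_by_child, cohort.pedigree, outdir / "cohort.vcf")
    cohort.truth.to_json(outdir / "truth.json")
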