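"""Cohort file formats and in-memory domain types.

Reads and writes the on-disk artefacts a family-cohort analysis consumes:
trio genotypes (VCF), pedigrees (TSV), phenotype tables (CSV), gene panels
with inheritance-mode annotations (TSV), excluded-region sets (BED), and
polygenic-score weight tables (TSV).

Coordinate conventions: VCF positions are 1-based inclusive at I/O; all
interval arithmetic inside the package is 0-based half-open.
"""

from __future__ import annotations

import bisect
import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# genotype codes
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

PRETERM_STRATA = ("extremely", "very", "moderate", "late")
CATEGORIES = (
    "behavior",
    "development",
    "mood",
    "growth",
    "birth",
    "eat",
    "neuro",
    "visaud",
    "sleep",
)
QUANT_MEASURES = ("cbcl_1_5", "cbcl_6_18", "dcdq", "rbsr", "scq", "fsiq")


def preterm_stratum(gestational_age_weeks: int | None, preterm: bool) -> str:
    """Gestational-age stratum for one birth.

    Preterm is delivery before 37 completed weeks; the preterm range is
    split into extremely (<28), very (28-31), moderate (32-33) and late
    (34-36) strata. A preterm birth with unknown gestational age gets the
    ``unknown_ga`` stratum; term births (>=37 weeks) get ``term``.
    """
    ga = gestational_age_weeks
    if ga is None:
        return "unknown_ga" if preterm else "term"
    if ga >= 37:
        return "term"
    if ga < 28:
        return "extremely"
    if ga <= 31:
        return "very"
    if ga <= 33:
        return "moderate"
    return "late"


@dataclass
class Individual:
    person_id: str
    family_id: str
    sex: str  # male | female
    role: str  # proband | sibling | mother | father
    asd: bool
    gestational_age_weeks: int | None = None
    preterm: bool = False
    preterm_stratum: str = "term"
    ancestry_pcs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"bad sex {self.sex!r} for {self.person_id}")
        ga = self.gestational_age_weeks
        if ga is not None:
            self.preterm = ga < 37
        self.preterm_stratum = preterm_stratum(ga, self.preterm)


@dataclass
class DiagnosticProfile:
    """Presence of the nine diagnostic categories for one person.

    A category is present iff at least one specific diagnosis within it is
    recorded; multimorbidity is the number of present categories (0..9).
    """

    person_id: str
    specific_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            self.specific_counts.setdefault(cat, 0)
        bad = set(self.specific_counts) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown diagnostic categories: {sorted(bad)}")

    @property
    def categories(self) -> dict[str, bool]:
        return {c: self.specific_counts[c] >= 1 for c in CATEGORIES}

    @property
    def multimorbidity(self) -> int:
        return sum(self.categories.values())


@dataclass
class QuantMeasures:
    person_id: str
    cbcl_1_5: float | None = None
    cbcl_6_18: float | None = None
    dcdq: float | None = None
    rbsr: float | None = None
    scq: float | None = None
    fsiq: float | None = None


@dataclass
class TrioVariantRecord:
    """One biallelic variant site for one child-mother-father trio."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    child_id: str
    family_id: str
    child_gt: str = HOM_REF
    mother_gt: str = HOM_REF
    father_gt: str = HOM_REF
    child_ad: tuple[int, int] = (0, 0)
    gq: dict[str, int] = field(default_factory=dict)  # member -> GQ
    dp: dict[str, int] = field(default_factory=dict)
    popmax_af: float | None = None
    consequence_terms: frozenset[str] = frozenset()
    gene: str | None = None
    is_exonic: bool = False
    cadd: float | None = None
    phylop: float | None = None
    revel: float | None = None
    sift: str | None = None  # D | T
    polyphen: str | None = None  # D | P | B
    n_alt_alleles_at_site: int = 1

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.n_alt_alleles_at_site < 1:
            raise ValueError("n_alt_alleles_at_site must be >= 1")
        self.consequence_terms = frozenset(self.consequence_terms)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def allele_balance(self) -> float | None:
        """Alt-read fraction in the child; undefined at zero depth."""
        ref_reads, alt_reads = self.child_ad
        denom = ref_reads + alt_reads
        if denom <= 0:
            return None
        return alt_reads / denom

    def gt(self, member: str) -> str:
        return {"child": self.child_gt, "mother": self.mother_gt, "father": self.father_gt}[member]


@dataclass(frozen=True)
class GenePanelEntry:
    gene: str
    inheritance: str  # dominant | recessive | unannotated
    source_flag: str = ""


class RegionSet:
    """Sorted, merged set of half-open 0-based genomic intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._starts):
            out.extend(
                (chrom, s, e) for s, e in zip(self._starts[chrom], self._ends[chrom])
            )
        return out

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                ivs.append((chrom, int(start), int(end)))
        return cls(ivs)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# gene panel


_DOMINANT_ALIASES = {"monoallelic", "dominant"}
_RECESSIVE_ALIASES = {"biallelic", "recessive"}


def normalize_inheritance(raw: str) -> str:
    token = raw.strip().lower()
    if token in _DOMINANT_ALIASES:
        return "dominant"
    if token in _RECESSIVE_ALIASES:
        return "recessive"
    return "unannotated"


def read_gene_panel(path: str | Path) -> list[GenePanelEntry]:
    """Read a gene panel TSV (columns: gene, inheritance[, source]).

    Inheritance labels are normalized (monoallelic/dominant -> dominant,
    biallelic/recessive -> recessive, anything else -> unannotated).
    Duplicate rows with the same mode collapse to one entry; conflicting
    modes for one gene are an error, surfaced rather than silently resolved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in df.columns or "inheritance" not in df.columns:
        raise ValueError(f"{path}: panel needs 'gene' and 'inheritance' columns")
    seen: dict[str, GenePanelEntry] = {}
    for row in df.itertuples(index=False):
        mode = normalize_inheritance(str(row.inheritance))
        flag = str(getattr(row, "source", "") or "")
        gene = str(row.gene)
        if gene in seen:
            if seen[gene].inheritance != mode:
                raise ValueError(
                    f"conflicting inheritance modes for gene {gene}: "
                    f"{seen[gene].inheritance} vs {mode}"
                )
            continue
        seen[gene] = GenePanelEntry(gene=gene, inheritance=mode, source_flag=flag)
    return list(seen.values())


def write_gene_panel(entries: Sequence[GenePanelEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tinheritance\tsource\n")
        for e in entries:
            fh.write(f"{e.gene}\t{e.inheritance}\t{e.source_flag}\n")


def panel_mode_map(entries: Sequence[GenePanelEntry]) -> dict[str, str]:
    return {e.gene: e.inheritance for e in entries}


# ---------------------------------------------------------------------------
# pedigree


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Pedigree TSV with columns family_id, person_id, father_id, mother_id,
    sex, role. '0' or empty parent ids mean founder."""
    ped = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    required = {"family_id", "person_id", "father_id", "mother_id", "sex", "role"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree missing columns: {sorted(missing)}")
    return ped


def write_pedigree(ped: pd.DataFrame, path: str | Path) -> None:
    ped.to_csv(path, sep="\t", index=False)


def trios_from_pedigree(ped: pd.DataFrame) -> list[tuple[str, str, str, str]]:
    """(family_id, child, mother, father) for every child with both parents.

    Every child of a multi-child family forms its own trio with the shared
    parents, so one family can contribute several trios.
    """
    out = []
    for row in ped.itertuples(index=False):
        if row.father_id not in ("0", "") and row.mother_id not in ("0", ""):
            out.append((row.family_id, row.person_id, row.mother_id, row.father_id))
    return out


# ---------------------------------------------------------------------------
# trio VCF


_GT_FROM_CODE = {0: HOM_REF, 1: HET, 2: HOM_ALT}

_INFO_FLOAT = {"POPMAX_AF": "popmax_af", "CADD": "cadd", "PHYLOP": "phylop", "REVEL": "revel"}
_INFO_STR = {"SIFT": "sift", "POLYPHEN": "polyphen"}

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=POPMAX_AF,Number=A,Type=Float,Description="Maximum population allele frequency">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Sequence Ontology consequence terms">
##INFO=<ID=EXONIC,Number=0,Type=Flag,Description="Variant overlaps an exon">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">
##INFO=<ID=PHYLOP,Number=1,Type=Float,Description="PhyloP conservation score">
##INFO=<ID=REVEL,Number=1,Type=Float,Description="REVEL missense score">
##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call (D damaging, T tolerated)">
##INFO=<ID=POLYPHEN,Number=1,Type=String,Description="PolyPhen call (D/P/B)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
""" + "".join(
    f"##contig=<ID={c}>\n" for c in [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)


def _classify_gt(alleles: Sequence[int], alt_index: int) -> str:
    """Collapse a diploid genotype to its state relative to one ALT allele."""
    if any(a < 0 for a in alleles):
        return MISSING
    hits = sum(1 for a in alleles if a == alt_index)
    if len(alleles) == 1:  # hemizygous call
        return HOM_ALT if hits == 1 else HOM_REF
    return _GT_FROM_CODE[hits]


def read_trio_vcf(
    path: str | Path, pedigree: pd.DataFrame
) -> dict[str, list[TrioVariantRecord]]:
    """Stream a multi-sample VCF into per-child trio variant records.

    Multiallelic sites are decomposed into one biallelic record per ALT
    allele; each decomposed record keeps the original site's ALT count so
    the multiallelic-excess filter can still see it. Children whose parent
    samples are absent from the VCF are skipped with a warning; malformed
    genotypes become ``missing``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_index = {s: i for i, s in enumerate(vcf.samples)}
    trios = []
    for family_id, child, mother, father in trios_from_pedigree(pedigree):
        if child not in sample_index:
            continue
        if mother not in sample_index or father not in sample_index:
            logger.warning("child %s skipped: parent sample missing from VCF", child)
            continue
        trios.append((family_id, child, mother, father))
    out: dict[str, list[TrioVariantRecord]] = {child: [] for _, child, _, _ in trios}

    for variant in vcf:
        n_alt = len(variant.ALT)
        genotypes = variant.genotypes  # [[a1, a2, phased], ...]
        ad = variant.format("AD")
        dp = variant.format("DP")
        gq = variant.format("GQ")
        info = dict(variant.INFO)
        gene = info.get("GENE")
        csq = info.get("CSQ")
        terms = frozenset(str(csq).split(",")) if csq else frozenset()
        is_exonic = "EXONIC" in info
        popmax = info.get("POPMAX_AF")
        extra = {}
        for key, attr in _INFO_FLOAT.items():
            if key == "POPMAX_AF":
                continue
            if key in info:
                extra[attr] = float(info[key])
        for key, attr in _INFO_STR.items():
            if key in info:
                extra[attr] = str(info[key])

        for alt_index0, alt in enumerate(variant.ALT):
            alt_code = alt_index0 + 1
            if isinstance(popmax, tuple):
                af = popmax[alt_index0]
            else:
                af = popmax
            af = float(af) if af is not None else None
            for family_id, child, mother, father in trios:
                gts = {}
                for member, sample in (("child", child), ("mother", mother), ("father", father)):
                    alleles = genotypes[sample_index[sample]][:-1]
                    try:
                        gts[member] = _classify_gt(alleles, alt_code)
                    except (KeyError, TypeError):
                        gts[member] = MISSING
                ci = sample_index[child]
                child_ad = (0, 0)
                if ad is not None:
                    row_ad = ad[ci]
                    ref_reads = int(row_ad[0]) if row_ad[0] >= 0 else 0
                    alt_reads = (
                        int(row_ad[alt_code]) if len(row_ad) > alt_code and row_ad[alt_code] >= 0 else 0
                    )
                    child_ad = (ref_reads, alt_reads)
                gq_map, dp_map = {}, {}
                for member, sample in (("child", child), ("mother", mother), ("father", father)):
                    si = sample_index[sample]
                    if gq is not None:
                        gq_map[member] = int(np.ravel(gq[si])[0])
                    if dp is not None:
                        dp_map[member] = int(np.ravel(dp[si])[0])
                out[child].append(
                    TrioVariantRecord(
                        chrom=variant.CHROM,
                        pos=variant.POS,
                        ref=variant.REF,
                        alt=alt,
                        child_id=child,
                        family_id=family_id,
                        child_gt=gts["child"],
                        mother_gt=gts["mother"],
                        father_gt=gts["father"],
                        child_ad=child_ad,
                        gq=gq_map,
                        dp=dp_map,
                        popmax_af=af,
                        consequence_terms=terms,
                        gene=str(gene) if gene is not None else None,
                        is_exonic=is_exonic,
                        n_alt_alleles_at_site=n_alt,
                        **extra,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# phenotype table


def read_phenotype_table(
    path: str | Path,
    ga_min: int = 20,
    ga_max: int = 42,
) -> tuple[list[Individual], list[DiagnosticProfile], list[QuantMeasures]]:
    """Read the per-person phenotype CSV.

    Expected columns: person_id, family_id, sex, role, asd,
    gestational_age_weeks (may be empty), preterm (used only when GA is
    missing), ``cat_<category>`` specific-diagnosis counts, and the
    quantitative measure columns. Rows with gestational age outside
    [ga_min, ga_max] are rejected (implausible or post-term records).
    """
    df = pd.read_csv(path)
    individuals, profiles, quant = [], [], []
    n_rejected = 0
    for row in df.itertuples(index=False):
        ga = getattr(row, "gestational_age_weeks", None)
        ga = None if ga is None or (isinstance(ga, float) and np.isnan(ga)) else int(ga)
        if ga is not None and not (ga_min <= ga <= ga_max):
            n_rejected += 1
            continue
        preterm_flag = bool(getattr(row, "preterm", False)) if ga is None else ga < 37
        individuals.append(
            Individual(
                person_id=str(row.person_id),
                family_id=str(row.family_id),
                sex=str(row.sex),
                role=str(getattr(row, "role", "proband")),
                asd=_as_bool(row.asd),
                gestational_age_weeks=ga,
                preterm=preterm_flag,
            )
        )
        counts = {}
        for cat in CATEGORIES:
            col = f"cat_{cat}"
            if hasattr(row, col):
                val = getattr(row, col)
                counts[cat] = 0 if pd.isna(val) else int(val)
        profiles.append(DiagnosticProfile(person_id=str(row.person_id), specific_counts=counts))
        qkw = {}
        for m in QUANT_MEASURES:
            if hasattr(row, m):
                val = getattr(row, m)
                qkw[m] = None if pd.isna(val) else float(val)
        quant.append(QuantMeasures(person_id=str(row.person_id), **qkw))
    if n_rejected:
        logger.warning("rejected %d rows with gestational age outside [%d, %d]", n_rejected, ga_min, ga_max)
    return individuals, profiles, quant


def _as_bool(val) -> bool:
    if isinstance(val, str):
        return val.strip().lower() in ("yes", "true", "1")
    return bool(val)


def individuals_frame(individuals: Sequence[Individual]) -> pd.DataFrame:
    """Tidy per-person DataFrame used by the statistical modules."""
    return pd.DataFrame(
        {
            "person_id": [p.person_id for p in individuals],
            "family_id": [p.family_id for p in individuals],
            "sex": [p.sex for p in individuals],
            "role": [p.role for p in individuals],
            "asd": [p.asd for p in individuals],
            "gestational_age_weeks": [p.gestational_age_weeks for p in individuals],
            "preterm": [p.preterm for p in individuals],
            "preterm_stratum": [p.preterm_stratum for p in individuals],
        }
    )


# ---------------------------------------------------------------------------
# trio VCF writing

_GT_STRING = {HOM_REF: "0/0", MISSING: "./."}
_PAD_BASES = ("G", "C", "T", "A")


def _chrom_sort_key(chrom: str) -> tuple:
    body = chrom.removeprefix("chr")
    return (0, int(body)) if body.isdigit() else (1, body)


def write_trio_vcf(
    records_by_child: Mapping[str, Sequence[TrioVariantRecord]],
    pedigree: pd.DataFrame,
    path: str | Path,
    default_gq: int = 50,
    default_dp: int = 30,
) -> None:
    """Write trio records back to a multi-sample VCF.

    Records sharing (chrom, pos, ref) are merged into one line; if a record
    declares more site ALT alleles than are represented, the ALT list is
    padded with carrier-free placeholder alleles so the site-level allele
    count survives a round trip. Samples without an explicit genotype at a
    site are written as confident hom-ref.
    """
    samples = list(pedigree["person_id"])
    trio_of = {c: (m, f) for _, c, m, f in trios_from_pedigree(pedigree)}

    sites: dict[tuple[str, int, str], dict] = {}
    for child, records in records_by_child.items():
        mother, father = trio_of.get(child, (None, None))
        for rec in records:
            site = sites.setdefault(
                (rec.chrom, rec.pos, rec.ref),
                {"alts": [], "info": {}, "gts": {}, "ad": {}, "gq": {}, "dp": {}, "n_alt": 1},
            )
            if rec.alt not in site["alts"]:
                site["alts"].append(rec.alt)
            site["n_alt"] = max(site["n_alt"], rec.n_alt_alleles_at_site)
            info = site["info"]
            if rec.popmax_af is not None:
                info["POPMAX_AF"] = rec.popmax_af
            if rec.gene is not None:
                info["GENE"] = rec.gene
            if rec.consequence_terms:
                info["CSQ"] = ",".join(sorted(rec.consequence_terms))
            if rec.is_exonic:
                info["EXONIC"] = True
            for key, attr in (("CADD", "cadd"), ("PHYLOP", "phylop"), ("REVEL", "revel"),
                              ("SIFT", "sift"), ("POLYPHEN", "polyphen")):
                val = getattr(rec, attr)
                if val is not None:
                    info[key] = val
            alt_idx = site["alts"].index(rec.alt) + 1
            members = [("child", rec.child_id), ("mother", mother), ("father", father)]
            for member, sample in members:
                if sample is None:
                    continue
                gt = rec.gt(member)
                site["gts"][sample] = (gt, alt_idx)
                if member == "child":
                    site["ad"][sample] = rec.child_ad
                site["gq"][sample] = rec.gq.get(member, default_gq)
                site["dp"][sample] = rec.dp.get(member, default_dp)

    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for (chrom, pos, ref) in sorted(sites, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2])):
            site = sites[(chrom, pos, ref)]
            alts = list(site["alts"])
            pad_i = 0
            while len(alts) < site["n_alt"]:
                cand = ref + _PAD_BASES[pad_i % 4] * (pad_i // 4 + 1)
                pad_i += 1
                if cand not in alts:
                    alts.append(cand)
            info = site["info"]
            parts = []
            for key, val in info.items():
                if val is True:
                    parts.append(key)
                elif key == "POPMAX_AF":
                    parts.append(f"{key}={','.join([f'{val:.6g}'] * len(alts))}")
                else:
                    parts.append(f"{key}={val}")
            info_str = ";".join(parts) if parts else "."
            fields = []
            for sample in samples:
                gt, alt_idx = site["gts"].get(sample, (HOM_REF, 1))
                if gt in _GT_STRING:
                    gt_str = _GT_STRING[gt]
                elif gt == HET:
                    gt_str = f"0/{alt_idx}"
                else:
                    gt_str = f"{alt_idx}/{alt_idx}"
                dp = site["dp"].get(sample, default_dp)
                gq = site["gq"].get(sample, default_gq)
                ad = [0] * (len(alts) + 1)
                if sample in site["ad"]:
                    ref_reads, alt_reads = site["ad"][sample]
                    ad[0], ad[alt_idx] = ref_reads, alt_reads
                elif gt == HOM_REF:
                    ad[0] = dp
                elif gt == HET:
                    ad[0] = ad[alt_idx] = dp // 2
                else:
                    ad[alt_idx] = dp
                fields.append(f"{gt_str}:{','.join(map(str, ad))}:{dp}:{gq}")
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t{info_str}\tGT:AD:DP:GQ\t"
                + "\t".join(fields)
                + "\n"
            )


# ---------------------------------------------------------------------------
# PRS weights


def read_prs_weights(path: str | Path) -> pd.DataFrame:
    """Weight table TSV with columns variant_id, effect_allele, weight."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "effect_allele": str})
    required = {"variant_id", "effect_allele", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weights missing columns: {sorted(missing)}")
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicate variant_id in weights: {dup}")
    return df


def write_prs_weights(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
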