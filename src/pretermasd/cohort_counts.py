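"""Published participant counts for the SPARK and SSC ASD cohorts.

Group sizes by analysis subset, as released in the cohort characteristics
tables (SPARK phenotype database version 9; SPARK genome-sequencing v1.1;
the exome-sequencing de novo call set; SSC). The restricted individual-
level data are not redistributable, but the subset sizes are public and
fully determine the preterm-birth fractions reported for each analysis
arm, so they serve as fixed reference inputs for consistency checks.
"""

from __future__ import annotations

#: participants with ASD by analysis subset: (preterm, term)
ASD_GROUP_COUNTS: dict[str, tuple[int, int]] = {
    # SPARK v9 basic medical screen (phenotype analysis)
    "phenotype_spark": (9196, 65021),
    # SSC probands with usable gestational age
    "phenotype_ssc": (157, 1479),
    # SPARK genome-sequencing de novo analysis
    "gs_dnv": (309, 2728),
    # exome-sequencing de novo call set
    "es_dnv": (697, 5747),
    # SPARK genome-sequencing inherited-variant analysis
    "inherited": (310, 2742),
    # SPARK polygenic-score analysis
    "prs": (305, 2702),
}

#: preterm-stratum counts among SPARK v9 ASD-preterm individuals
ASD_PRETERM_STRATA: dict[str, int] = {
    "extremely": 699,
    "very": 987,
    "moderate": 1274,
    "late": 5659,
    "unknown_ga": 577,
}


def preterm_fraction(analysis: str) -> float:
    """Preterm fraction among ASD participants of one analysis subset."""
    try:
        preterm, term = ASD_GROUP_COUNTS[analysis]
    except KeyError:
        raise KeyError(
            f"unknown analysis {analysis!r}; choose from {sorted(ASD_GROUP_COUNTS)}"
        ) from None
    return preterm / (preterm + term)
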