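"""Shared fixtures: hand-built trio records and cached synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from pretermasd.cohort_io import HET, HOM_ALT, HOM_REF, TrioVariantRecord
from pretermasd.synthetic_cohort import SimConfig, simulate_cohort


def make_record(
    child_id: str = "F1_C0",
    family_id: str = "F1",
    chrom: str = "chr1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    child_gt: str = HET,
    mother_gt: str = HOM_REF,
    father_gt: str = HOM_REF,
    child_ad: tuple[int, int] = (10, 10),
    gq: int | dict = 50,
    dp: int | dict = 30,
    **kwargs,
) -> TrioVariantRecord:
    """A de novo candidate record passing every filter unless overridden."""
    if isinstance(gq, int):
        gq = {m: gq for m in ("child", "mother", "father")}
    if isinstance(dp, int):
        dp = {m: dp for m in ("child", "mother", "father")}
    return TrioVariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        child_id=child_id, family_id=family_id,
        child_gt=child_gt, mother_gt=mother_gt, father_gt=father_gt,
        child_ad=child_ad, gq=gq, dp=dp, **kwargs,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Variant-level cohort small enough for exhaustive re-checks."""
    return simulate_cohort(SimConfig(n_families=40, seed=11, compound_het_rate=0.2))


@pytest.fixture(scope="session")
def people_cohort():
    """Person-level cohort (no variant records) for the statistical models."""
    return simulate_cohort(SimConfig(n_families=300, seed=2), emit_variants=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
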