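"""Polygenic risk scoring and the ASD probability models.

Raw scores are per-allele weighted averages (sum of dosage x weight over
non-missing variants, divided by twice the number of variants used), then
z-standardized over the cohort. Association analyses combine Wilcoxon
rank-sum group contrasts with family-clustered GEE logistic models, and
the explained variance of ASD status is reported as McFadden's pseudo-r2
from ordinary logistic fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gee_models import GEEFit, fit_gee

logger = logging.getLogger(__name__)


@dataclass
class PRSResult:
    person_id: str
    raw_score: float
    z_score: float
    n_variants_used: int


def score_individuals(
    dosages: pd.DataFrame,
    variants: pd.DataFrame,
    weights: pd.DataFrame,
    mode: str = "avg",
) -> tuple[list[PRSResult], pd.DataFrame]:
    """Allelic scores for every person from effect-allele dosages.

    ``dosages`` is persons x variant_id with alt-allele dosage 0/1/2 (NaN
    missing); ``variants`` maps variant_id to its ref/alt alleles;
    ``weights`` carries variant_id, effect_allele, weight. Weights whose
    effect allele is the variant's ref allele are applied to the flipped
    dosage (2 - alt dosage); weights matching neither allele are skipped
    and counted. ``mode='avg'`` divides the weighted sum by twice the
    number of non-missing variants used (per-allele average); ``'sum'``
    reports the plain weighted sum.

    Returns the per-person results plus a one-row audit frame (variants
    matched / flipped / skipped). Standardization is over all persons with
    a defined score; zero variance is an error.
    """
    if mode not in ("avg", "sum"):
        raise ValueError("mode must be 'avg' or 'sum'")
    vmeta = variants.set_index("variant_id")
    usable, flipped, skipped = [], 0, 0
    w = {}
    for row in weights.itertuples(index=False):
        vid = row.variant_id
        if vid not in vmeta.index or vid not in dosages.columns:
            skipped += 1
            continue
        ref, alt = vmeta.loc[vid, "ref"], vmeta.loc[vid, "alt"]
        if row.effect_allele == alt:
            w[vid] = (float(row.weight), False)
        elif row.effect_allele == ref:
            w[vid] = (float(row.weight), True)
            flipped += 1
        else:
            logger.warning("weight for %s skipped: effect allele matches neither ref nor alt", vid)
            skipped += 1
            continue
        usable.append(vid)

    mat = dosages[usable].to_numpy(dtype=float)
    wvec = np.array([w[v][0] for v in usable])
    flip = np.array([w[v][1] for v in usable])
    eff = np.where(flip, 2.0 - mat, mat)  # effect-allele dosage
    present = ~np.isnan(mat)
    weighted = np.where(present, eff * wvec, 0.0)
    n_used = present.sum(axis=1)
    raw = weighted.sum(axis=1)
    if mode == "avg":
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = raw / (2.0 * n_used)
    raw = np.where(n_used > 0, raw, np.nan)
    if np.isnan(raw).any():
        logger.warning("%d person(s) have no overlapping variants; score missing", int(np.isnan(raw).sum()))
    defined = raw[~np.isnan(raw)]
    sd = defined.std(ddof=0)
    if sd == 0 or len(defined) < 2:
        raise ValueError("zero variance in raw scores; cannot standardize")
    z = (raw - defined.mean()) / sd
    results = [
        PRSResult(person_id=str(pid), raw_score=float(r), z_score=float(zz), n_variants_used=int(n))
        for pid, r, zz, n in zip(dosages.index, raw, z, n_used)
    ]
    audit = pd.DataFrame(
        [{"n_weights": len(weights), "n_used": len(usable), "n_flipped": flipped, "n_skipped": skipped}]
    )
    return results, audit


def scores_frame(results: list[PRSResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": [r.person_id for r in results],
            "raw_score": [r.raw_score for r in results],
            "prs_z": [r.z_score for r in results],
            "n_variants_used": [r.n_variants_used for r in results],
        }
    )


def prs_group_tests(
    cohort: pd.DataFrame,
    contrasts: dict[str, tuple[pd.Series, pd.Series]],
    pc_cols: tuple[str, ...] = tuple(f"pc{i}" for i in range(1, 11)),
) -> pd.DataFrame:
    """Wilcoxon rank-sum plus GEE logistic association per group contrast.

    ``contrasts`` maps a name to a pair of boolean masks over ``cohort``
    (group membership); the GEE model regresses membership on prs_z with
    sex and ancestry PCs (PC columns absent from the table are flagged and
    omitted).
    """
    have_pcs = [c for c in pc_cols if c in cohort.columns]
    if len(have_pcs) < len(pc_cols):
        logger.warning("ancestry PCs missing; GEE models run without them")
    rows = []
    for name, (mask_a, mask_b) in contrasts.items():
        xa = cohort.loc[mask_a, "prs_z"].dropna()
        xb = cohort.loc[mask_b, "prs_z"].dropna()
        stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
        sub = cohort[mask_a | mask_b].copy()
        sub["is_a"] = mask_a[mask_a | mask_b].astype(int)
        covs = ["prs_z", "sex"] + have_pcs
        fit = fit_gee(sub, "is_a", covs, "binomial_logit")
        rows.append(
            {
                "contrast": name,
                "wilcoxon_stat": float(stat),
                "wilcoxon_p": float(p),
                "gee_prs_coef": fit.coef("prs_z"),
                "gee_prs_p": fit.p("prs_z"),
            }
        )
    return pd.DataFrame(rows)


def fit_probability_model(
    cohort: pd.DataFrame,
    with_interaction: bool = False,
    prs_grid: np.ndarray | None = None,
) -> tuple[GEEFit, pd.DataFrame]:
    """GEE logistic model asd ~ sex + preterm + prs_z, family-clustered.

    With ``with_interaction`` a preterm x PRS product term is added. The
    returned grid holds average predicted probabilities over the observed
    covariate distribution for each PRS grid value x sex x preterm cell
    (the marginal-effects display of the fitted model).
    """
    covs = ["sex", "preterm", "prs_z"]
    if with_interaction:
        covs.append("preterm:prs_z")
    data = cohort.copy()
    data["preterm"] = data["preterm"].astype(int)
    data["asd"] = data["asd"].astype(int)
    fit = fit_gee(data, "asd", covs, "binomial_logit")
    if prs_grid is None:
        prs_grid = np.linspace(data["prs_z"].min(), data["prs_z"].max(), 9)
    rows = []
    result = fit.result
    for sex in ("male", "female"):
        for preterm in (0, 1):
            for z in prs_grid:
                counterfactual = data.copy()
                counterfactual["sex"] = sex
                counterfactual["preterm"] = preterm
                counterfactual["prs_z"] = z
                prob = float(np.mean(result.predict(counterfactual)))
                rows.append({"sex": sex, "preterm": preterm, "prs_z": float(z), "probability": prob})
    return fit, pd.DataFrame(rows)


def mcfadden_r2(
    cohort: pd.DataFrame,
    pc_cols: tuple[str, ...] = tuple(f"pc{i}" for i in range(1, 11)),
) -> tuple[float, float]:
    """McFadden pseudo-r2 of ASD status from PRS, by ordinary logistic fits.

    r2_full = 1 - ll(sex + PCs + PRS) / ll(intercept only); the increment
    subtracts the covariate-only pseudo-r2, isolating the PRS share. Both
    are reported because either convention is common.
    """
    have_pcs = [c for c in pc_cols if c in cohort.columns]
    data = cohort.copy()
    data["asd"] = data["asd"].astype(int)
    ll_null = _logit_ll(data, [])
    ll_red = _logit_ll(data, ["sex"] + have_pcs)
    ll_full = _logit_ll(data, ["sex"] + have_pcs + ["prs_z"])
    r2_full = 1.0 - ll_full / ll_null
    r2_increment = r2_full - (1.0 - ll_red / ll_null)
    return float(r2_full), float(r2_increment)


def _logit_ll(data: pd.DataFrame, covariates: list[str]) -> float:
    formula = "asd ~ " + (" + ".join(covariates) if covariates else "1")
    model = sm.Logit.from_formula(formula, data=data)
    res = model.fit(disp=0)
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit failed to converge (possible separation)")
    return float(res.llf)
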