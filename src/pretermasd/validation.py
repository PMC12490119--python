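"""Simulation-based calibration checks for the whole pipeline.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stage, and returns the measured quantities: published-count
ratios, cascade specificity against planted artifacts, parameter-recovery
coverage for the clustered models, GEE/GLM degeneracy, classifier null
and positive controls, and the scoring contract. Both the acceptance
tests and ``scripts/acceptance.py`` are thin callers of this module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import cohort_counts
from .dnv_pipeline import apply_qc_cascade, build_parent_carrier_index, detect_candidates
from .gee_models import fit_gee
from .ml_predict import nested_cv
from .prs_assoc import score_individuals
from .synthetic_cohort import SimConfig, simulate_cohort

#: logistic-normal marginalization constant (16*sqrt(3)/(15*pi))^2
_ATTENUATION_C2 = 0.3457


def table1_preterm_percentages() -> dict[str, float]:
    """Preterm percentage among ASD participants per analysis subset,
    recomputed from the published group counts."""
    return {
        name: 100.0 * cohort_counts.preterm_fraction(name)
        for name in cohort_counts.ASD_GROUP_COUNTS
    }


def dnv_cascade_specificity(n_families: int = 200, seed: int = 0) -> dict[str, float]:
    """Plant artifacts in a synthetic cohort and audit the cascade.

    Returns the percentage of artifacts rejected by exactly their intended
    filter and the percentage of clean planted de novo variants retained
    (outlier exclusion off: specificity is a per-record property).
    """
    cfg = SimConfig(n_families=n_families, seed=seed)
    co = simulate_cohort(cfg)
    sex = dict(zip(co.pedigree["person_id"], co.pedigree["sex"]))
    candidates = detect_candidates(co.records_by_child, child_sex=sex)
    index = build_parent_carrier_index(co.records_by_child)
    calls, _ = apply_qc_cascade(candidates, index, co.regions, sd_k=None)
    by_key = {(c.child_id, c.variant_id): c for c in calls}

    n_art = len(co.truth.artifacts)
    n_correct = 0
    for art in co.truth.artifacts:
        call = by_key.get((art["child_id"], art["variant_id"]))
        if call is not None and call.rejected_by and call.rejected_by[0] == art["expected_filter"]:
            n_correct += 1
    clean = [(ch, v) for ch, vs in co.truth.true_dnv_ids.items() for v in vs]
    n_clean_kept = sum(1 for key in clean if key in by_key and by_key[key].passed)
    # the per-child mean is reported for the baseline group, i.e. outside the
    # ASD-preterm cell whose rate the generator deliberately multiplies
    ch = co.children
    baseline_ids = set(ch.loc[~(ch["asd"] & ch["preterm"]), "person_id"])
    counts = [len(vs) for child, vs in co.truth.true_dnv_ids.items() if child in baseline_ids]
    return {
        "n_artifacts": n_art,
        "artifact_rejection_pct": 100.0 * n_correct / n_art if n_art else float("nan"),
        "n_clean": len(clean),
        "clean_retained_pct": 100.0 * n_clean_kept / len(clean) if clean else float("nan"),
        "mean_dnv_per_child": float(np.mean(counts)),
    }


def parameter_recovery(
    n_reps: int = 50, n_families: int = 300, seed: int = 0
) -> dict[str, float]:
    """Coverage of the planted generative parameters by GEE robust 95% CIs.

    Per replicate: a fresh cohort; a family-clustered Poisson model of DNV
    count on the ASD-preterm indicator plus sex (truth: log rate ratio);
    and a family-clustered logistic model of ASD on sex, preterm, and PRS.
    The logistic truths are the population-averaged effects: the
    conditional (family-intercept) coefficients shrunk by the standard
    logistic-normal attenuation factor, since GEE estimates marginal
    effects.
    """
    base = SimConfig()
    shrink = 1.0 / np.sqrt(1.0 + _ATTENUATION_C2 * base.family_intercept_sd**2)
    truths = {
        "rate_ratio": np.log(base.burden_rate_ratio_asd_preterm),
        "male": base.male_effect_logOR * shrink,
        "preterm": base.preterm_effect_logOR * shrink,
        "prs": base.prs_effect_logOR * shrink,
    }
    hits = {k: 0 for k in truths}
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    for rep_seed in rep_seeds:
        cfg = SimConfig(n_families=n_families, seed=int(rep_seed))
        ch = simulate_cohort(cfg, emit_variants=False).children.copy()
        ch["asd_preterm"] = (ch["asd"] & ch["preterm"]).astype(int)
        ch["count"] = ch["dnv_count"]
        pois = fit_gee(ch, "count", ["asd_preterm", "sex"], "poisson_log")
        lo, hi = pois.ci("asd_preterm")
        hits["rate_ratio"] += lo <= truths["rate_ratio"] <= hi
        ch["asd"] = ch["asd"].astype(int)
        ch["preterm"] = ch["preterm"].astype(int)
        logit = fit_gee(ch, "asd", ["sex", "preterm", "prs_z"], "binomial_logit")
        for key, term in (("male", "sex"), ("preterm", "preterm"), ("prs", "prs_z")):
            lo, hi = logit.ci(term)
            hits[key] += lo <= truths[key] <= hi
    return {f"coverage_{k}_pct": 100.0 * v / n_reps for k, v in hits.items()}


def gee_glm_degeneracy(seed: int = 0, n_families: int = 250) -> float:
    """Max |GEE - GLM| coefficient difference at cluster size one."""
    cfg = SimConfig(n_families=n_families, seed=seed, children_per_family={1: 1.0})
    ch = simulate_cohort(cfg, emit_variants=False).children.copy()
    ch["count"] = ch["dnv_count"]
    ch["preterm"] = ch["preterm"].astype(int)
    gee = fit_gee(ch, "count", ["preterm", "sex"], "poisson_log",
                  working_corr="independence")
    glm = sm.GLM.from_formula("count ~ preterm + sex", data=ch,
                              family=sm.families.Poisson()).fit()
    return float(np.abs(gee.coefs.values - glm.params.values).max())


_FEATURES = ["sex", "gestational_age_weeks", "birth_complications",
             "insufficient_oxygen", "dnv_count", "prs_z"]
_FAST_GRID = [{"n_estimators": [50], "max_depth": [2, 3]}]


def _feature_table(n_families: int, seed: int):
    from .ml_predict import assemble_features

    cfg = SimConfig(n_families=n_families, seed=seed)
    ch = simulate_cohort(cfg, emit_variants=False).children
    return assemble_features(ch, _FEATURES)


def ml_null_control(
    n_permutations: int = 20, n_families: int = 250, seed: int = 0
) -> dict[str, float]:
    """Median pooled out-of-fold AUROC under label permutation."""
    X, y = _feature_table(n_families, seed)
    rng = np.random.default_rng(seed)
    aurocs = []
    for i in range(n_permutations):
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        res = nested_cv(X, y_perm, "xgboost", grid=[{"n_estimators": [50], "max_depth": [2]}],
                        seed=seed + i, outer_folds=5, inner_folds=2, inner_repeats=1)
        aurocs.append(res.metrics["auroc"])
    return {"null_auroc_median": float(np.median(aurocs))}


def ml_positive_control(
    n_seeds: int = 5, n_families: int = 250, seed: int = 0
) -> dict[str, float]:
    """Pooled out-of-fold AUROC on cohorts with the planted birth effects."""
    aurocs = []
    for i in range(n_seeds):
        X, y = _feature_table(n_families, seed + i)
        res = nested_cv(X, y, "xgboost", grid=_FAST_GRID, seed=seed + i,
                        outer_folds=10, inner_folds=3, inner_repeats=1)
        aurocs.append(res.metrics["auroc"])
    return {
        "planted_auroc_min": float(np.min(aurocs)),
        "planted_auroc_mean": float(np.mean(aurocs)),
    }


def prs_contract(seed: int = 0, n_families: int = 150) -> dict[str, float]:
    """Standardization, allele-flip, and linearity contracts of the scorer."""
    cfg = SimConfig(n_families=n_families, seed=seed)
    co = simulate_cohort(cfg, emit_variants=False)
    results, _ = score_individuals(co.dosages, co.variants_meta, co.prs_weights)
    z = np.array([r.z_score for r in results])

    flipped = co.prs_weights.copy()
    flip_mask = np.arange(len(flipped)) % 2 == 0
    ref = co.variants_meta.set_index("variant_id")["ref"]
    flipped.loc[flip_mask, "effect_allele"] = ref.loc[
        flipped.loc[flip_mask, "variant_id"]
    ].to_numpy()
    flipped.loc[flip_mask, "weight"] = -flipped.loc[flip_mask, "weight"]
    z_flip = np.array(
        [r.z_score for r in score_individuals(co.dosages, co.variants_meta, flipped)[0]]
    )

    w1 = co.prs_weights.copy()
    w2 = co.prs_weights.copy()
    rng = np.random.default_rng(seed)
    w2["weight"] = rng.normal(0, 0.1, len(w2))
    wsum = w1.copy()
    wsum["weight"] = w1["weight"] + w2["weight"]
    r1 = np.array([r.raw_score for r in score_individuals(co.dosages, co.variants_meta, w1)[0]])
    r2 = np.array([r.raw_score for r in score_individuals(co.dosages, co.variants_meta, w2)[0]])
    rs = np.array([r.raw_score for r in score_individuals(co.dosages, co.variants_meta, wsum)[0]])

    return {
        "z_mean_abs": float(abs(z.mean())),
        "z_sd_err": float(abs(z.std(ddof=0) - 1.0)),
        "allele_flip_max_z_diff": float(np.abs(z - z_flip).max()),
        "linearity_max_err": float(np.abs(r1 + r2 - rs).max()),
    }
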