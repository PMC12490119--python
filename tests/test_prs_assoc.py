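"""Polygenic scoring conventions and the ASD probability models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pretermasd.prs_assoc import (
    fit_probability_model,
    mcfadden_r2,
    prs_group_tests,
    score_individuals,
    scores_frame,
)


def _toy(weights_rows, dosage_rows, variants=None):
    variants = variants if variants is not None else pd.DataFrame(
        {"variant_id": ["v1", "v2"], "ref": ["A", "C"], "alt": ["G", "T"]}
    )
    weights = pd.DataFrame(weights_rows, columns=["variant_id", "effect_allele", "weight"])
    dosages = pd.DataFrame(dosage_rows["data"], index=dosage_rows["index"],
                           columns=dosage_rows["columns"])
    return dosages, variants, weights


def test_per_allele_average_convention():
    """One variant, weight 0.5, dosage 2: raw = (2 * 0.5) / (2 * 1) = 0.5."""
    dosages, variants, weights = _toy(
        [("v1", "G", 0.5)],
        {"data": [[2.0], [0.0]], "index": ["p1", "p2"], "columns": ["v1"]},
        variants=pd.DataFrame({"variant_id": ["v1"], "ref": ["A"], "alt": ["G"]}),
    )
    results, _ = score_individuals(dosages, variants, weights)
    raw = {r.person_id: r.raw_score for r in results}
    assert raw == {"p1": pytest.approx(0.5), "p2": pytest.approx(0.0)}
    total = {r.person_id: r.raw_score for r in
             score_individuals(dosages, variants, weights, mode="sum")[0]}
    assert total["p1"] == pytest.approx(1.0)


def test_z_scores_standardized():
    rng = np.random.default_rng(0)
    dosages = pd.DataFrame(rng.integers(0, 3, size=(50, 2)).astype(float),
                           index=[f"p{i}" for i in range(50)], columns=["v1", "v2"])
    variants = pd.DataFrame({"variant_id": ["v1", "v2"], "ref": ["A", "C"], "alt": ["G", "T"]})
    weights = pd.DataFrame({"variant_id": ["v1", "v2"], "effect_allele": ["G", "T"],
                            "weight": [0.3, -0.2]})
    results, _ = score_individuals(dosages, variants, weights)
    z = np.array([r.z_score for r in results])
    assert abs(z.mean()) < 1e-8
    assert abs(z.std(ddof=0) - 1) < 1e-8


def test_allele_flip_invariance():
    """Restating a weight on the other allele with negated weight shifts all
    raw scores by a constant, leaving z-scores unchanged."""
    rng = np.random.default_rng(1)
    dosages = pd.DataFrame(rng.integers(0, 3, size=(30, 2)).astype(float),
                           index=[f"p{i}" for i in range(30)], columns=["v1", "v2"])
    variants = pd.DataFrame({"variant_id": ["v1", "v2"], "ref": ["A", "C"], "alt": ["G", "T"]})
    w_alt = pd.DataFrame({"variant_id": ["v1", "v2"], "effect_allele": ["G", "T"],
                          "weight": [0.4, 0.1]})
    w_flip = pd.DataFrame({"variant_id": ["v1", "v2"], "effect_allele": ["A", "T"],
                           "weight": [-0.4, 0.1]})
    za = np.array([r.z_score for r in score_individuals(dosages, variants, w_alt)[0]])
    zb = np.array([r.z_score for r in score_individuals(dosages, variants, w_flip)[0]])
    assert np.allclose(za, zb)
    audit = score_individuals(dosages, variants, w_flip)[1]
    assert audit.loc[0, "n_flipped"] == 1


def test_score_linearity_on_complete_genotypes():
    rng = np.random.default_rng(2)
    dosages = pd.DataFrame(rng.integers(0, 3, size=(20, 3)).astype(float),
                           index=[f"p{i}" for i in range(20)], columns=["v1", "v2", "v3"])
    variants = pd.DataFrame({"variant_id": ["v1", "v2", "v3"], "ref": list("AAA"),
                             "alt": list("GGG")})
    w1 = pd.DataFrame({"variant_id": ["v1", "v2", "v3"], "effect_allele": list("GGG"),
                       "weight": [0.1, 0.2, 0.3]})
    w2 = pd.DataFrame({"variant_id": ["v1", "v2", "v3"], "effect_allele": list("GGG"),
                       "weight": [0.5, -0.1, 0.0]})
    wsum = w1.copy()
    wsum["weight"] = w1["weight"] + w2["weight"]
    r1 = np.array([r.raw_score for r in score_individuals(dosages, variants, w1)[0]])
    r2 = np.array([r.raw_score for r in score_individuals(dosages, variants, w2)[0]])
    rs = np.array([r.raw_score for r in score_individuals(dosages, variants, wsum)[0]])
    assert np.allclose(r1 + r2, rs)


def test_mismatched_effect_allele_skipped():
    dosages = pd.DataFrame([[1.0]], index=["p1"], columns=["v1"])
    variants = pd.DataFrame({"variant_id": ["v1"], "ref": ["A"], "alt": ["G"]})
    weights = pd.DataFrame({"variant_id": ["v1", "v1b"], "effect_allele": ["T", "G"],
                            "weight": [0.5, 0.5]})
    with pytest.raises(ValueError):  # nothing usable -> zero variance
        score_individuals(dosages, variants, weights)


def test_zero_variance_errors():
    dosages = pd.DataFrame([[1.0], [1.0]], index=["p1", "p2"], columns=["v1"])
    variants = pd.DataFrame({"variant_id": ["v1"], "ref": ["A"], "alt": ["G"]})
    weights = pd.DataFrame({"variant_id": ["v1"], "effect_allele": ["G"], "weight": [0.0]})
    with pytest.raises(ValueError, match="variance"):
        score_individuals(dosages, variants, weights)


def test_generator_scores_match_package_scoring(people_cohort):
    """The package's scorer reproduces the generator's latent PRS exactly."""
    co = people_cohort
    results, _ = score_individuals(co.dosages, co.variants_meta, co.prs_weights)
    sf = scores_frame(results)
    merged = co.children.merge(sf, on="person_id")
    assert np.allclose(merged["prs_z_x"], merged["prs_z_y"])


def test_probability_model_recovers_monotone_effects(people_cohort):
    """With positive male/preterm/PRS liabilities, predicted ASD probability
    rises with PRS inside every sex x preterm cell and is highest for
    preterm males at the top of the PRS range."""
    ch = people_cohort.children
    fit, grid = fit_probability_model(ch)
    assert fit.coef("sex") > 0 and fit.coef("preterm") > 0 and fit.coef("prs_z") > 0
    assert ((grid["probability"] > 0) & (grid["probability"] < 1)).all()
    for (sex, pre), sub in grid.groupby(["sex", "preterm"]):
        probs = sub.sort_values("prs_z")["probability"].to_numpy()
        assert np.all(np.diff(probs) > 0)
    top = grid.sort_values("prs_z").groupby(["sex", "preterm"]).tail(1)
    best = top.sort_values("probability").iloc[-1]
    assert best["sex"] == "male" and best["preterm"] == 1


def test_interaction_term_null_when_absent(people_cohort):
    fit, _ = fit_probability_model(people_cohort.children, with_interaction=True)
    assert fit.p("preterm:prs_z") > 0.01  # generator plants no interaction


def test_group_tests_detect_planted_asd_shift(people_cohort):
    ch = people_cohort.children.copy()
    rng = np.random.default_rng(3)
    pcs = rng.normal(size=(len(ch), 10))
    for i in range(10):
        ch[f"pc{i+1}"] = pcs[:, i]
    contrasts = {
        "asd_vs_nonasd": (ch["asd"].astype(bool), ~ch["asd"].astype(bool)),
        "preterm_vs_term_in_asd": (ch["asd"] & ch["preterm"], ch["asd"] & ~ch["preterm"]),
    }
    res = prs_group_tests(ch, contrasts).set_index("contrast")
    # PRS raises ASD liability, so ASD children carry higher scores;
    # preterm status within ASD carries no planted PRS shift
    assert res.loc["asd_vs_nonasd", "wilcoxon_p"] < 1e-3
    assert res.loc["preterm_vs_term_in_asd", "wilcoxon_p"] > 0.01


def test_mcfadden_matches_brute_force_loglik():
    """Pseudo-r2 equals 1 - ll_full/ll_null with log-likelihoods computed
    directly from predicted probabilities."""
    rng = np.random.default_rng(4)
    n = 400
    prs = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-0.3 + 0.8 * prs)))
    df = pd.DataFrame({
        "asd": (rng.random(n) < p).astype(int),
        "prs_z": prs,
        "sex": rng.choice(["male", "female"], n),
    })
    r2_full, r2_inc = mcfadden_r2(df, pc_cols=())
    import statsmodels.api as sm

    full = sm.Logit.from_formula("asd ~ sex + prs_z", data=df).fit(disp=0)
    probs = full.predict(df)
    ll_full = np.sum(df["asd"] * np.log(probs) + (1 - df["asd"]) * np.log(1 - probs))
    base = df["asd"].mean()
    ll_null = np.sum(df["asd"] * np.log(base) + (1 - df["asd"]) * np.log(1 - base))
    assert r2_full == pytest.approx(1 - ll_full / ll_null, abs=1e-8)
    assert 0 < r2_inc <= r2_full


def test_mcfadden_null_increment_near_zero():
    rng = np.random.default_rng(5)
    n = 500
    df = pd.DataFrame({
        "asd": rng.integers(0, 2, n),
        "prs_z": rng.normal(size=n),
        "sex": rng.choice(["male", "female"], n),
    })
    _, r2_inc = mcfadden_r2(df, pc_cols=())
    assert abs(r2_inc) < 0.02
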