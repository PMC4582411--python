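import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitdmr import (
    AssocResult,
    SimConfig,
    approximate_score_effect,
    combine_with_consortium,
    dl_tau2,
    emit_summary_stats,
    fit_linear,
    meta_analyse,
    meta_fixed,
    meta_random,
    meta_regression,
    select_model,
    simulate_prepared_cohort,
)
from vitdmr.scores import default_scores

TWO_STUDIES = [(0.0, 0.1, "a"), (1.0, 0.1, "b")]


def test_single_study_identity():
    res = meta_fixed([(1.2, 0.4, "only")])
    assert (res.beta, res.se) == (1.2, 0.4)
    assert res.q == 0.0 and res.i2 == 0.0


def test_two_equal_studies_closed_form():
    res = meta_fixed([(1.0, 0.5, "a"), (1.0, 0.5, "b")])
    assert res.beta == pytest.approx(1.0, abs=1e-12)
    assert res.se == pytest.approx(0.5 / np.sqrt(2), abs=1e-12)


def test_heterogeneous_pair_hand_calculation():
    """w=100 each: pooled 0.5, Q=50, I2=98%; DL tau2=0.49, random se 0.5."""
    fixed = meta_fixed(TWO_STUDIES)
    assert fixed.beta == pytest.approx(0.5, abs=1e-10)
    assert fixed.q == pytest.approx(50.0, abs=1e-10)
    assert fixed.i2 == pytest.approx(98.0, abs=1e-10)
    assert dl_tau2(TWO_STUDIES) == pytest.approx(0.49, abs=1e-10)
    random = meta_random(TWO_STUDIES)
    assert random.beta == pytest.approx(0.5, abs=1e-10)
    assert random.se == pytest.approx(0.5, abs=1e-10)


def test_random_equals_fixed_when_homogeneous():
    ests = [(1.0, 0.5, "a"), (1.0, 0.5, "b"), (1.0, 0.5, "c")]
    f, r = meta_fixed(ests), meta_random(ests)
    assert r.tau2 == 0.0
    assert r.beta == pytest.approx(f.beta, abs=1e-15)
    assert r.se == pytest.approx(f.se, abs=1e-15)


def test_against_statsmodels_combine_effects():
    """Independent cross-check of fixed and DL-random pooling."""
    from statsmodels.stats.meta_analysis import combine_effects

    betas = np.array([0.2, -0.1, 0.45, 0.05, 0.3])
    ses = np.array([0.12, 0.2, 0.15, 0.3, 0.1])
    ref = combine_effects(betas, ses**2, method_re="dl")
    ests = list(zip(betas, ses, "abcde"))
    fixed, random = meta_fixed(ests), meta_random(ests)
    frame = ref.summary_frame()
    assert fixed.beta == pytest.approx(frame.loc["fixed effect", "eff"], abs=1e-8)
    assert random.beta == pytest.approx(frame.loc["random effect", "eff"], abs=1e-8)
    assert fixed.q == pytest.approx(ref.q, abs=1e-8)
    assert random.tau2 == pytest.approx(ref.tau2, abs=1e-8)


def test_model_selection_rule():
    assert select_model(meta_fixed([(1.0, 0.5, "a"), (1.1, 0.5, "b")])) == "fixed"
    assert select_model(meta_fixed(TWO_STUDIES)) == "random"
    # boundary: p_q equal to alpha stays fixed (strict inequality)
    fixed = meta_fixed(TWO_STUDIES)
    assert select_model(fixed, alpha_q=fixed.p_q) == "fixed"
    hetero = meta_analyse(TWO_STUDIES)
    assert hetero.model == "random"


def test_errors():
    with pytest.raises(ValueError):
        meta_fixed([])
    with pytest.raises(ValueError):
        meta_random([(1.0, 0.5, "a")])
    with pytest.raises(ValueError, match="constant covariate"):
        meta_regression([(0, 0.1, "a"), (1, 0.1, "b"), (2, 0.1, "c")], [1.0, 1.0, 1.0])


@given(
    betas=st.lists(st.floats(-2, 2), min_size=2, max_size=8),
    scale=st.floats(0.1, 10),
)
@settings(derandomize=True, max_examples=40)
def test_pooled_se_and_i2_invariance(betas, scale):
    """Fixed pooled SE never exceeds the smallest input SE; I2 is invariant
    to rescaling all betas and SEs by a common constant."""
    ests = [(b, 0.2 + 0.1 * i, f"s{i}") for i, b in enumerate(betas)]
    res = meta_fixed(ests)
    assert res.se <= min(e[1] for e in ests) + 1e-12
    scaled = [(b * scale, s * scale, l) for b, s, l in ests]
    assert meta_fixed(scaled).i2 == pytest.approx(res.i2, abs=1e-8)


def test_meta_regression_exact_linear_fit():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    ests = [(0.5 + 0.3 * xi, 0.2, f"s{i}") for i, xi in enumerate(x)]
    slope, se, p = meta_regression(ests, x)
    assert slope == pytest.approx(0.3, abs=1e-10)  # equals the OLS slope
    # exact fit: residual Q is zero, so no between-study variance is added
    assert se == pytest.approx(0.2 / np.sqrt(np.sum((x - x.mean()) ** 2)), abs=1e-10)
    assert 0 < p < 0.01


def test_meta_regression_two_level_covariate_equals_subgroup_difference():
    """Equal SEs: the slope on a binary study-level factor equals the
    difference of subgroup fixed-effect means."""
    ests = [(0.1, 0.3, "a"), (0.3, 0.3, "b"), (0.9, 0.3, "c"), (1.1, 0.3, "d")]
    x = [0, 0, 1, 1]
    slope, _, _ = meta_regression(ests, x)
    lo = meta_fixed(ests[:2]).beta
    hi = meta_fixed(ests[2:]).beta
    assert slope == pytest.approx(hi - lo, abs=1e-10)


def test_meta_regression_null_covariate_centred_on_zero():
    rng = np.random.default_rng(13)
    zs = []
    for _ in range(60):
        betas = rng.normal(0.2, 0.05, size=8)
        x = rng.normal(size=8)
        slope, se, _ = meta_regression([(b, 0.05, f"s{i}") for i, b in enumerate(betas)], x)
        zs.append(slope / se)
    assert abs(np.mean(zs)) < 3 / np.sqrt(len(zs))


def test_dl_tau2_recovery_by_simulation():
    """DL estimate of between-study variance is unbiased-ish at tau2=0.04."""
    rng = np.random.default_rng(17)
    tau2_hat = []
    for _ in range(200):
        truths = rng.normal(0.5, np.sqrt(0.04), size=20)
        ses = np.full(20, 0.1)
        obs = rng.normal(truths, ses)
        tau2_hat.append(dl_tau2(list(zip(obs, ses, [str(i) for i in range(20)]))))
    assert np.mean(tau2_hat) == pytest.approx(0.04, abs=0.01)


SYNTH = default_scores()["synthesis"]


def test_approximate_score_effect_closed_forms():
    rows = pd.DataFrame(
        [
            {"snp_id": SYNTH.snp_ids[0], "eaf": 0.5, "beta": 0.1, "se": 0.02, "n": 100},
            {"snp_id": SYNTH.snp_ids[1], "eaf": 0.5, "beta": 0.3, "se": 0.02, "n": 100},
        ]
    )
    res = approximate_score_effect(rows, SYNTH)
    assert res.beta == pytest.approx(0.2, abs=1e-12)  # equal-variance average
    # one SNP's dosage variance -> 0: the other SNP's beta dominates
    rows.loc[0, "eaf"] = 1e-6
    res = approximate_score_effect(rows, SYNTH)
    assert res.beta == pytest.approx(0.3, abs=1e-4)


def test_approximate_score_effect_missing_inputs():
    rows = pd.DataFrame([
        {"snp_id": SYNTH.snp_ids[0], "eaf": 0.5, "beta": 0.1, "se": 0.02, "n": 100},
    ])
    with pytest.raises(KeyError, match="missing summary row"):
        approximate_score_effect(rows, SYNTH)


def test_approximation_matches_individual_level_regression():
    """Central oracle: the summary-statistic score approximation agrees with
    the individual-level score regression."""
    cohort = simulate_prepared_cohort(SimConfig(n_individuals=20_000, seed=19))
    summary = emit_summary_stats(cohort, "ln25ohd")
    approx = approximate_score_effect(summary, SYNTH, outcome="ln25ohd")
    from vitdmr.regression import BASE_COVARIATES, OHD_EXTRA_COVARIATES

    direct = fit_linear(
        cohort, "ln25ohd", "score_synthesis", BASE_COVARIATES + OHD_EXTRA_COVARIATES
    )
    combined_se = np.hypot(approx.se, direct.se)
    assert abs(approx.beta - direct.beta) < 3 * combined_se


def test_combine_with_consortium_limits():
    cohort_pool = meta_fixed([(1.0, 0.2, "a"), (1.0, 0.2, "b")])
    inf_se = AssocResult("consortium_a", "score_synthesis", "sbp", 5.0, float("inf"), 1000)
    out = combine_with_consortium(cohort_pool, inf_se)
    assert out.beta == pytest.approx(cohort_pool.beta, abs=1e-12)
    assert out.se == pytest.approx(cohort_pool.se, abs=1e-12)
    equal = AssocResult("consortium_a", "score_synthesis", "sbp", 1.0, 0.1, 1000)
    out = combine_with_consortium(cohort_pool, equal)
    assert out.beta == pytest.approx(1.0, abs=1e-12)
    assert out.se < min(cohort_pool.se, equal.se)
    with pytest.raises(ValueError, match="scale"):
        combine_with_consortium(cohort_pool, equal, scale="per_allele_log_odds")


def test_combined_strata_beat_either_stratum():
    """Pooling two strata from one truth reduces RMSE."""
    rng = np.random.default_rng(23)
    truth = 0.3
    err_a, err_b, err_c = [], [], []
    for _ in range(300):
        a = rng.normal(truth, 0.2)
        b = rng.normal(truth, 0.25)
        pooled = combine_with_consortium(
            meta_fixed([(a, 0.2, "a")]),
            AssocResult("consortium", "x", "y", b, 0.25, 100),
        )
        err_a.append((a - truth) ** 2)
        err_b.append((b - truth) ** 2)
        err_c.append((pooled.beta - truth) ** 2)
    assert np.mean(err_c) < min(np.mean(err_a), np.mean(err_b))
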