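import dataclasses

import numpy as np
import pandas as pd
import pytest

from vitdmr import (
    ConfigurationError,
    SimConfig,
    emit_summary_stats,
    fit_linear,
    generate_cohort,
    generate_multi_study,
    meta_fixed,
    simulate_prepared_cohort,
)
from vitdmr.regression import BASE_COVARIATES, OHD_EXTRA_COVARIATES

from conftest import zero_effect_panel


def quiet_config(**kw):
    """Config with every systematic effect switched off."""
    base = dict(
        snps=zero_effect_panel(),
        mu_ln25ohd=4.0,
        seasonal_amplitude=0.0,
        confounder_effects={},
        confounder_bp_effects={},
        sd_ln25ohd=0.0,
        sd_sbp=0.0,
        sd_dbp=0.0,
        treatment_model={"intercept": -30.0, "slope": 0.0},
    )
    base.update(kw)
    return SimConfig(**base)


def test_degenerate_noise_free_case():
    """With all effects and SDs zero, ln 25(OH)D is exactly the baseline."""
    cohort = generate_cohort(quiet_config(n_individuals=200, seed=1))
    assert np.all(cohort["ln25ohd"] == 4.0)
    assert np.all(cohort["sbp_observed"] == 130.0)
    assert not cohort["on_meds"].any()
    # seasonal term re-enabled: values deviate by at most the amplitude
    seasonal = generate_cohort(quiet_config(n_individuals=200, seed=1, seasonal_amplitude=0.2))
    assert np.all(np.abs(seasonal["ln25ohd"] - 4.0) <= 0.2 + 1e-12)


def test_dosage_moments_match_binomial():
    """Mean dosage is within 3 Monte-Carlo SEs of 2*EAF (HWE, independence)."""
    panel = tuple(dataclasses.replace(s, eaf=0.5) for s in zero_effect_panel())
    cohort = generate_cohort(SimConfig(n_individuals=50_000, seed=3, snps=panel))
    mc_se = np.sqrt(2 * 0.5 * 0.5 / 50_000)
    for s in panel:
        assert abs(cohort[s.snp_id].mean() - 1.0) < 3 * mc_se


def test_hwe_genotype_proportions():
    cohort = generate_cohort(SimConfig(n_individuals=20_000, seed=4))
    for s in SimConfig().snps:
        counts = cohort[s.snp_id].value_counts(normalize=True)
        p = s.eaf
        expected = {2.0: p**2, 1.0: 2 * p * (1 - p), 0.0: (1 - p) ** 2}
        for g, freq in expected.items():
            se = np.sqrt(freq * (1 - freq) / 20_000)
            assert abs(counts.get(g, 0.0) - freq) < 4 * se


def test_snp_effect_recovery_by_ols():
    """OLS of ln 25(OH)D on a dosage recovers the generative beta."""
    panel = list(zero_effect_panel())
    panel[0] = dataclasses.replace(panel[0], beta_ln_25ohd=0.03)
    cfg = SimConfig(n_individuals=40_000, seed=5, snps=tuple(panel), seasonal_amplitude=0.0,
                    confounder_effects={})
    cohort = generate_cohort(cfg)
    res = fit_linear(cohort, "ln25ohd", panel[0].snp_id)
    assert abs(res.beta - 0.03) < 3 * res.se


def test_determinism_byte_identical(tmp_path):
    cfg = SimConfig(n_individuals=500, seed=9, study_id="s")
    a, b = generate_cohort(cfg), generate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    a.to_csv(pa, sep="\t", index=False)
    b.to_csv(pb, sep="\t", index=False)
    assert pa.read_bytes() == pb.read_bytes()


def test_multi_study_streams_decorrelated():
    """Same seed, different study labels -> independent draws."""
    cfgs = [
        SimConfig(n_individuals=5000, seed=7, study_id="a"),
        SimConfig(n_individuals=5000, seed=7, study_id="b"),
    ]
    a, b = generate_multi_study(cfgs)
    assert not np.array_equal(a["ln25ohd"], b["ln25ohd"])
    r = np.corrcoef(a["ln25ohd"], b["ln25ohd"])[0, 1]
    assert abs(r) < 4 / np.sqrt(5000)


def test_multi_study_single_and_duplicates():
    cfg = SimConfig(n_individuals=100, seed=2, study_id="only")
    (one,) = generate_multi_study([cfg])
    pd.testing.assert_frame_equal(one, generate_cohort(cfg))
    with pytest.raises(ValueError, match="duplicate"):
        generate_multi_study([cfg, cfg])
    with pytest.raises(ValueError, match="at least one"):
        generate_multi_study([])


def test_homogeneous_studies_show_no_heterogeneity():
    """20 studies from one truth: score-exposure meta has I2 near zero."""
    cfgs = [
        SimConfig(n_individuals=800, seed=21, study_id=f"s{i}") for i in range(20)
    ]
    results = []
    for cohort in generate_multi_study(cfgs):
        res = fit_linear(cohort, "ln25ohd", "rs12794714")
        results.append((res.beta, res.se, res.study_id))
    meta = meta_fixed(results)
    assert meta.i2 < 30.0
    assert meta.p_q > 0.05


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimConfig(sd_sbp=-1.0)
    with pytest.raises(ConfigurationError):
        SimConfig(mu_ln25ohd=float("nan"))
    with pytest.raises(ConfigurationError):
        SimConfig(treatment_effect_sbp=-5.0)


def test_emit_summary_stats_matches_direct_regression(null_cohort):
    """Summary-table betas are bit-for-bit the adjusted single-SNP fits."""
    table = emit_summary_stats(null_cohort, "sbp")
    for _, row in table.iterrows():
        direct = fit_linear(null_cohort, "sbp", row["snp_id"], BASE_COVARIATES)
        assert row["beta"] == direct.beta
        assert row["se"] == direct.se
        assert row["n"] == direct.n
        assert row["eaf"] == null_cohort[row["snp_id"]].mean() / 2.0
    # 25(OH)D outcome adds month/batch to the adjustment set
    ohd = emit_summary_stats(null_cohort, "ln25ohd")
    direct = fit_linear(
        null_cohort, "ln25ohd", "rs12785878", BASE_COVARIATES + OHD_EXTRA_COVARIATES
    )
    assert ohd.set_index("snp_id").loc["rs12785878", "beta"] == direct.beta


def test_emit_summary_stats_rejects_unknown_outcome(null_cohort):
    with pytest.raises(ValueError, match="unknown outcome"):
        emit_summary_stats(null_cohort, "pulse")


def test_null_simulation_summary_betas_centred_on_zero():
    """With no causal effect, per-SNP BP betas are jointly centred on 0."""
    zs = []
    for i in range(12):
        cohort = simulate_prepared_cohort(
            SimConfig(n_individuals=1200, seed=100 + i, study_id=f"r{i}")
        )
        table = emit_summary_stats(cohort, "dbp")
        zs.extend(table["beta"] / table["se"])
    zs = np.asarray(zs)
    assert abs(zs.mean()) < 3 / np.sqrt(len(zs))
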