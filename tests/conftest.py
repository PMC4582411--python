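import dataclasses

import pytest

from vitdmr import SimConfig, simulate_prepared_cohort
from vitdmr.scores import DEFAULT_PANEL


def zero_effect_panel(beta: float = 0.0):
    """Panel with all per-allele ln-25(OH)D effects set to `beta`."""
    return tuple(dataclasses.replace(s, beta_ln_25ohd=beta) for s in DEFAULT_PANEL)


@pytest.fixture(scope="session")
def null_cohort():
    """Prepared cohort with no causal 25(OH)D->BP effect (defaults)."""
    return simulate_prepared_cohort(SimConfig(n_individuals=2500, seed=11, study_id="null"))


@pytest.fixture(scope="session")
def causal_cohort():
    """Prepared cohort with a real diastolic effect of ln 25(OH)D."""
    cfg = SimConfig(
        n_individuals=4000, seed=12, study_id="causal", causal_effect_dbp=-3.0,
        causal_effect_sbp=-3.0,
    )
    return simulate_prepared_cohort(cfg)
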