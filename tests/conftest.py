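import numpy as np
import pandas as pd
import pytest

from rrscore.preprocessing import OUTCOME_NAMES, Standardizer, build_design, \
    derive_outcomes, orient_outcomes
from rrscore.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Complete 50-subject cohort with moderate noise."""
    cfg = SimConfig(n_subjects=50, seed=11, noise_sd=0.5)
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free cohort: derived outcomes are exactly the latent targets."""
    cfg = SimConfig(n_subjects=50, seed=3, noise_sd=0.0)
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def standardized_small(small_cohort):
    """Standardized design + outcomes for the small cohort (whole-data fit)."""
    cfg, table, truth = small_cohort
    outcomes = orient_outcomes(derive_outcomes(table))
    cont = [s.name for s in cfg.predictor_specs if s.kind == "continuous"]
    std = Standardizer().fit(
        pd.concat([table[cont], outcomes], axis=1), cont + list(OUTCOME_NAMES)
    )
    design = build_design(table, cfg.predictor_specs, std)
    return cfg, table, truth, design, std.transform(outcomes)


def oriented_targets(truth, outcomes):
    """Recover latent targets from derived outcomes via the stored offsets/scales."""
    from rrscore.preprocessing import OUTCOME_ORIENTATION

    rec = np.empty((len(outcomes), len(truth.outcome_names)))
    for i, name in enumerate(truth.outcome_names):
        flip = OUTCOME_ORIENTATION[name]
        rec[:, i] = (outcomes[name].to_numpy() - flip * truth.offsets[name]) \
            / truth.scales[name]
    return rec
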