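import numpy as np
import pytest

from mirdose.design import default_design
from mirdose.normalize import cpm, log2fc_baseline, normalized_log2_cpm, prefilter_features, tmm_factors
from mirdose.synthetic import PlantedTruth, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with the default planted markers."""
    cfg = SimulationConfig(n_features=120, seed=42)
    counts, meta, truth = simulate_cohort(cfg, default_design())
    return counts, meta, truth


@pytest.fixture(scope="session")
def null_cohort():
    """500-feature cohort with no planted effects, for calibration checks."""
    cfg = SimulationConfig(n_features=500, planted=PlantedTruth(), seed=7)
    counts, meta, _ = simulate_cohort(cfg, default_design())
    return counts, meta


@pytest.fixture(scope="session")
def normalized(planted_cohort):
    counts, meta, truth = planted_cohort
    filtered = prefilter_features(counts)
    factors = tmm_factors(filtered)
    cpm_values = cpm(filtered, factors)
    return {
        "counts": filtered,
        "meta": meta,
        "truth": truth,
        "cpm": cpm_values,
        "expr": normalized_log2_cpm(cpm_values),
        "fc": log2fc_baseline(cpm_values, meta),
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
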