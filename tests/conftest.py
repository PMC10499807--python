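"""Shared fixtures: simulated cohorts and (expensive) workflow reports.

Workflow fixtures are session-scoped so the end-to-end and reproducibility
checks reuse one run instead of repeating multi-second constructions.
"""

import numpy as np
import pandas as pd
import pytest

from melb.pipeline import (PipelineConfig, run_diagnostic_workflow,
                           run_prognostic_workflow)
from melb.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The reference scenario: 50/50 serum groups, planted effects 0.3."""
    cfg = SimulationConfig(seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for structural checks."""
    cfg = SimulationConfig(
        seed=5, n_probes=900, n_serum_mng=20,
        n_serum_nonmng={"glioma": 8, "glioblastoma": 4, "pituitary": 4,
                        "control": 4},
        n_tissue_mng_extra=20, n_tissue_control=10,
        n_signature_diag=40, n_signature_prog=30, n_cluster_probes=20,
        n_gbm_probes=20, n_immune_probes=100)
    return simulate_cohort(cfg)


def fast_pipeline_config(seed: int, **sim_overrides) -> PipelineConfig:
    cfg = PipelineConfig(seed=seed, fast_mode=True)
    cfg.simulation = SimulationConfig(seed=seed, **sim_overrides)
    return cfg


@pytest.fixture(scope="session")
def diagnostic_report():
    return run_diagnostic_workflow(fast_pipeline_config(11))


@pytest.fixture(scope="session")
def diagnostic_report_rerun():
    return run_diagnostic_workflow(fast_pipeline_config(11))


@pytest.fixture(scope="session")
def prognostic_report():
    return run_prognostic_workflow(fast_pipeline_config(11))


@pytest.fixture(scope="session")
def prognostic_report_rerun():
    return run_prognostic_workflow(fast_pipeline_config(11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
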