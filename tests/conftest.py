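"""Shared fixtures: small synthetic sessions and simulated cohorts."""

import numpy as np
import pytest

import gammasync as gs


@pytest.fixture(scope="session")
def small_session():
    """Two 8-contact probes 2.5 mm apart, 9 conditions x 12 trials."""
    cfg = gs.default_session_config(
        probes=[gs.ProbeGeometry(n_contacts=8, position_mm=0.0, n_superficial=6),
                gs.ProbeGeometry(n_contacts=8, position_mm=2.5, n_superficial=6)],
        n_trials=12,
    )
    return gs.generate_session(cfg, seed=101)


@pytest.fixture(scope="session")
def small_session_analysis(small_session):
    cfg = gs.AnalysisConfig(channels_per_probe=2)
    return gs.run_session_analysis(small_session, cfg)


@pytest.fixture(scope="session")
def recovery_cohort_analysis():
    """Oscillator cohort spanning detuning and coupling, fully analyzed."""
    cohort = gs.make_cohort(
        delta_omegas=np.arange(-6.0, 6.1, 1.5),
        distances=[1.0, 2.5, 4.0, 5.5],
    )
    return cohort, gs.run_cohort_analysis(cohort, sigma=18.0, n_trials=80, seed=12345)
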