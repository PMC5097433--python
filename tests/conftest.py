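"""Shared fixtures: small simulated studies reused across test modules."""

from __future__ import annotations

import pytest

import dictycore as dc


@pytest.fixture(scope="session")
def small_config() -> dc.SimulationConfig:
    """A reduced study used by fast structural tests."""
    return dc.SimulationConfig(
        seed=11,
        n_families_conserved=25,
        n_species_specific_per_species=6,
        frac_core_dev=0.2,
        library_size_per_stage=100_000,
        cds_length_range=(300, 900),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    catalogue, truth = dc.simulate_families(small_config)
    counts = dc.simulate_counts(catalogue, truth, small_config, include_ax4=True)
    return small_config, catalogue, truth, counts


@pytest.fixture(scope="session")
def default_pipeline() -> dc.PipelineResult:
    """The full pipeline on the default seeded study (the planted-signal
    fixture: 100 conserved families, 10 % core, fold 4-20, dispersion 0.2,
    asynchrony 0.3, seed 42).  Session-scoped: it is the slow fixture."""
    return dc.run_pipeline(dc.SimulationConfig())
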