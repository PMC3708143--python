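"""Shared fixtures: the packaged 10-cluster dataset and its summaries."""

import pytest

import sparsesynergy as ss


@pytest.fixture(scope="session")
def fig2_config():
    return ss.figure2_config()


@pytest.fixture(scope="session")
def fig2_dataset(fig2_config):
    """Seeded burst table + ground truth for the packaged fixture."""
    df, truth = ss.generate_burst_dataset(fig2_config, seed=1)
    return df, truth


@pytest.fixture(scope="session")
def fig2_control_stats(fig2_dataset):
    df, _ = fig2_dataset
    stats, _ = ss.summarize_condition(df, "unobstructed")
    return stats


@pytest.fixture(scope="session")
def fig2_reference(fig2_control_stats):
    return ss.cluster_bursts(fig2_control_stats)
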