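import pytest

from clonoscope import (ArtifactRates, SimConfig, clean_airr, count_clonotypes,
                        log_normalize, merge_samples, pair_chains, simulate)


@pytest.fixture(scope="session")
def sim_default():
    """Artifact-free dataset at the default study conditions:
    500 αβ + 50 γδ cells, dominant clone at 30% of αβ cells in 'Post'."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_artifacts():
    """Medium dataset with every artifact type injected."""
    return simulate(SimConfig(
        n_ab_cells=200, n_gd_cells=30, n_b_cells=15, seed=5,
        artifact_rates=ArtifactRates(utr=0.1, missing_c_call=0.15,
                                     unpaired=0.05, multiplet=0.08),
    ))


@pytest.fixture(scope="session")
def paired_default(sim_default):
    paired, report = pair_chains(clean_airr(sim_default.airr))
    return paired, report


@pytest.fixture(scope="session")
def pipeline_state(sim_default, paired_default):
    """Merged + normalized expression alongside paired cells and counts."""
    paired, _ = paired_default
    norm = log_normalize(merge_samples(sim_default.expression))
    counts = count_clonotypes(paired)
    return norm, paired, counts
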