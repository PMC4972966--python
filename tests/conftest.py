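import pytest

from retroforge.detection import DetectionParams
from retroforge.homology import ProteinAligner
from retroforge.pipeline import run_pipeline
from retroforge.simulate import SimulationConfig, simulate_cohort

ZERO_RATES = dict(rate_to_ancestor=0.0, rate_to_A=0.0, rate_to_B=0.0, rate_to_outgroup=0.0)


def expected_detectable(events):
    """Planted retrocopies the cascade should report: every 1-CDE retro copy
    (ancestral, lineage, truncated, duplicated) minus the intron-gained
    orthologs (no longer 1-CDE) and the confounders (filtered by design)."""
    gained = {g for e in events if e.event_type == "intron_gain" for g in e.gene_ids}
    out = set()
    for e in events:
        if e.event_type in ("retroposition_ancestral", "retroposition_lineage"):
            out.update(e.gene_ids)
        elif e.event_type == "retro_duplication":
            out.add(e.gene_ids[0])
    return out - gained


def confounder_ids(events):
    return {
        g
        for e in events
        if e.event_type in ("segmental_duplication", "te_insertion")
        for g in e.gene_ids
    }


@pytest.fixture(scope="session")
def aligner():
    return ProteinAligner()


@pytest.fixture(scope="session")
def params():
    return DetectionParams()


@pytest.fixture(scope="session")
def zero_cohort():
    cfg = SimulationConfig(seed=11, **ZERO_RATES)
    genomes, events = simulate_cohort(cfg)
    return cfg, genomes, events


@pytest.fixture(scope="session")
def default_cohort():
    cfg = SimulationConfig(seed=3)
    genomes, events = simulate_cohort(cfg)
    return cfg, genomes, events


@pytest.fixture(scope="session")
def default_result(default_cohort):
    """Full pipeline output on the default cohort (dN/dS included)."""
    _, genomes, _ = default_cohort
    return run_pipeline(genomes, ("A", "B"), "O", seed=3)
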