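import pytest

from pas_atlas import PipelineConfig, run_pipeline
from pas_atlas.similarity import DomainSequence
from pas_atlas.synthetic import (generate_families, standard_element_maps,
                                 standard_family_specs)

STANDARD_SEED = 1


def make_seq(seq_id: str, residues: str, **kwargs) -> DomainSequence:
    return DomainSequence(id=seq_id, residues=residues, **kwargs)


@pytest.fixture(scope="session")
def standard_fixture():
    """The six-family planted-motif study fixture at the standard seed."""
    specs = standard_family_specs()
    sequences, truth = generate_families(specs, seed=STANDARD_SEED)
    return {
        "specs": specs,
        "sequences": sequences,
        "truth": truth,
        "element_maps": standard_element_maps(specs),
    }


@pytest.fixture(scope="session")
def standard_run(standard_fixture):
    """Full pipeline run on the standard fixture (shared across tests;
    the pipeline is deterministic for a fixed config)."""
    report = run_pipeline(
        PipelineConfig(seed=STANDARD_SEED),
        sequences=standard_fixture["sequences"],
        element_maps=standard_fixture["element_maps"],
    )
    return report
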