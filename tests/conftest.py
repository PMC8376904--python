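import numpy as np
import pytest

from fretseq import SimulationConfig, fyn_lib2_layout, zap70_lib2_layout


@pytest.fixture(scope="session")
def fyn_layout():
    return fyn_lib2_layout()


@pytest.fixture(scope="session")
def zap70_layout():
    return zap70_lib2_layout()


@pytest.fixture
def small_config():
    """Desk-scale study: enough cells/reads for clear enrichment signal."""
    return SimulationConfig(
        n_variants=60,
        n_cells_per_context=4000,
        reads_per_pool=8000,
        seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def perfect_read(layout, variable_dna, quality=40, read_id="r1"):
    """A clean FASTQ-style record for the given variable region."""
    from fretseq import ReadRecord

    seq = layout.read_for_variant(variable_dna)
    return ReadRecord(id=read_id, sequence=seq, qualities=[quality] * len(seq))
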