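import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from predblp.model import PipelineConfig
from predblp.seqio import STANDARD_AA, ProteinRecord, SequenceDataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def cheap_config(**overrides) -> PipelineConfig:
    """Scaled-down pipeline configuration used by end-to-end tests.

    The coarse (C, gamma) grid is reduced to the decades that matter for
    standardized feature spaces of a few hundred dimensions, and the inner
    grid CV uses three folds; selection is exercised separately.
    """
    base = dict(
        do_selection=False,
        c_grid=(1.0, 32.0),
        gamma_grid=(2.0**-11, 2.0**-9, 2.0**-7, 2.0**-5),
        grid_folds=3,
    )
    base.update(overrides)
    return PipelineConfig(**base)


def toy_dataset(sequences_pos, sequences_neg, lineage="unknown"):
    """Labelled dataset from raw sequence lists."""
    records = [
        ProteinRecord(f"p{i}", s, label=1, lineage=lineage)
        for i, s in enumerate(sequences_pos)
    ] + [
        ProteinRecord(f"n{i}", s, label=0, lineage=lineage)
        for i, s in enumerate(sequences_neg)
    ]
    return SequenceDataset(records)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def random_record(rng):
    seq = "".join(rng.choice(list(STANDARD_AA), size=80))
    return ProteinRecord("rnd", seq)
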