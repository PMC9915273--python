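"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from smireg.fixtures import FixtureConfig, generate_fixture_relations
from smireg.types import Label, MirnaRecord, RelationRecord, RelationSet, SmRecord


@pytest.fixture(scope="session")
def small_relations() -> RelationSet:
    """A 60-pair noise-free planted-rule relation set."""
    return generate_fixture_relations(
        FixtureConfig(n_mirnas=20, n_sms=15, n_relations=60, noise_rate=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def make_relation(sm_id: str, smiles: str, mir_id: str, seq: str, label: Label) -> RelationRecord:
    return RelationRecord(
        sm=SmRecord(id=sm_id, smiles=smiles),
        mirna=MirnaRecord(id=mir_id, sequence=seq),
        label=label,
    )
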