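"""Shared fixtures: a seeded synthetic transcriptome and its mined catalogue."""

from __future__ import annotations

import pytest

from laccmine.pipeline import mine_transcripts
from laccmine.synthetic import SyntheticConfig, generate_laccase_cds, generate_transcriptome

SEED = 3


@pytest.fixture(scope="session")
def synthetic_bundle():
    """Default-condition mock transcriptome plus its ground-truth manifest."""
    return generate_transcriptome(SyntheticConfig(), rng_seed=SEED)


@pytest.fixture(scope="session")
def mined(synthetic_bundle):
    transcripts, _ = synthetic_bundle
    return mine_transcripts(transcripts)


@pytest.fixture(scope="session")
def catalogue(mined):
    records, _, _ = mined
    return records


@pytest.fixture(scope="session")
def planted_cds():
    """One reproducible planted laccase CDS with known ground truth."""
    return generate_laccase_cds(7, length_aa=520, axial="L")
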