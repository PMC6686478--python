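import numpy as np
import pytest

from reportmatch.corpus_io import PairDataset, Report, ReportPair
from reportmatch.synthetic_data import SynthConfig, generate_corpus


def make_pair(pair_id, imaging_tokens, pathology_tokens, label=None):
    """Pair with pre-filled tokens (raw_text is the joined tokens)."""
    return ReportPair(
        pair_id=pair_id,
        imaging=Report(
            id=f"{pair_id}:imaging",
            kind="imaging",
            raw_text=" ".join(imaging_tokens),
            tokens=tuple(imaging_tokens),
        ),
        pathology=Report(
            id=f"{pair_id}:pathology",
            kind="pathology",
            raw_text=" ".join(pathology_tokens),
            tokens=tuple(pathology_tokens),
        ),
        label=label,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """500-pair synthetic corpus with its ontology and provenance."""
    return generate_corpus(SynthConfig(n_pairs=500, seed=20240901))


@pytest.fixture(scope="session")
def toy_dataset():
    """Six hand-written labeled pairs (positives share the site token)."""
    pairs = [
        make_pair("p0", ["thyroid", "nodule", "clear"], ["thyroid", "adenoma"], 1),
        make_pair("p1", ["kidney", "cyst"], ["kidney", "tissue"], 1),
        make_pair("p2", ["liver", "mass"], ["liver", "lesion"], 1),
        make_pair("p3", ["thyroid", "nodule"], ["kidney", "tissue"], 0),
        make_pair("p4", ["liver", "mass"], ["thyroid", "adenoma"], 0),
        make_pair("p5", ["kidney", "cyst"], ["liver", "lesion"], 0),
    ]
    return PairDataset(pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
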