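import numpy as np
import pytest

from carbshell import profile_classifier as pc
from carbshell import synthetic_data as sd
from carbshell.io_formats import GeneTableRow


@pytest.fixture(scope="session")
def seed_alignments():
    return sd.generate_seed_alignments(seed=3)


@pytest.fixture(scope="session")
def profiles(seed_alignments):
    return pc.build_profiles_from_seeds(seed_alignments)


@pytest.fixture(scope="session")
def uniform_background():
    return np.full(20, 0.05)


def make_rows(labels_at, genome_id="g0", replicon_id="chr", total=None):
    """Build a consecutive gene table with carboxysome labels at given ordinals.

    ``labels_at`` maps ordinal -> label; all other ordinals up to ``total``
    become Other.
    """
    if total is None:
        total = max(labels_at) + 5 if labels_at else 10
    return [
        GeneTableRow(
            genome_id=genome_id,
            replicon_id=replicon_id,
            ordinal=i,
            gene_id=f"{genome_id}_{i:04d}",
            label=labels_at.get(i, "Other"),
        )
        for i in range(total)
    ]


@pytest.fixture
def rows_factory():
    return make_rows
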