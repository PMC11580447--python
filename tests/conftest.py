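import numpy as np
import pytest

from aureomine.synthetic import DEFAULT_SEED, mutate_peptide


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_family_records():
    """Two planted peptide families: ~0.1 within-family pairwise distance,
    ~0.7 between families (hierarchical mutants of two far-apart centers)."""
    rng = np.random.default_rng(777)
    center_a = DEFAULT_SEED
    center_b, _ = mutate_peptide(DEFAULT_SEED, 0.7, rng, new_id="centerB")
    fam_a = [
        mutate_peptide(center_a, 0.05, rng, new_id=f"a{i}")[0] for i in range(6)
    ]
    fam_b = [
        mutate_peptide(center_b, 0.05, rng, new_id=f"b{i}")[0] for i in range(6)
    ]
    return fam_a, fam_b
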