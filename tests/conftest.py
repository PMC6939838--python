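import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# FASTA byte fixtures: the round-trip contract is asserted against these
# literal bytes, covering wrapping quirks, case, ambiguity codes and
# missing final newlines.
FASTA_FIXTURES = {
    "minimal": b">a\nACGT\n",
    "two_records_wrapped": b">first one\nACGT\nTTGG\nAC\n>second\nGGGGCCCC\n",
    "lowercase_ambiguous": b">soft masked\nacgtNnRYacgt\n",
    "irregular_wrap": b">ragged\nACGTACGTAC\nGT\nACGTACGTACGTACGTACGT\nA\n",
    "no_final_newline": b">x\nACGTAC",
    "empty_residues": b">nothing here\n>something\nACGT\n",
    "blank_line_inside": b">gappy\nACGT\n\nTTTT\n",
    "leading_blank_lines": b"\n\n>late start\nACGT\n",
    "n_rich": b">enn\n" + b"ACGTACGTAC\n" + b"N" * 40 + b"\nACGTTGCAAC\n",
}


@pytest.fixture(params=sorted(FASTA_FIXTURES))
def fasta_bytes(request):
    return FASTA_FIXTURES[request.param]


@pytest.fixture(scope="session")
def two_family_records():
    from eccomp import FamilySpec, generate_dataset

    records, labels = generate_dataset(
        FamilySpec(n_families=2, members_per_family=3, ancestor_length=3000, seed=11)
    )
    return records, labels


@pytest.fixture(scope="session")
def two_block_matrix():
    """Two tight blocks of 5 points: within-distance 0.01, between 0.9."""
    d = np.full((10, 10), 0.9)
    for i in range(10):
        for j in range(10):
            if (i < 5) == (j < 5):
                d[i, j] = 0.01
    np.fill_diagonal(d, 0.0)
    return d


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    d = rng.uniform(0.01, 1.0, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d
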