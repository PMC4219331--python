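import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tctransfer.homology import ScoringScheme, default_scheme
from tctransfer.seqdata import AnnotatedDataset, TransporterRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def blosum():
    return default_scheme()


@pytest.fixture(scope="session")
def tiny_scheme():
    """4-letter scheme with mild gap costs so short alignments open gaps."""
    matrix = np.full((4, 4), -2, dtype=np.int64)
    np.fill_diagonal(matrix, 4)
    return ScoringScheme(
        matrix=matrix, alphabet="ACDE", gap_open=-4, gap_extend=-1,
        lam=0.5, K=0.1,
    )


def make_record(rid, seq, family="2.A.1", organism="Ec", substrates=()):
    return TransporterRecord(
        id=rid, organism=organism, sequence=seq, tc_family=family,
        substrates=frozenset(substrates),
    )


def make_dataset(organism, specs):
    """specs: iterable of (id, seq, family, substrates)."""
    return AnnotatedDataset(
        records=[
            make_record(rid, seq, family, organism, substrates)
            for rid, seq, family, substrates in specs
        ],
        organism=organism,
    )


@pytest.fixture
def two_family_pair():
    """Two organisms sharing families 2.A.1 / 3.A.1 with distinct sequences."""
    seq1 = "MKVLAWAGLVSTQWERTYHKNMKVLAWAGLVSTQ"
    seq2 = "GGHHPPLLIKNNMMQQRRSSTTVVWWYYAACCDD"
    ds_a = make_dataset("Ec", [
        ("ecA1", seq1, "2.A.1", ["sugar"]),
        ("ecA2", seq1[2:] + "AC", "2.A.1", ["sugar"]),
        ("ecB1", seq2, "3.A.1", ["metal"]),
        ("ecB2", seq2[1:] + "G", "3.A.1", ["metal"]),
    ])
    ds_b = make_dataset("At", [
        ("atA1", seq1, "2.A.1", ["sugar"]),
        ("atA2", seq1[:-2] + "WW", "2.A.1", ["sugar"]),
        ("atB1", seq2, "3.A.1", ["metal"]),
        ("atB2", seq2[2:] + "GG", "3.A.1", ["metal"]),
    ])
    return ds_a, ds_b
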