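import numpy as np
import pytest

from herbrec.corpus import ClinicalRecord
from herbrec.synthetic import CorpusSpec, DomainSpec, generate_corpus


@pytest.fixture
def toy_records():
    """Three hand-written records across both domains."""
    return [
        ClinicalRecord("r1", "source", ("s1", "s2"), ("h1", "h2")),
        ClinicalRecord("r2", "source", ("s2", "s3"), ("h2",)),
        ClinicalRecord("r3", "target", ("s3",), ("h1", "h3")),
    ]


def random_records(rng: np.random.Generator, n: int = 12,
                   n_symptoms: int = 6, n_herbs: int = 5) -> list[ClinicalRecord]:
    """Small random corpus for brute-force oracle comparisons."""
    records = []
    for i in range(n):
        domain = "source" if i % 2 == 0 else "target"
        k_s = int(rng.integers(1, n_symptoms + 1))
        k_h = int(rng.integers(1, n_herbs + 1))
        syms = tuple(f"s{j}" for j in rng.choice(n_symptoms, size=k_s, replace=False))
        herbs = tuple(f"h{j}" for j in rng.choice(n_herbs, size=k_h, replace=False))
        records.append(ClinicalRecord(f"r{i}", domain, syms, herbs))
    return records


@pytest.fixture
def small_spec():
    """Two-domain generator spec at test scale."""
    return CorpusSpec(
        source=DomainSpec(n_records=120, n_symptoms=60, n_herbs=30,
                          mean_symptoms=8.0, mean_herbs=10.0),
        target=DomainSpec(n_records=120, n_symptoms=50, n_herbs=25,
                          mean_symptoms=10.0, mean_herbs=5.0),
        shared_symptoms=15, shared_herbs=10, seed=7,
    )


@pytest.fixture
def small_corpus(small_spec):
    return generate_corpus(small_spec)
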