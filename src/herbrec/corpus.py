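"""Two-domain clinical corpora: records, vocabularies, co-occurrence, splits.

A clinical record is one patient visit: the set of recorded symptom terms
(the features) and the set of herbs in the prescription (the labels), tagged
with the corpus it came from.  Two corpora play the roles of source and
target domain; their shared herb (and, to a lesser degree, symptom)
vocabulary is what carries signal across domains.

Co-occurrence counting is per-patient binary: a record contributes at most 1
to the count of a (herb, symptom) pair regardless of duplicates, and the
count C_ij is the number of records in which herb i and symptom j appear
together.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.io
import scipy.sparse

Domain = Literal["source", "target"]
DOMAINS = ("source", "target")

__all__ = [
    "ClinicalRecord", "Vocabulary", "CooccurrenceMatrix", "SparsityReport",
    "build_vocabularies", "build_cooccurrence", "sparsity_report",
    "sparsity_fraction", "split_records", "read_records_jsonl",
    "write_records_jsonl", "read_records_tsv", "write_records_tsv",
    "export_cooccurrence",
]


def _dedupe(terms: Iterable[str]) -> tuple[str, ...]:
    return tuple(dict.fromkeys(terms))


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient visit: symptom set, prescribed herb set, domain tag.

    Terms are stored deduplicated in input order (set semantics for
    membership; the order only pins down deterministic vocabulary
    construction).
    """

    record_id: str
    domain: Domain
    symptoms: tuple[str, ...]
    herbs: tuple[str, ...]

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")
        object.__setattr__(self, "symptoms", _dedupe(self.symptoms))
        object.__setattr__(self, "herbs", _dedupe(self.herbs))
        if not self.symptoms:
            raise ValueError(f"record {self.record_id!r}: symptoms must be nonempty")
        if not self.herbs:
            raise ValueError(f"record {self.record_id!r}: herbs must be nonempty")

    @property
    def symptom_set(self) -> frozenset:
        return frozenset(self.symptoms)

    @property
    def herb_set(self) -> frozenset:
        return frozenset(self.herbs)


@dataclass
class Vocabulary:
    """Union vocabulary over both domains with per-domain membership."""

    terms: list[str]
    in_source: np.ndarray  # bool, aligned with terms
    in_target: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.terms)}
        if len(self.index) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")

    @property
    def union_size(self) -> int:
        return len(self.terms)

    @property
    def per_domain_sizes(self) -> tuple[int, int]:
        return int(self.in_source.sum()), int(self.in_target.sum())

    def domain_mask(self, domain: Domain) -> np.ndarray:
        return self.in_source if domain == "source" else self.in_target

    def domain_terms(self, domain: Domain) -> list[str]:
        mask = self.domain_mask(domain)
        return [t for t, m in zip(self.terms, mask) if m]

    def __len__(self) -> int:
        return self.union_size

    def __contains__(self, term: str) -> bool:
        return term in self.index


@dataclass
class CooccurrenceMatrix:
    """Integer herb x symptom (or transposed) joint-appearance counts."""

    row_kind: Literal["herb", "symptom"]
    col_kind: Literal["herb", "symptom"]
    domain: Literal["source", "target", "union"]
    counts: np.ndarray  # int, shape (len(row_terms), len(col_terms))
    row_terms: list[str]
    col_terms: list[str]
    n_records: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_terms), len(self.col_terms)):
            raise ValueError("counts shape does not match term lists")
        if (self.counts < 0).any() or (self.counts > self.n_records).any():
            raise ValueError("counts must lie in [0, n_records]")

    def transpose(self) -> "CooccurrenceMatrix":
        return CooccurrenceMatrix(
            row_kind=self.col_kind, col_kind=self.row_kind, domain=self.domain,
            counts=self.counts.T.copy(), row_terms=list(self.col_terms),
            col_terms=list(self.row_terms), n_records=self.n_records,
        )


@dataclass(frozen=True)
class SparsityReport:
    mean_symptoms_per_record: float
    mean_herbs_per_record: float
    symptom_sparsity: float
    herb_sparsity: float
    max_symptom_frequency: int
    max_herb_frequency: int
    n_records: int
    symptom_vocab_size: int
    herb_vocab_size: int


def build_vocabularies(
    records: Sequence[ClinicalRecord],
    ordering: Literal["first-occurrence", "lexicographic"] = "first-occurrence",
) -> tuple[Vocabulary, Vocabulary]:
    """Union symptom and herb vocabularies over both domains.

    Default ordering is first occurrence in the record stream (deterministic
    for a fixed file); ``lexicographic`` gives an ordering that is invariant
    to record permutation.
    """
    seen_ids: set[str] = set()
    symptoms: dict[str, None] = {}
    herbs: dict[str, None] = {}
    s_dom: dict[str, set] = {}
    h_dom: dict[str, set] = {}
    for rec in records:
        if rec.record_id in seen_ids:
            raise ValueError(f"duplicate record_id: {rec.record_id!r}")
        seen_ids.add(rec.record_id)
        for s in rec.symptoms:
            symptoms.setdefault(s, None)
            s_dom.setdefault(s, set()).add(rec.domain)
        for h in rec.herbs:
            herbs.setdefault(h, None)
            h_dom.setdefault(h, set()).add(rec.domain)

    def make(terms: dict[str, None], dom: dict[str, set]) -> Vocabulary:
        order = sorted(terms) if ordering == "lexicographic" else list(terms)
        in_src = np.array(["source" in dom[t] for t in order], dtype=bool)
        in_tgt = np.array(["target" in dom[t] for t in order], dtype=bool)
        return Vocabulary(order, in_src, in_tgt)

    return make(symptoms, s_dom), make(herbs, h_dom)


def build_cooccurrence(
    records: Sequence[ClinicalRecord],
    symptom_vocab: Vocabulary,
    herb_vocab: Vocabulary,
    domain_filter: Literal["source", "target", "union"] = "union",
) -> CooccurrenceMatrix:
    """Herb-rows x symptom-cols joint appearance counts.

    For a single-domain filter the axes are that domain's vocabulary slice;
    for ``union`` they are the full union vocabularies.  Each record adds 1
    to every (herb, symptom) pair it contains.
    """
    if domain_filter == "union":
        herb_terms = list(herb_vocab.terms)
        symptom_terms = list(symptom_vocab.terms)
        recs = list(records)
    else:
        herb_terms = herb_vocab.domain_terms(domain_filter)
        symptom_terms = symptom_vocab.domain_terms(domain_filter)
        recs = [r for r in records if r.domain == domain_filter]
    h_index = {t: i for i, t in enumerate(herb_terms)}
    s_index = {t: i for i, t in enumerate(symptom_terms)}
    counts = np.zeros((len(herb_terms), len(symptom_terms)), dtype=np.int64)
    for rec in recs:
        try:
            hi = [h_index[h] for h in rec.herbs]
        except KeyError as exc:
            raise KeyError(f"herb term {exc.args[0]!r} absent from vocabulary") from None
        try:
            si = [s_index[s] for s in rec.symptoms]
        except KeyError as exc:
            raise KeyError(f"symptom term {exc.args[0]!r} absent from vocabulary") from None
        counts[np.ix_(hi, si)] += 1
    return CooccurrenceMatrix(
        row_kind="herb", col_kind="symptom", domain=domain_filter,
        counts=counts, row_terms=herb_terms, col_terms=symptom_terms,
        n_records=len(recs),
    )


def sparsity_fraction(mean_set_size: float, vocab_size: int) -> float:
    """Sample-level sparsity: 1 - (mean terms per record) / (vocabulary size)."""
    if vocab_size <= 0:
        raise ValueError("vocab_size must be positive")
    return 1.0 - mean_set_size / vocab_size


def sparsity_report(
    records: Sequence[ClinicalRecord],
    symptom_vocab: Vocabulary | None = None,
    herb_vocab: Vocabulary | None = None,
    use_union: bool = False,
) -> SparsityReport:
    """Mean set sizes, term-frequency maxima, and sample-level sparsities.

    Sparsity denominators default to the vocabulary of the records actually
    passed (the per-corpus convention); ``use_union=True`` uses the union
    vocabulary sizes instead (requires the vocabularies).
    """
    if not records:
        raise ValueError("sparsity_report requires a nonempty corpus")
    mean_s = float(np.mean([len(r.symptoms) for r in records]))
    mean_h = float(np.mean([len(r.herbs) for r in records]))
    s_freq: dict[str, int] = {}
    h_freq: dict[str, int] = {}
    for rec in records:
        for s in rec.symptoms:
            s_freq[s] = s_freq.get(s, 0) + 1
        for h in rec.herbs:
            h_freq[h] = h_freq.get(h, 0) + 1
    if use_union:
        if symptom_vocab is None or herb_vocab is None:
            raise ValueError("use_union=True requires both vocabularies")
        n_s, n_h = symptom_vocab.union_size, herb_vocab.union_size
    else:
        n_s, n_h = len(s_freq), len(h_freq)
    return SparsityReport(
        mean_symptoms_per_record=mean_s,
        mean_herbs_per_record=mean_h,
        symptom_sparsity=sparsity_fraction(mean_s, n_s),
        herb_sparsity=sparsity_fraction(mean_h, n_h),
        max_symptom_frequency=max(s_freq.values()),
        max_herb_frequency=max(h_freq.values()),
        n_records=len(records),
        symptom_vocab_size=n_s,
        herb_vocab_size=n_h,
    )


def split_records(
    records: Sequence[ClinicalRecord], train_fraction: float, seed: int,
) -> tuple[list[ClinicalRecord], list[ClinicalRecord]]:
    """Seeded shuffle, then exact partition with floor(train_fraction * N) train."""
    n = len(records)
    if n == 0:
        raise ValueError("cannot split an empty corpus")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = math.floor(train_fraction * n)
    train = [records[i] for i in perm[:n_train]]
    test = [records[i] for i in perm[n_train:]]
    return train, test


# ---------------------------------------------------------------------------
# File formats: JSONL and TSV record files, MatrixMarket co-occurrence export


def _record_from_dict(d: dict) -> ClinicalRecord:
    return ClinicalRecord(
        record_id=str(d["id"]), domain=d["domain"],
        symptoms=tuple(d["symptoms"]), herbs=tuple(d["herbs"]),
    )


def read_records_jsonl(path: str | Path) -> list[ClinicalRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(_record_from_dict(json.loads(line)))
    return records


def write_records_jsonl(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps({
                "id": rec.record_id, "domain": rec.domain,
                "symptoms": list(rec.symptoms), "herbs": list(rec.herbs),
            }, ensure_ascii=False) + "\n")


def read_records_tsv(path: str | Path) -> list[ClinicalRecord]:
    """TSV dialect: id <TAB> domain <TAB> pipe-joined symptoms <TAB> pipe-joined herbs."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rec_id, domain, symptoms, herbs = line.split("\t")
            records.append(ClinicalRecord(
                record_id=rec_id, domain=domain,
                symptoms=tuple(t for t in symptoms.split("|") if t),
                herbs=tuple(t for t in herbs.split("|") if t),
            ))
    return records


def write_records_tsv(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write("\t".join([
                rec.record_id, rec.domain,
                "|".join(rec.symptoms), "|".join(rec.herbs),
            ]) + "\n")


def export_cooccurrence(matrix: CooccurrenceMatrix, directory: str | Path, stem: str = "cooccurrence") -> dict[str, Path]:
    """Write counts as MatrixMarket plus row/column term lists as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mtx = directory / f"{stem}.mtx"
    scipy.io.mmwrite(str(mtx), scipy.sparse.coo_matrix(matrix.counts))
    rows = directory / f"{stem}.rows.tsv"
    cols = directory / f"{stem}.cols.tsv"
    rows.write_text("".join(f"{t}\n" for t in matrix.row_terms), encoding="utf-8")
    cols.write_text("".join(f"{t}\n" for t in matrix.col_terms), encoding="utf-8")
    return {"matrix": mtx, "rows": rows, "cols": cols}
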