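"""Seeded generators of two-domain clinical corpora and toy PPI fixtures.

The corpus generator emulates the statistical profile of real prescription
corpora: long-tailed (Zipf-like) term frequencies, per-record set sizes
scattered around corpus-specific means (truncated Poisson, minimum 1), an
exact number of symptom and herb terms shared between the two domains, and a
planted symptom->herb rule table.  Rules on shared herbs are identical in
both domains — the minimal structure under which cross-domain transfer can
help — while domain-specific rules differ.  Everything is a pure function of
the spec and its seed.

The PPI generator plants two node sets in an Erdős–Rényi graph whose
inter-set edge probability is boosted by a configurable factor, giving the
proximity statistics a fixture with known signal (boost 1 is exactly the
background distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import networkx as nx
import numpy as np

from .corpus import ClinicalRecord

__all__ = ["DomainSpec", "CorpusSpec", "generate_corpus", "generate_ppi",
           "tcm_ssd_like", "tcm_lung_like", "paper_profile_spec", "PRESETS"]


@dataclass(frozen=True)
class DomainSpec:
    """Size and density targets for one domain's corpus."""

    n_records: int
    n_symptoms: int          # domain symptom vocabulary size (incl. shared)
    n_herbs: int
    mean_symptoms: float     # target mean symptoms per record
    mean_herbs: float


@dataclass(frozen=True)
class CorpusSpec:
    source: DomainSpec
    target: DomainSpec
    shared_symptoms: int
    shared_herbs: int
    zipf_exponent: float = 1.1
    n_shared_rules: int = 10      # symptom->herb rules on shared terms, same in both domains
    n_domain_rules: int = 5       # extra domain-specific rules per domain
    rule_strength: float = 0.8    # P(paired herb | trigger symptom present)
    noise_rate: float = 0.05      # P(an herb slot is replaced by a uniform draw)
    seed: int = 0

    def __post_init__(self):
        for dom in (self.source, self.target):
            if self.shared_symptoms > dom.n_symptoms or self.shared_herbs > dom.n_herbs:
                raise ValueError("overlap exceeds a per-domain vocabulary size")
            if dom.mean_symptoms < 1 or dom.mean_herbs < 1:
                raise ValueError("mean set sizes must be >= 1")
            if dom.mean_symptoms > dom.n_symptoms or dom.mean_herbs > dom.n_herbs:
                raise ValueError("mean set size exceeds the vocabulary size")
        if not (0.0 <= self.rule_strength <= 1.0 and 0.0 <= self.noise_rate <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")


# Emulation targets from the two published corpus profiles: mean set sizes,
# record counts and term overlaps are as reported for the real datasets; the
# per-domain vocabulary sizes are chosen to reproduce the printed union sizes
# (928 herbs, 42,975 symptoms) given the printed overlaps (285, 328).
_SSD = DomainSpec(n_records=17_593, n_symptoms=25_000, n_herbs=720,
                  mean_symptoms=13.58, mean_herbs=20.98)
_LUNG = DomainSpec(n_records=14_948, n_symptoms=18_303, n_herbs=493,
                   mean_symptoms=17.39, mean_herbs=7.89)


def _scaled(dom: DomainSpec, scale: float) -> DomainSpec:
    n_sym = max(8, round(dom.n_symptoms * scale))
    n_herb = max(8, round(dom.n_herbs * scale))
    return DomainSpec(
        n_records=max(10, round(dom.n_records * scale)),
        n_symptoms=n_sym, n_herbs=n_herb,
        mean_symptoms=min(dom.mean_symptoms, n_sym / 2),
        mean_herbs=min(dom.mean_herbs, n_herb / 2),
    )


def tcm_ssd_like(scale: float = 1.0) -> DomainSpec:
    return _scaled(_SSD, scale) if scale != 1.0 else _SSD


def tcm_lung_like(scale: float = 1.0) -> DomainSpec:
    return _scaled(_LUNG, scale) if scale != 1.0 else _LUNG


def paper_profile_spec(scale: float = 1.0, seed: int = 0) -> CorpusSpec:
    """Two-domain spec with the published corpus profile, optionally scaled
    down (record counts, vocabularies and overlaps shrink together; the mean
    set sizes are kept unless the shrunken vocabulary forces them down)."""
    src, tgt = tcm_ssd_like(scale), tcm_lung_like(scale)
    shared_s = min(max(2, round(328 * scale)), src.n_symptoms, tgt.n_symptoms)
    shared_h = min(max(2, round(285 * scale)), src.n_herbs, tgt.n_herbs)
    return CorpusSpec(source=src, target=tgt, shared_symptoms=shared_s,
                      shared_herbs=shared_h, seed=seed)


PRESETS = {"tcm-ssd-like": tcm_ssd_like, "tcm-lung-like": tcm_lung_like,
           "paper-profile": paper_profile_spec}


def _zipf_weights(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    ranks = rng.permutation(n) + 1
    w = 1.0 / ranks.astype(float) ** exponent
    return w / w.sum()


def _trunc_poisson(rng: np.random.Generator, mean: float, upper: int) -> int:
    return int(min(max(1, rng.poisson(mean)), upper))


def _domain_vocab(kind: str, domain: str, n_total: int, n_shared: int) -> list[str]:
    shared = [f"{kind}_shared_{i}" for i in range(n_shared)]
    own = [f"{kind}_{domain}_{i}" for i in range(n_total - n_shared)]
    return shared + own


def generate_corpus(spec: CorpusSpec) -> list[ClinicalRecord]:
    """Draw a two-domain corpus from the spec; same spec + seed -> identical
    records.  Every vocabulary term is guaranteed to appear in its domain, so
    generated overlaps match the spec exactly."""
    rng = np.random.default_rng(spec.seed)
    records: list[ClinicalRecord] = []
    # planted rules: shared rules identical across domains
    n_sr = min(spec.n_shared_rules, spec.shared_symptoms, spec.shared_herbs)
    shared_rules = {f"sym_shared_{i}": f"herb_shared_{i}" for i in range(n_sr)}
    for domain, dom in (("source", spec.source), ("target", spec.target)):
        symptoms = _domain_vocab("sym", domain, dom.n_symptoms, spec.shared_symptoms)
        herbs = _domain_vocab("herb", domain, dom.n_herbs, spec.shared_herbs)
        rules = dict(shared_rules)
        n_dr = min(spec.n_domain_rules, dom.n_symptoms - spec.shared_symptoms,
                   dom.n_herbs - spec.shared_herbs)
        for i in range(max(n_dr, 0)):
            rules[f"sym_{domain}_{i}"] = f"herb_{domain}_{i}"
        w_sym = _zipf_weights(rng, dom.n_symptoms, spec.zipf_exponent)
        w_herb = _zipf_weights(rng, dom.n_herbs, spec.zipf_exponent)
        used_s: set[str] = set()
        used_h: set[str] = set()
        dom_records = []
        for r in range(dom.n_records):
            k_s = _trunc_poisson(rng, dom.mean_symptoms, dom.n_symptoms)
            sym_idx = rng.choice(dom.n_symptoms, size=k_s, replace=False, p=w_sym)
            rec_syms = [symptoms[i] for i in sym_idx]
            rec_herbs: list[str] = []
            for s in rec_syms:
                h = rules.get(s)
                if h is not None and rng.random() < spec.rule_strength:
                    rec_herbs.append(h)
            k_h = _trunc_poisson(rng, dom.mean_herbs, dom.n_herbs)
            if len(rec_herbs) < k_h:
                extra = rng.choice(dom.n_herbs, size=k_h, replace=False, p=w_herb)
                for i in extra:
                    if herbs[i] not in rec_herbs:
                        rec_herbs.append(herbs[i])
                    if len(rec_herbs) >= k_h:
                        break
            if spec.noise_rate > 0.0:
                protected = {rules.get(s) for s in rec_syms}
                for j, h in enumerate(rec_herbs):
                    if h not in protected and rng.random() < spec.noise_rate:
                        rec_herbs[j] = herbs[int(rng.integers(dom.n_herbs))]
            rec_herbs = list(dict.fromkeys(rec_herbs))
            used_s.update(rec_syms)
            used_h.update(rec_herbs)
            dom_records.append((f"{domain}-{r:06d}", rec_syms, rec_herbs))
        # coverage injection: every vocabulary term must occur in its domain
        missing_s = [t for t in symptoms if t not in used_s]
        missing_h = [t for t in herbs if t not in used_h]
        for t in missing_s:
            _, syms, _ = dom_records[int(rng.integers(len(dom_records)))]
            syms.append(t)
        for t in missing_h:
            _, _, hs = dom_records[int(rng.integers(len(dom_records)))]
            hs.append(t)
        records.extend(
            ClinicalRecord(rid, domain, tuple(syms), tuple(hs))
            for rid, syms, hs in dom_records
        )
    return records


def generate_ppi(
    n_nodes: int,
    edge_prob: float,
    seed: int = 0,
    set_size: int = 10,
    boost: float = 1.0,
) -> tuple[nx.Graph, set[str], set[str]]:
    """Erdős–Rényi graph with two planted disjoint node sets whose inter-set
    edge probability is ``boost * edge_prob`` (capped checks, not silently
    clipped).  ``boost=1`` leaves the planted pair statistically identical to
    the background."""
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if not 0.0 < edge_prob < 1.0:
        raise ValueError("edge_prob must lie in (0, 1)")
    if 2 * set_size > n_nodes:
        raise ValueError("planted sets do not fit in the graph")
    q = boost * edge_prob
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"infeasible boost: inter-set edge probability {q} outside [0, 1]")
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_nodes, edge_prob, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(n_nodes)})
    picks = rng.choice(n_nodes, size=2 * set_size, replace=False)
    A = {f"g{i}" for i in picks[:set_size]}
    B = {f"g{i}" for i in picks[set_size:]}
    # resample every A x B pair at the boosted probability
    for a in A:
        for b in B:
            if g.has_edge(a, b):
                g.remove_edge(a, b)
            if rng.random() < q:
                g.add_edge(a, b)
    return g, A, B
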