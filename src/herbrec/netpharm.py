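"""Network-pharmacology proximity of two gene sets on a PPI graph.

Given an undirected protein-protein interaction network, a set A of
symptom-associated genes and a set B of herb-target genes, this module
computes the standard network-medicine statistics:

* separation score S_AB = d_AB - (d_AA + d_BB) / 2, built from
  closest-distance means (within-set distances exclude the node itself;
  nodes shared by A and B contribute 0 to d_AB) — negative values mean the
  two neighborhoods overlap;
* a randomization z-score of the observed proximity d_AB against a null of
  uniformly random node sets of the same sizes (degree-binned sampling is
  available behind a flag);
* ASPL, the plain mean shortest-path length over all A x B pairs;
* an inter-set edge-count permutation test whose significance is an
  upper-tail binomial probability with the per-pair rate estimated from the
  permutation null.

Unreachable pairs are dropped from means with a warning by default; strict
mode raises instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "ProximityResult", "separation_score", "proximity_zscore", "aspl",
    "edge_permutation_test", "read_graph_tsv", "read_gene_set",
    "proximity_suite", "write_proximity_json",
]


def _check_sets(graph: nx.Graph, A: Iterable, B: Iterable) -> tuple[set, set]:
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("both gene sets must be nonempty")
    missing = (A | B) - set(graph.nodes)
    if missing:
        raise ValueError(f"{len(missing)} gene(s) not in the graph, e.g. {sorted(missing)[:5]}")
    return A, B


def _min_dists(graph: nx.Graph, sources: set, targets: set, exclude_self: bool,
               on_unreachable: str) -> list[float]:
    """For each source node, BFS distance to the closest target node."""
    out = []
    dropped = 0
    for s in sources:
        tgts = targets - {s} if exclude_self else targets
        if not tgts:
            out.append(0.0)  # singleton set: within-set distance defined as 0
            continue
        if s in tgts:
            out.append(0.0)
            continue
        lengths = nx.single_source_shortest_path_length(graph, s)
        best = min((lengths[t] for t in tgts if t in lengths), default=None)
        if best is None:
            if on_unreachable == "error":
                raise ValueError(f"node {s!r} cannot reach the opposite set")
            dropped += 1
        else:
            out.append(float(best))
    if dropped:
        warnings.warn(f"dropped {dropped} node(s) unreachable from the opposite set")
    if not out:
        raise ValueError("no node pair is reachable")
    return out


def separation_score(
    graph: nx.Graph, A: Iterable, B: Iterable, on_unreachable: str = "drop",
) -> dict[str, float]:
    """S_AB with its components d_AA, d_BB, d_AB (closest-distance means)."""
    A, B = _check_sets(graph, A, B)
    d_aa = float(np.mean(_min_dists(graph, A, A, True, on_unreachable)))
    d_bb = float(np.mean(_min_dists(graph, B, B, True, on_unreachable)))
    cross = (_min_dists(graph, A, B, False, on_unreachable)
             + _min_dists(graph, B, A, False, on_unreachable))
    d_ab = float(np.mean(cross))
    return {"S_AB": d_ab - (d_aa + d_bb) / 2.0, "d_AA": d_aa, "d_BB": d_bb, "d_AB": d_ab}


def _observed_proximity(graph: nx.Graph, A: set, B: set, on_unreachable: str) -> float:
    cross = (_min_dists(graph, A, B, False, on_unreachable)
             + _min_dists(graph, B, A, False, on_unreachable))
    return float(np.mean(cross))


def _degree_bins(graph: nx.Graph, n_bins: int = 10) -> dict:
    """Nodes bucketed by degree quantile, for degree-aware null sampling."""
    nodes = list(graph.nodes)
    degrees = np.array([graph.degree(n) for n in nodes])
    edges = np.quantile(degrees, np.linspace(0, 1, n_bins + 1))
    bin_of = np.clip(np.searchsorted(edges, degrees, side="right") - 1, 0, n_bins - 1)
    bins: dict[int, list] = {}
    for node, b in zip(nodes, bin_of):
        bins.setdefault(int(b), []).append(node)
    return {"bins": bins, "bin_of": dict(zip(nodes, (int(b) for b in bin_of)))}


def _sample_like(rng: np.random.Generator, nodes: list, size: int,
                 like: set | None, binned: dict | None) -> set:
    if binned is None:
        return {nodes[j] for j in rng.choice(len(nodes), size=size, replace=False)}
    # degree-binned: one draw per original node, from its degree bin
    picked: set = set()
    for node in like:
        pool = binned["bins"][binned["bin_of"][node]]
        choice = pool[int(rng.integers(len(pool)))]
        while choice in picked:
            choice = pool[int(rng.integers(len(pool)))]
        picked.add(choice)
    return picked


def proximity_zscore(
    graph: nx.Graph, A: Iterable, B: Iterable, n_rand: int = 10_000,
    seed: int = 0, degree_matched: bool = False, on_unreachable: str = "drop",
) -> dict[str, float]:
    """Z-score of the observed closest-distance proximity d_AB against
    uniformly random same-size node sets (n_rand trials, seeded)."""
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    A, B = _check_sets(graph, A, B)
    s_obs = _observed_proximity(graph, A, B, on_unreachable)
    nodes = list(graph.nodes)
    rng = np.random.default_rng(seed)
    binned = _degree_bins(graph) if degree_matched else None
    null = np.empty(n_rand)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unreachable-drop warnings in null draws
        for i in range(n_rand):
            ra = _sample_like(rng, nodes, len(A), A, binned)
            rb = _sample_like(rng, nodes, len(B), B, binned)
            null[i] = _observed_proximity(graph, ra, rb, "drop")
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    if sd == 0.0:
        raise ValueError("degenerate null: zero standard deviation")
    return {"z": (s_obs - mean) / sd, "observed": s_obs,
            "null_mean": mean, "null_sd": sd, "n_rand": n_rand}


def aspl(graph: nx.Graph, A: Iterable, B: Iterable, on_unreachable: str = "drop") -> float:
    """Average shortest-path length over all (a in A, b in B) pairs."""
    A, B = _check_sets(graph, A, B)
    total, count, dropped = 0.0, 0, 0
    for a in A:
        lengths = nx.single_source_shortest_path_length(graph, a)
        for b in B:
            if b in lengths:
                total += lengths[b]
                count += 1
            else:
                if on_unreachable == "error":
                    raise ValueError(f"pair ({a!r}, {b!r}) is unreachable")
                dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} unreachable pair(s)")
    if count == 0:
        raise ValueError("all pairs unreachable")
    return total / count


def _inter_set_edges(graph: nx.Graph, A: set, B: set) -> int:
    return sum(1 for u, v in graph.edges
               if (u in A and v in B) or (u in B and v in A))


def edge_permutation_test(
    graph: nx.Graph, A: Iterable, B: Iterable, n_rounds: int = 1000, seed: int = 0,
) -> dict:
    """Observed inter-set edge count against random same-size node sets.

    The per-pair edge probability is estimated as the null-mean count divided
    by |A||B|, and the p-value is the upper-tail binomial probability of
    seeing at least the observed count among |A||B| pairs.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    A, B = _check_sets(graph, A, B)
    n_pairs = len(A) * len(B)
    observed = _inter_set_edges(graph, A, B)
    nodes = list(graph.nodes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_rounds, dtype=np.int64)
    for i in range(n_rounds):
        ra = {nodes[j] for j in rng.choice(len(nodes), size=len(A), replace=False)}
        rb = {nodes[j] for j in rng.choice(len(nodes), size=len(B), replace=False)}
        null[i] = _inter_set_edges(graph, ra, rb)
    p_hat = min(float(null.mean()) / n_pairs, 1.0)
    p_value = float(stats.binom.sf(observed - 1, n_pairs, p_hat))
    return {"observed": observed, "null": null, "null_mean": float(null.mean()),
            "p_pair": p_hat, "p_value": p_value, "n_pairs": n_pairs}


@dataclass
class ProximityResult:
    S_AB: float
    d_AA: float
    d_BB: float
    d_AB: float
    z: float
    null_mean: float
    null_sd: float
    aspl: float
    observed_edges: int
    edge_null_mean: float
    binomial_p: float
    n_rand: int
    n_rounds: int


def proximity_suite(
    graph: nx.Graph, A: Iterable, B: Iterable,
    n_rand: int = 10_000, n_rounds: int = 1000, seed: int = 0,
    degree_matched: bool = False,
) -> ProximityResult:
    """All proximity statistics for one (A, B) pair in one call."""
    sep = separation_score(graph, A, B)
    zres = proximity_zscore(graph, A, B, n_rand=n_rand, seed=seed,
                            degree_matched=degree_matched)
    spl = aspl(graph, A, B)
    edge = edge_permutation_test(graph, A, B, n_rounds=n_rounds, seed=seed + 1)
    return ProximityResult(
        S_AB=sep["S_AB"], d_AA=sep["d_AA"], d_BB=sep["d_BB"], d_AB=sep["d_AB"],
        z=zres["z"], null_mean=zres["null_mean"], null_sd=zres["null_sd"],
        aspl=spl, observed_edges=edge["observed"],
        edge_null_mean=edge["null_mean"], binomial_p=edge["p_value"],
        n_rand=n_rand, n_rounds=n_rounds,
    )


# ---------------------------------------------------------------------------
# File formats


def read_graph_tsv(path: str | Path) -> nx.Graph:
    """Two-column TSV edge list -> simple undirected graph (self-loops dropped)."""
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v = line.split("\t")[:2]
            if u != v:
                g.add_edge(u, v)
    return g


def read_gene_set(path: str | Path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def write_proximity_json(result: ProximityResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(result), indent=1), encoding="utf-8")
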