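"""Gaussian Bayesian networks over {SDP, miRNAs, genes} with bootstrap averaging.

A network is a DAG scored by the decomposable Gaussian BIC: each node is
regressed (with intercept) on its parents and contributes

    -(n/2) * ln(RSS/n) - (|parents| + 2)/2 * ln(n)

(higher is better).  Structure search is greedy hill-climbing from the empty
graph over single-edge additions, deletions and reversals, with every edge
into an SDP node blacklisted: genetic variants are causes, never effects, of
expression.  Edge confidence comes from model averaging over bootstrap
resamples of the strains; an edge is retained when it appears (in either
direction) in at least half of the resampled networks, oriented by the
majority direction, and signed by the Spearman correlation of its endpoints
on the original data.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "bic_score",
    "local_score",
    "hill_climb",
    "bootstrap_average",
    "AveragedNetwork",
    "GaussianNetwork",
    "NetworkResults",
]

RSS_FLOOR_SCALE = 1e-12
# minimal score gain to accept a move: guards against floating-point
# oscillation (e.g. endless reversals between exactly symmetric fits)
MIN_IMPROVEMENT = 1e-9


def local_score(child: str, parents: tuple[str, ...], data: pd.DataFrame) -> float:
    """BIC contribution of one node given its parent set (higher is better)."""
    y = data[child].to_numpy(dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n)] + [data[p].to_numpy(dtype=float) for p in parents])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return -np.inf
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ coef) ** 2).sum())
    floor = RSS_FLOOR_SCALE * n * max(float(np.var(y)), 1e-300)
    rss = max(rss, floor)
    penalty = (len(parents) + 2) / 2.0 * np.log(n)
    return float(-(n / 2.0) * np.log(rss / n) - penalty)


def bic_score(dag: nx.DiGraph, data: pd.DataFrame) -> float:
    """Decomposable network score: sum of local scores over nodes."""
    n = len(data)
    max_parents = max((dag.in_degree(v) for v in dag), default=0)
    if n <= max_parents + 2:
        raise ValueError("too few observations for the largest parent set")
    return sum(local_score(v, tuple(sorted(dag.predecessors(v))), data) for v in dag)


def _creates_cycle(dag: nx.DiGraph, u: str, v: str) -> bool:
    return dag.has_node(v) and dag.has_node(u) and nx.has_path(dag, v, u)


def hill_climb(
    data: pd.DataFrame,
    blacklist: set[tuple[str, str]] | None = None,
    seed: int | None = None,
) -> nx.DiGraph:
    """Greedy BIC hill-climbing from the empty graph.

    Moves are single-edge additions, deletions and reversals; the best
    strictly improving move is accepted until none exists.  Ties between
    equal-score moves break lexicographically on (source, target), so the
    search is deterministic (``seed`` is accepted for interface symmetry but
    unused).  Blacklisted edges are never created, directly or by reversal.
    """
    del seed
    blacklist = blacklist or set()
    nodes = sorted(data.columns)
    dag = nx.DiGraph()
    dag.add_nodes_from(nodes)
    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def score(child: str, parents: tuple[str, ...]) -> float:
        key = (child, parents)
        if key not in cache:
            cache[key] = local_score(child, parents, data)
        return cache[key]

    def parents_of(v: str) -> tuple[str, ...]:
        return tuple(sorted(dag.predecessors(v)))

    while True:
        best_delta, best_move = MIN_IMPROVEMENT, None
        for u, v in permutations(nodes, 2):
            pv = parents_of(v)
            if not dag.has_edge(u, v):
                if (u, v) in blacklist or _creates_cycle(dag, u, v):
                    continue
                delta = score(v, tuple(sorted(pv + (u,)))) - score(v, pv)
                move = ("add", u, v)
            else:
                delta = score(v, tuple(p for p in pv if p != u)) - score(v, pv)
                move = ("del", u, v)
                # reversal considered separately below
                if delta > best_delta:
                    best_delta, best_move = delta, move
                if (v, u) not in blacklist:
                    dag.remove_edge(u, v)
                    cyclic = _creates_cycle(dag, v, u)
                    dag.add_edge(u, v)
                    if not cyclic:
                        pu = parents_of(u)
                        delta_rev = (
                            score(v, tuple(p for p in pv if p != u))
                            - score(v, pv)
                            + score(u, tuple(sorted(pu + (v,))))
                            - score(u, pu)
                        )
                        if delta_rev > best_delta:
                            best_delta, best_move = delta_rev, ("rev", u, v)
                continue
            if delta > best_delta:
                best_delta, best_move = delta, move
        if best_move is None:
            return dag
        op, u, v = best_move
        if op == "add":
            dag.add_edge(u, v)
        elif op == "del":
            dag.remove_edge(u, v)
        else:
            dag.remove_edge(u, v)
            dag.add_edge(v, u)


@dataclass
class AveragedNetwork:
    """Bootstrap model-averaged network.

    ``edges`` has one row per retained edge: source, target, strength (the
    fraction of bootstrap networks containing the edge in either direction),
    direction_confidence (fraction of edge-containing networks agreeing with
    the majority direction) and sign (+1/-1 from the Spearman correlation of
    the endpoints on the original data).
    """

    nodes: dict[str, str]  # node -> type (sdp | mirna | gene)
    edges: pd.DataFrame
    n_boot: int
    threshold: float

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node, t in self.nodes.items():
            g.add_node(node, type=t)
        for _, e in self.edges.iterrows():
            g.add_edge(e["source"], e["target"], strength=e["strength"],
                       direction_confidence=e["direction_confidence"], sign=e["sign"])
        return g

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [{"id": k, "type": v} for k, v in self.nodes.items()],
                "edges": self.edges.to_dict(orient="records"),
                "n_boot": self.n_boot,
                "threshold": self.threshold,
            },
            indent=2,
        )

    def to_dot(self) -> str:
        lines = ["digraph averaged {"]
        for k, v in self.nodes.items():
            shape = {"sdp": "box", "mirna": "ellipse", "gene": "diamond"}.get(v, "ellipse")
            lines.append(f'  "{k}" [shape={shape}];')
        for _, e in self.edges.iterrows():
            label = "+" if e["sign"] > 0 else "-"
            lines.append(
                f'  "{e["source"]}" -> "{e["target"]}" '
                f'[label="{label}", penwidth={1 + 3 * e["strength"]:.2f}];'
            )
        lines.append("}")
        return "\n".join(lines)


def bootstrap_average(
    data: pd.DataFrame,
    blacklist: set[tuple[str, str]] | None = None,
    n_boot: int = 500,
    threshold: float = 0.5,
    seed: int = 0,
    node_types: dict[str, str] | None = None,
) -> AveragedNetwork:
    """Model averaging over bootstrap resamples of the strains.

    Learns one DAG per resample, then keeps edges whose either-direction
    frequency reaches ``threshold``, oriented by majority.  If the retained
    edges form a cycle (possible under ties), the weakest edge of each cycle
    is dropped with a log notice.
    """
    if n_boot < 1:
        raise ValueError("need at least one bootstrap resample")
    blacklist = blacklist or set()
    rng = np.random.default_rng(seed)
    nodes = sorted(data.columns)
    und_counts: dict[frozenset, int] = {}
    dir_counts: dict[tuple[str, str], int] = {}
    n = len(data)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx].reset_index(drop=True)
        if (sample.nunique() <= 1).any():
            # degenerate resample (constant column): redraw
            while (sample.nunique() <= 1).any():
                idx = rng.integers(0, n, size=n)
                sample = data.iloc[idx].reset_index(drop=True)
        dag = hill_climb(sample, blacklist=blacklist)
        for u, v in dag.edges:
            und_counts[frozenset((u, v))] = und_counts.get(frozenset((u, v)), 0) + 1
            dir_counts[(u, v)] = dir_counts.get((u, v), 0) + 1

    rows = []
    for pair, cnt in und_counts.items():
        strength = cnt / n_boot
        if strength < threshold:
            continue
        u, v = sorted(pair)
        fwd, bwd = dir_counts.get((u, v), 0), dir_counts.get((v, u), 0)
        if bwd > fwd or ((bwd == fwd) and (v, u) not in blacklist and (u, v) in blacklist):
            u, v = v, u
            fwd, bwd = bwd, fwd
        rho = stats.spearmanr(data[u], data[v]).statistic
        rows.append(
            {
                "source": u,
                "target": v,
                "strength": strength,
                "direction_confidence": fwd / cnt,
                "sign": 1 if rho >= 0 else -1,
            }
        )
    edges = pd.DataFrame(
        rows, columns=["source", "target", "strength", "direction_confidence", "sign"]
    ).sort_values(["source", "target"]).reset_index(drop=True)
    edges = _break_cycles(edges)
    types = node_types or {v: "unknown" for v in nodes}
    return AveragedNetwork(nodes=types, edges=edges, n_boot=n_boot, threshold=threshold)


def _break_cycles(edges: pd.DataFrame) -> pd.DataFrame:
    g = nx.DiGraph()
    for _, e in edges.iterrows():
        g.add_edge(e["source"], e["target"], strength=e["strength"])
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return edges
        weakest = min(cycle, key=lambda uv: g.edges[uv]["strength"])
        log.warning("averaged network contained a cycle; dropping edge %s", weakest)
        g.remove_edge(*weakest)
        keep = ~((edges["source"] == weakest[0]) & (edges["target"] == weakest[1]))
        edges = edges[keep].reset_index(drop=True)


class GaussianNetwork:
    """Model object for one locus network: an SDP plus its associated traits.

    ``data`` holds one column per node (the SDP's 0/1 genotype and the
    strain-mean expression of every miRNA and gene associated with it); edges
    into any SDP node are blacklisted automatically.
    """

    def __init__(self, data: pd.DataFrame, sdp_nodes: list[str],
                 node_types: dict[str, str] | None = None) -> None:
        unknown = [s for s in sdp_nodes if s not in data.columns]
        if unknown:
            raise ValueError(f"sdp nodes absent from data: {unknown}")
        self.data = data
        self.sdp_nodes = list(sdp_nodes)
        self.node_types = node_types or {
            c: ("sdp" if c in sdp_nodes else "unknown") for c in data.columns
        }
        self.blacklist = {
            (u, s) for s in sdp_nodes for u in data.columns if u != s
        }

    def fit(self, seed: int | None = None) -> "NetworkResults":
        dag = hill_climb(self.data, blacklist=self.blacklist, seed=seed)
        return NetworkResults(self, dag, bic_score(dag, self.data))

    def fit_averaged(
        self, n_boot: int = 500, threshold: float = 0.5, seed: int = 0
    ) -> AveragedNetwork:
        return bootstrap_average(
            self.data,
            blacklist=self.blacklist,
            n_boot=n_boot,
            threshold=threshold,
            seed=seed,
            node_types=self.node_types,
        )


class NetworkResults:
    def __init__(self, model: GaussianNetwork, dag: nx.DiGraph, score: float) -> None:
        self.model = model
        self.dag = dag
        self.score = score

    def summary(self) -> str:
        lines = [
            "Gaussian Bayesian network (hill-climbing, BIC)",
            "==============================================",
            f"nodes: {self.dag.number_of_nodes()}  edges: {self.dag.number_of_edges()}",
            f"BIC score: {self.score:.3f}",
        ]
        for u, v in sorted(self.dag.edges):
            lines.append(f"  {u} -> {v}")
        return "\n".join(lines)
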