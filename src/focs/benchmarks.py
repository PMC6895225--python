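"""Synthetic-network generators and calibration/power experiments.

Everything here is driven by explicit configs and a seed, so the package's
statistical claims are checkable without downloading any data: degree
sequences from a truncated power law, configuration-model (community-less)
null graphs, planted-partition graphs with a tunable mixing parameter, an
empirical false-positive-rate experiment against detected communities on
null graphs, and a power curve over the mixing parameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_RHO, focs_score
from .errors import ParameterError
from .graph import Community, Graph
from .null_model import NullParams  # noqa: F401  (re-exported for configs)

logger = logging.getLogger(__name__)

__all__ = [
    "NullExperimentConfig",
    "PowerExperimentConfig",
    "sample_powerlaw_degrees",
    "configuration_model_graph",
    "planted_partition_graph",
    "louvain_detector",
    "greedy_modularity_detector",
    "null_calibration",
    "power_curve",
]

DEFAULT_ALPHA_GRID = (0.05, 0.1, 0.25, 0.5)


@dataclass(frozen=True)
class NullExperimentConfig:
    """Setup for the false-positive calibration on community-less graphs."""

    n_networks: int = 200
    n_nodes: int = 100
    exponent: float = -2.0
    degree_range: tuple[int, int] = (10, 50)
    seed: int = 0
    alphas: tuple[float, ...] = DEFAULT_ALPHA_GRID
    rho: float = DEFAULT_RHO
    simple_graphs: bool = True

    def __post_init__(self):
        dmin, dmax = self.degree_range
        if self.n_nodes < dmax + 1:
            raise ParameterError(
                f"n_nodes={self.n_nodes} too small for max degree {dmax}"
            )
        if self.exponent >= 0:
            raise ParameterError("degree exponent must be negative")
        if any(not 0.0 < a < 1.0 for a in self.alphas):
            raise ParameterError("alpha grid must lie in (0, 1)")


@dataclass(frozen=True)
class PowerExperimentConfig:
    """Setup for the detection-power sweep over the mixing parameter."""

    n_nodes: int = 1000
    community_size_range: tuple[int, int] = (10, 50)
    mu_grid: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    n_reps: int = 5
    degree_range: tuple[int, int] = (10, 50)
    exponent: float = -2.0
    seed: int = 0
    rho: float = DEFAULT_RHO

    def __post_init__(self):
        if any(not 0.0 <= mu <= 1.0 for mu in self.mu_grid):
            raise ParameterError("mixing parameters must lie in [0, 1]")
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        smin, smax = self.community_size_range
        if smin < 3 or smax < smin or smax > self.n_nodes:
            raise ParameterError(
                f"community size range {self.community_size_range} incompatible "
                f"with n_nodes={self.n_nodes}"
            )


def sample_powerlaw_degrees(
    n: int,
    exponent: float,
    dmin: int,
    dmax: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """i.i.d. degrees with P(d) proportional to d**exponent on [dmin, dmax].

    The sum is forced even by resampling single entries, so the sequence is
    always realizable by stub matching.
    """
    if dmin < 1 or dmax < dmin:
        raise ParameterError(f"invalid degree range [{dmin}, {dmax}]")
    if exponent >= 0:
        raise ParameterError("exponent must be negative")
    values = np.arange(dmin, dmax + 1)
    weights = values.astype(float) ** exponent
    probs = weights / weights.sum()
    degrees = rng.choice(values, size=n, p=probs)
    while degrees.sum() % 2 != 0:
        degrees[rng.integers(n)] = rng.choice(values, p=probs)
    return degrees


def configuration_model_graph(
    degrees,
    rng: np.random.Generator,
    nodes: list[str] | None = None,
    simple: bool = False,
) -> Graph:
    """Uniform stub matching of the degree sequence into a multigraph.

    Self-loop pairs are dropped (consistently with the loader), so realized
    degrees can fall short of the request by the dropped stubs.  Multi-edges
    are kept by default; ``simple=True`` additionally collapses repeated
    pairs to a single edge (the usual simplified configuration model).
    """
    degrees = np.asarray(degrees, dtype=int)
    if degrees.sum() % 2 != 0:
        raise ParameterError("degree sum must be even")
    if nodes is None:
        width = len(str(max(len(degrees) - 1, 0)))
        nodes = [f"n{i:0{width}d}" for i in range(len(degrees))]
    stubs = np.repeat(np.arange(len(degrees)), degrees)
    rng.shuffle(stubs)
    edges = []
    seen: set[tuple[int, int]] = set()
    n_loops = 0
    for i in range(0, len(stubs) - 1, 2):
        u, v = int(stubs[i]), int(stubs[i + 1])
        if u == v:
            n_loops += 1
            continue
        if simple:
            key = (u, v) if u < v else (v, u)
            if key in seen:
                continue
            seen.add(key)
        edges.append((nodes[u], nodes[v], 1))
    if n_loops:
        logger.info("configuration model: dropped %d self-loop pair(s)", n_loops)
    graph = Graph(edges, nodes=nodes)
    graph.n_self_loops_dropped = n_loops
    return graph


def _draw_community_sizes(n: int, smin: int, smax: int, rng) -> list[int]:
    sizes = []
    remaining = n
    while remaining > 0:
        s = int(rng.integers(smin, smax + 1))
        if remaining - s < smin:
            s = remaining  # absorb the tail into the final community
        sizes.append(min(s, remaining))
        remaining -= sizes[-1]
    return sizes


def planted_partition_graph(
    config: PowerExperimentConfig,
    mu: float,
    rng: np.random.Generator,
) -> tuple[Graph, list[Community]]:
    """Graph with planted communities at mixing parameter ``mu``.

    Each node splits its stubs binomially: a fraction ``1 - mu`` (in
    expectation) is matched within its community, the rest in a global
    external pool.  ``mu = 0`` yields externally disconnected communities;
    ``mu = 1`` removes any within-community preference.
    """
    if not 0.0 <= mu <= 1.0:
        raise ParameterError(f"mu must be in [0, 1], got {mu}")
    n = config.n_nodes
    smin, smax = config.community_size_range
    sizes = _draw_community_sizes(n, smin, smax, rng)
    width = len(str(n - 1))
    nodes = [f"n{i:0{width}d}" for i in range(n)]
    degrees = sample_powerlaw_degrees(
        n, config.exponent, config.degree_range[0], config.degree_range[1], rng
    )

    membership = np.empty(n, dtype=int)
    start = 0
    blocks = []
    for ci, s in enumerate(sizes):
        membership[start:start + s] = ci
        blocks.append(list(range(start, start + s)))
        start += s

    internal = rng.binomial(degrees, 1.0 - mu)
    edges: list[tuple[str, str, int]] = []
    external_stubs: list[int] = []
    for ci, block in enumerate(blocks):
        block_internal = internal[block].copy()
        if block_internal.sum() % 2 != 0:
            # discard one internal stub to fix parity (never leaks a
            # boundary edge, so mu = 0 stays exactly disconnected)
            j = int(rng.choice(np.nonzero(block_internal > 0)[0]))
            block_internal[j] -= 1
            degrees = degrees.copy()
            degrees[block[j]] -= 1
        stubs = np.repeat(np.asarray(block, dtype=int), block_internal)
        rng.shuffle(stubs)
        for i in range(0, len(stubs) - 1, 2):
            u, v = stubs[i], stubs[i + 1]
            if u != v:
                edges.append((nodes[u], nodes[v], 1))
        for j, node_idx in enumerate(block):
            external_stubs.extend([node_idx] * int(degrees[node_idx] - block_internal[j]))

    ext = np.asarray(external_stubs, dtype=int)
    rng.shuffle(ext)
    if len(ext) % 2 != 0:
        ext = ext[:-1]
    for i in range(0, len(ext) - 1, 2):
        u, v = ext[i], ext[i + 1]
        if u != v:
            edges.append((nodes[u], nodes[v], 1))

    graph = Graph(edges, nodes=nodes)
    communities = [
        Community(frozenset(nodes[i] for i in block), id=f"pp{ci}")
        for ci, block in enumerate(blocks)
    ]
    return graph, communities


def louvain_detector(graph: Graph, seed: int) -> list[frozenset]:
    """Partition via the Louvain algorithm (multiplicities as weights)."""
    import networkx as nx

    g = graph.to_networkx()
    parts = nx.community.louvain_communities(g, weight="weight", seed=seed)
    return [frozenset(p) for p in parts]


def greedy_modularity_detector(graph: Graph, seed: int = 0) -> list[frozenset]:
    """Deterministic greedy-modularity fallback detector."""
    import networkx as nx

    g = graph.to_networkx()
    parts = nx.community.greedy_modularity_communities(g, weight="weight")
    return [frozenset(p) for p in parts]


def karate_club_graph() -> Graph:
    """The 34-node karate-club social network (from networkx)."""
    import networkx as nx

    kg = nx.karate_club_graph()
    return Graph([(str(u), str(v), 1) for u, v in kg.edges()])


def best_modularity_partition(
    graph: Graph,
    n_runs: int = 50,
    seed: int = 0,
    detector=louvain_detector,
) -> list[frozenset]:
    """Best-of-``n_runs`` detector partition by (weighted) modularity."""
    import networkx as nx

    g = graph.to_networkx()
    rng = np.random.default_rng(seed)
    best, best_q = None, -np.inf
    for _ in range(n_runs):
        parts = detector(graph, seed=int(rng.integers(2**31 - 1)))
        q = nx.community.modularity(g, parts, weight="weight")
        if q > best_q:
            best, best_q = parts, q
    return best


@dataclass(frozen=True)
class CalibrationResult:
    """Empirical false-positive rates of the score on null graphs."""

    table: pd.DataFrame  # columns: alpha, fpr, se, n
    scores: tuple[float, ...]
    n_skipped: int = 0

    def max_calibrated_alpha(self, slack_se: float = 2.0) -> float:
        """Largest grid alpha such that fpr <= alpha + slack_se * se for
        every grid point up to and including it; 0.0 if none."""
        best = 0.0
        for row in self.table.itertuples():
            if row.fpr <= row.alpha + slack_se * row.se:
                best = row.alpha
            else:
                break
        return best


def null_calibration(
    config: NullExperimentConfig,
    detector=louvain_detector,
) -> CalibrationResult:
    """Empirical FPR of the score on configuration-model graphs.

    Per network: detect communities, pick one of size > 2 uniformly at
    random, score it.  Networks without a non-trivial community are skipped
    (and counted); denominators use scored networks only.
    """
    rng = np.random.default_rng(config.seed)
    scores = []
    n_skipped = 0
    for rep in range(config.n_networks):
        degrees = sample_powerlaw_degrees(
            config.n_nodes, config.exponent,
            config.degree_range[0], config.degree_range[1], rng,
        )
        graph = configuration_model_graph(degrees, rng, simple=config.simple_graphs)
        parts = detector(graph, seed=int(rng.integers(2**31 - 1)))
        candidates = [p for p in parts if 2 < len(p) < graph.n_nodes]
        if not candidates:
            n_skipped += 1
            logger.info("network %d: no non-trivial community, skipped", rep)
            continue
        chosen = candidates[int(rng.integers(len(candidates)))]
        community = Community(chosen, id=f"net{rep}")
        result = focs_score(
            graph, community, config.rho, seed=int(rng.integers(2**31 - 1))
        )
        scores.append(result.score)
        if (rep + 1) % 25 == 0:
            logger.info("calibration: %d/%d networks scored", rep + 1, config.n_networks)
    arr = np.asarray(scores)
    rows = []
    for alpha in config.alphas:
        fpr = float((arr <= alpha).mean()) if len(arr) else float("nan")
        se = math.sqrt(fpr * (1 - fpr) / len(arr)) if len(arr) else float("nan")
        rows.append({"alpha": alpha, "fpr": fpr, "se": se, "n": len(arr)})
    return CalibrationResult(
        table=pd.DataFrame(rows), scores=tuple(scores), n_skipped=n_skipped
    )


def power_curve(
    config: PowerExperimentConfig,
    detector=None,
) -> pd.DataFrame:
    """Median and 5%/95% percentile score per mixing parameter.

    Ground-truth planted communities are scored unless a detector is given,
    in which case its non-trivial communities are scored instead.  Returns a
    frame with columns (mu, median_score, q05, q95, n).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for mu in config.mu_grid:
        scores = []
        for _ in range(config.n_reps):
            graph, truth = planted_partition_graph(config, mu, rng)
            if detector is not None:
                parts = detector(graph, seed=int(rng.integers(2**31 - 1)))
                communities = [
                    Community(p, id=f"det{i}")
                    for i, p in enumerate(parts)
                    if 2 < len(p) < graph.n_nodes
                ]
            else:
                communities = truth
            for community in communities:
                result = focs_score(
                    graph, community, config.rho, seed=int(rng.integers(2**31 - 1))
                )
                scores.append(result.score)
        arr = np.asarray(scores)
        rows.append({
            "mu": mu,
            "median_score": float(np.median(arr)),
            "q05": float(np.quantile(arr, 0.05)),
            "q95": float(np.quantile(arr, 0.95)),
            "n": len(arr),
        })
        logger.info("power: mu=%.2f done (%d communities)", mu, len(arr))
    return pd.DataFrame(rows)
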