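"""Spearman correlation networks over sampled fluxes.

Correlated reaction sets are read off the sampling output: the Spearman rank
correlation of every reaction pair is computed from the sampled flux vectors,
pairs with |rho| >= 0.7 become edges of an undirected graph, nodes carry their
subsystem annotation, and the connected components of the thresholded graph
are reported as modules.  Rank correlation makes the result invariant to any
strictly monotone rescaling of individual fluxes.

Fluxes pinned by the constraints (zero-variance columns) carry no rank
information and are excluded with a logged warning rather than producing NaN
edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .flux_sampling import FluxSampleSet

logger = logging.getLogger(__name__)

RHO_THRESHOLD = 0.7


class CorrelationError(ValueError):
    pass


def spearman_matrix(
    sample: FluxSampleSet, reaction_subset: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Spearman rho over the sampled flux vectors of a subset.

    Zero-variance (constraint-fixed) columns are dropped with a warning; an
    all-constant subset is an error.
    """
    rids = list(reaction_subset) if reaction_subset is not None else list(sample.reaction_ids)
    if not rids:
        raise CorrelationError("empty reaction subset")
    missing = [r for r in rids if r not in sample.reaction_ids]
    if missing:
        raise CorrelationError(f"reactions not in sample: {missing}")
    cols = [sample.reaction_ids.index(r) for r in rids]
    X = sample.matrix[:, cols]
    variable = np.ptp(X, axis=0) > 0  # exact: a pinned flux has zero range
    dropped = [r for r, v in zip(rids, variable) if not v]
    if dropped:
        logger.warning(
            "excluding %d zero-variance flux column(s) from correlation: %s",
            len(dropped), dropped,
        )
    rids = [r for r, v in zip(rids, variable) if v]
    if not rids:
        raise CorrelationError("all columns in the subset are constant")
    X = X[:, variable]
    if len(rids) == 1:
        rho = np.ones((1, 1))
    else:
        stat = stats.spearmanr(X).statistic
        if np.ndim(stat) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, float(stat)], [float(stat), 1.0]])
        else:
            rho = np.asarray(stat)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=rids, columns=rids)


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    condition: str = ""
    threshold: float = RHO_THRESHOLD
    modules: list[frozenset[str]] = field(init=False)

    def __post_init__(self):
        comps = sorted(
            (frozenset(c) for c in nx.connected_components(self.graph)),
            key=lambda c: sorted(c)[0],
        )
        self.modules = list(comps)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"reaction_i": u, "reaction_j": v, "rho": d["rho"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["reaction_i", "reaction_j", "rho"])

    def module_table(self) -> pd.DataFrame:
        rows = []
        for k, mod in enumerate(self.modules):
            for rid in sorted(mod):
                rows.append(
                    {
                        "reaction": rid,
                        "module": k,
                        "subsystem": self.graph.nodes[rid].get("subsystem", ""),
                    }
                )
        return pd.DataFrame(rows, columns=["reaction", "module", "subsystem"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for u, v, d in self.graph.edges(data=True):
                rel = "pos_corr" if d["rho"] >= 0 else "neg_corr"
                fh.write(f"{u}\t{rel}\t{v}\n")
            for node in self.graph.nodes:
                if self.graph.degree[node] == 0:
                    fh.write(f"{node}\n")


def threshold_network(
    rho: pd.DataFrame,
    threshold: float = RHO_THRESHOLD,
    subsystems: dict[str, str] | None = None,
    condition: str = "",
) -> CorrelationNetwork:
    """Adjacency at |rho| >= threshold (boundary included); modules are the
    connected components of the resulting graph."""
    subsystems = subsystems or {}
    g = nx.Graph()
    rids = list(rho.index)
    for rid in rids:
        g.add_node(rid, subsystem=subsystems.get(rid, ""))
    vals = rho.to_numpy()
    for i in range(len(rids)):
        for j in range(i + 1, len(rids)):
            if abs(vals[i, j]) >= threshold:
                g.add_edge(rids[i], rids[j], rho=float(vals[i, j]))
    return CorrelationNetwork(graph=g, condition=condition, threshold=threshold)


def count_correlations(network: CorrelationNetwork, reaction_subset: list[str] | None = None) -> int:
    """Number of edges with both endpoints inside the subset."""
    if reaction_subset is None:
        return network.n_edges
    nodes = set(reaction_subset)
    unknown = nodes - set(network.graph.nodes)
    if unknown:
        raise CorrelationError(f"subset nodes absent from network: {sorted(unknown)}")
    return sum(1 for u, v in network.graph.edges if u in nodes and v in nodes)


def leiden_like_modules(network: CorrelationNetwork, seed: int = 0) -> list[frozenset[str]]:
    """Optional modularity-based community split (greedy modularity).

    Not part of the reference procedure — connected components are the
    default module definition; this exists for exploratory use.
    """
    comms = nx.algorithms.community.greedy_modularity_communities(
        network.graph, weight=None
    )
    return [frozenset(c) for c in comms]
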