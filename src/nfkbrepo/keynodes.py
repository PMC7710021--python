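"""Master-regulator (key node) search on a directed signalling network.

Every node is scored as a candidate master regulator of an *input set* (the
NF-κB complex components): with R the set of nodes reachable from the
candidate in at most ``radius`` directed steps (default 10), the key-node
score is the weighted ratio

    score = (|R ∩ inputs| + w_c · |R ∩ context|) / max(|R|, 1)

where *context proteins* (disease-relevant proteins supplied externally, e.g.
from text mining) up-weight a candidate with weight ``w_c`` (default 2).  A
high score means the candidate feeds signal specifically into the input set
rather than broadcasting widely.

Significance is empirical: pseudo-input and pseudo-context sets of matching
sizes are redrawn uniformly from the node universe ``n_random`` times, each
node's null score distribution yields a Z-score and a permutation p-value,
and Benjamini–Hochberg converts p-values to FDR.  Controlling nodes are those
with FDR <= 0.05 and Z >= 1.0 (both inclusive); intersecting them with a
disease target-gene list names the therapeutic key nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


class NetworkParseError(ValueError):
    pass


@dataclass
class SignalingNetwork:
    """Directed signalling graph; an edge u -> v means signal flows u to v."""

    graph: nx.DiGraph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "SignalingNetwork":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return cls(g)


@dataclass
class AnalysisInputs:
    """Seed configuration for the key-node search."""

    input_set: frozenset[str]
    context_set: frozenset[str] = frozenset()
    context_weight: float = 2.0
    radius: int = 10

    def __post_init__(self) -> None:
        self.input_set = frozenset(self.input_set)
        self.context_set = frozenset(self.context_set)
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.context_weight <= 0:
            raise ValueError("context weight must be > 0")


def load_network(path: str | Path) -> SignalingNetwork:
    """Read a directed edge list (``from<TAB>to[<TAB>type]``); duplicates collapse."""
    g = nx.DiGraph()
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise NetworkParseError(f"{path}:{ln}: expected 'from<TAB>to', got {line!r}")
        g.add_edge(fields[0].strip(), fields[1].strip())
    return SignalingNetwork(g)


def write_network(net: SignalingNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(net.graph.edges):
            fh.write(f"{u}\t{v}\n")


def reachable_within(net: SignalingNetwork, node: str, radius: int) -> frozenset[str]:
    """Nodes reachable from ``node`` in <= ``radius`` directed steps, excluding itself."""
    if node not in net.graph:
        raise KeyError(f"node {node!r} not in network")
    dist = nx.single_source_shortest_path_length(net.graph, node, cutoff=radius)
    return frozenset(n for n in dist if n != node)


@dataclass(frozen=True)
class KeyNodeScore:
    node: str
    reached_input_weight: float
    total_reachable: int
    score: float


def key_node_score(net: SignalingNetwork, node: str, inputs: AnalysisInputs) -> KeyNodeScore:
    """Weighted-ratio master-regulator score of one candidate node."""
    reach = reachable_within(net, node, inputs.radius)
    weight = len(reach & inputs.input_set) + inputs.context_weight * len(
        reach & inputs.context_set
    )
    return KeyNodeScore(
        node=node,
        reached_input_weight=float(weight),
        total_reachable=len(reach),
        score=float(weight) / max(len(reach), 1),
    )


def score_all(net: SignalingNetwork, inputs: AnalysisInputs) -> pd.DataFrame:
    """Score every node; rows sorted by descending score, ties by node id."""
    rows = [key_node_score(net, n, inputs) for n in net.nodes]
    df = pd.DataFrame(
        {
            "node": [r.node for r in rows],
            "reached_input_weight": [r.reached_input_weight for r in rows],
            "total_reachable": [r.total_reachable for r in rows],
            "score": [r.score for r in rows],
        }
    )
    return df.sort_values(["score", "node"], ascending=[False, True]).reset_index(drop=True)


def _reach_matrix(net: SignalingNetwork, radius: int) -> tuple[list[str], np.ndarray]:
    """Boolean node x node matrix: entry (i, j) iff j reachable from i."""
    nodes = net.nodes
    index = {n: i for i, n in enumerate(nodes)}
    mat = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for n in nodes:
        for m in reachable_within(net, n, radius):
            mat[index[n], index[m]] = True
    return nodes, mat


def empirical_significance(
    net: SignalingNetwork,
    inputs: AnalysisInputs,
    scores: pd.DataFrame | None = None,
    n_random: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach empirical Z, permutation p and BH-FDR to every node's score.

    Each of ``n_random`` replicates redraws disjoint pseudo-input and
    pseudo-context sets of the observed sizes uniformly from the node
    universe (one permutation per replicate) and rescores all nodes.  Then
    ``z = (score - null mean) / null sd`` (0 when the null is degenerate) and
    ``p_emp = (1 + #{null >= observed}) / (n_random + 1)``.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    if scores is None:
        scores = score_all(net, inputs)
    nodes, reach = _reach_matrix(net, inputs.radius)
    n = len(nodes)
    k_in, k_ctx = len(inputs.input_set), len(inputs.context_set)
    if k_in + k_ctx > n:
        raise ValueError("input + context sets larger than the network")
    denom = np.maximum(reach.sum(axis=1), 1).astype(float)

    rng = np.random.default_rng(seed)
    weight_cols = np.zeros((n, n_random))
    for r in range(n_random):
        perm = rng.permutation(n)
        w = np.zeros(n)
        w[perm[:k_in]] = 1.0
        w[perm[k_in : k_in + k_ctx]] = inputs.context_weight
        weight_cols[:, r] = w
    null_scores = (reach.astype(float) @ weight_cols) / denom[:, None]

    obs = scores.set_index("node").loc[nodes, "score"].to_numpy()
    mu = null_scores.mean(axis=1)
    sd = null_scores.std(axis=1)
    z = np.where(sd > 0, (obs - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    p_emp = (1.0 + (null_scores >= obs[:, None]).sum(axis=1)) / (n_random + 1.0)
    fdr = multipletests(p_emp, method="fdr_bh")[1]

    out = scores.set_index("node").copy()
    out.loc[nodes, "z"] = z
    out.loc[nodes, "p_emp"] = p_emp
    out.loc[nodes, "fdr"] = fdr
    return (
        out.reset_index()
        .sort_values(["z", "node"], ascending=[False, True])
        .reset_index(drop=True)
    )


def select_controlling_nodes(
    table: pd.DataFrame, fdr_max: float = 0.05, z_min: float = 1.0
) -> list[str]:
    """Nodes passing both cut-offs (fdr <= fdr_max and z >= z_min, inclusive)."""
    keep = table[(table["fdr"] <= fdr_max) & (table["z"] >= z_min)]
    return keep["node"].tolist()


def intersect_with_targets(
    controlling_nodes: Iterable[str],
    disease_targets: pd.DataFrame | Iterable[str],
) -> pd.DataFrame:
    """Intersect controlling nodes with a disease target list (case-insensitive).

    ``disease_targets`` may be a plain symbol iterable or a DataFrame with a
    ``symbol`` column plus arbitrary evidence columns, which are carried
    through for each key node.
    """
    if not isinstance(disease_targets, pd.DataFrame):
        disease_targets = pd.DataFrame({"symbol": list(disease_targets)})
    nodes = {n.upper(): n for n in controlling_nodes}
    mask = disease_targets["symbol"].astype(str).str.upper().isin(nodes)
    hits = disease_targets[mask].copy()
    hits.insert(0, "node", [nodes[s.upper()] for s in hits["symbol"].astype(str)])
    return hits.sort_values("node").reset_index(drop=True)
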