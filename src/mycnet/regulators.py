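"""Master-regulator search over a directed signed interaction network.

A master regulator is a node lying upstream of a disproportionate share of an
input gene set: traversal runs from the candidate along edge direction, and
genes reached within ``max_radius`` directed steps contribute decay-weighted
mass.  The score is the reconstruction

    score = [ sum_{g in reached inputs} decay^(d(g)-1)
              - penalty * sum_{v in reached non-inputs} decay^(d(v)-1) ]
            / max(1, sum_{v in all reached} decay^(d(v)-1))

so a candidate whose only reached node is a single direct input scores exactly
1, off-target reach is penalized, and score lies in [-penalty, 1].
Significance comes from permuting the input set over the network's genes:
a Z-score against the permutation null and Benjamini-Hochberg q-values over
the empirical permutation p-values.  Edge signs (activation / inhibition /
regulation) are carried through for reporting but do not alter traversal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._util import pct_half_up

logger = logging.getLogger(__name__)

EDGE_TYPES = ("activation", "inhibition", "regulation")
#: specific signed annotations outrank the generic one when collapsing
_TYPE_RANK = {"activation": 2, "inhibition": 2, "regulation": 1}


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class MRParams:
    max_radius: int = 4
    decay: float = 0.1
    penalty: float = 0.1
    score_cutoff: float = 0.2
    z_cutoff: float = 1.0
    fdr_cutoff: float = 0.05
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_radius < 1:
            raise NetworkError("max_radius must be >= 1")
        for name in ("decay", "penalty"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise NetworkError(f"{name} must lie in (0, 1]")


@dataclass(frozen=True)
class MasterRegulatorResult:
    node: str
    reached_inputs: dict[str, int]
    score: float
    z_score: float
    fdr_q: float
    passes: bool
    network_fraction: float  # reached inputs / |input set|


def load_network(path: str | Path) -> nx.DiGraph:
    """Read a directed edge list TSV (source, target[, type]).

    Self-loops are dropped and parallel edges collapsed, keeping the more
    specific annotation (activation/inhibition over plain regulation).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str).iloc[:, :3]
    df.columns = ["source", "target", "type"][: df.shape[1]]
    if "type" not in df.columns:
        df["type"] = "regulation"
    df["type"] = df["type"].fillna("regulation")
    bad = set(df["type"]) - set(EDGE_TYPES)
    if bad:
        raise NetworkError(f"unknown interaction type(s): {sorted(bad)}")
    g = nx.DiGraph()
    for src, tgt, typ in df.itertuples(index=False):
        if src == tgt:
            warnings.warn(f"self-loop on {src!r} dropped", stacklevel=2)
            continue
        if g.has_edge(src, tgt):
            old = g[src][tgt]["type"]
            keep = typ if _TYPE_RANK[typ] > _TYPE_RANK[old] else old
            warnings.warn(f"duplicate edge {src}->{tgt} collapsed (kept {keep!r})", stacklevel=2)
            g[src][tgt]["type"] = keep
            continue
        g.add_edge(src, tgt, type=typ)
    logger.info("network: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return g


def downstream_distances(net: nx.DiGraph, candidate: str, max_radius: int) -> dict[str, int]:
    """Shortest directed distances (1..max_radius) from candidate, itself excluded."""
    if candidate not in net:
        raise NetworkError(f"candidate {candidate!r} absent from network")
    dist = nx.single_source_shortest_path_length(net, candidate, cutoff=max_radius)
    dist.pop(candidate, None)
    return dist


def reachable_inputs(
    net: nx.DiGraph, candidate: str, input_genes: Iterable[str], max_radius: int
) -> dict[str, int]:
    """Distance map restricted to input genes reached within max_radius."""
    inputs = set(input_genes)
    return {g: d for g, d in downstream_distances(net, candidate, max_radius).items() if g in inputs}


def mr_score(distances: Mapping[str, int], input_genes: Iterable[str], params: MRParams) -> float:
    """Decay-weighted input mass, penalized off-target mass, normalized total mass."""
    inputs = set(input_genes)
    w_in = w_out = 0.0
    for node, d in distances.items():
        w = params.decay ** (d - 1)
        if node in inputs:
            w_in += w
        else:
            w_out += w
    return (w_in - params.penalty * w_out) / max(1.0, w_in + w_out)


def _all_reach(net: nx.DiGraph, params: MRParams) -> dict[str, dict[str, int]]:
    return {n: downstream_distances(net, n, params.max_radius) for n in net.nodes}


def recommended_permutations(n_candidates: int, fdr: float = 0.05, margin: float = 2.0) -> int:
    """Permutations needed so a lone true positive can clear BH at the given FDR.

    The smallest achievable empirical p with +1 smoothing is 1/(B+1); for it to
    survive Benjamini-Hochberg alone among ``n_candidates`` tests we need
    1/(B+1) <= fdr / n_candidates, padded by ``margin``.
    """
    return max(1000, int(np.ceil(margin * n_candidates / fdr)))


def mr_significance(
    net: nx.DiGraph,
    input_genes: Iterable[str],
    params: MRParams,
    reach: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """Permutation Z-scores and BH q-values for every candidate node.

    The null redraws input sets of equal size uniformly from the network's
    nodes; reachability is fixed, so each permutation only reweights which
    reached nodes count as inputs.  With w_tot the candidate's total decay
    mass and w_in the mass on the (permuted) inputs,

        score = ((1 + penalty) * w_in - penalty * w_tot) / max(1, w_tot),

    so the whole null is one weight-matrix x indicator-matrix product.
    Empirical p-values use +1 smoothing.
    """
    if params.n_permutations < 100:
        raise NetworkError("n_permutations must be >= 100")
    inputs = sorted(set(input_genes))
    if not inputs:
        raise NetworkError("empty input set")
    reach = reach if reach is not None else _all_reach(net, params)
    nodes = sorted(net.nodes)
    node_index = {n: j for j, n in enumerate(nodes)}
    N = len(nodes)
    rng = np.random.default_rng(params.seed)

    W = np.zeros((N, N))  # W[cand, target] = decay^(d-1)
    for j, n in enumerate(nodes):
        for tgt, d in reach[n].items():
            W[j, node_index[tgt]] = params.decay ** (d - 1)
    w_tot = W.sum(axis=1)
    denom = np.maximum(1.0, w_tot)

    def scores(indicator: np.ndarray) -> np.ndarray:
        w_in = W @ indicator
        return ((1 + params.penalty) * w_in.T - params.penalty * w_tot).T / denom[:, None]

    obs_ind = np.zeros((N, 1))
    obs_ind[[node_index[g] for g in inputs if g in node_index], 0] = 1.0
    obs = scores(obs_ind)[:, 0]

    k = min(len(inputs), N)
    B = params.n_permutations
    ind = np.zeros((N, B))
    for b in range(B):
        ind[rng.choice(N, size=k, replace=False), b] = 1.0
    perm = scores(ind)  # (N, B)

    mean = perm.mean(axis=1)
    sd = perm.std(axis=1, ddof=1)
    z = np.zeros(N)
    nonzero = sd > 0
    z[nonzero] = (obs[nonzero] - mean[nonzero]) / sd[nonzero]
    if not nonzero.all():
        warnings.warn(f"{int((~nonzero).sum())} candidate(s) with degenerate null: z set to 0",
                      stacklevel=2)
    emp_p = (1 + (perm >= obs[:, None]).sum(axis=1)) / (B + 1)
    q = multipletests(emp_p, method="fdr_bh")[1]
    return pd.DataFrame({"node": nodes, "score": obs, "z_score": z, "p_value": emp_p, "fdr_q": q})


def rank_master_regulators(
    net: nx.DiGraph,
    input_genes: Iterable[str],
    params: MRParams,
) -> list[MasterRegulatorResult]:
    """Score, test and rank every node as a candidate master regulator.

    Ordering: passing candidates first, then score, then Z, then node id for
    deterministic ties.  ``network_fraction`` is the integer half-up percentage
    of input genes reached within the radius.
    """
    inputs = sorted(set(input_genes))
    if not inputs:
        raise NetworkError("empty input set")
    reach = _all_reach(net, params)
    stats = mr_significance(net, inputs, params, reach=reach).set_index("node")
    input_set = set(inputs)
    results = []
    for node in stats.index:
        reached = {g: d for g, d in reach[node].items() if g in input_set}
        row = stats.loc[node]
        passes = (
            row["score"] >= params.score_cutoff
            and row["z_score"] >= params.z_cutoff
            and row["fdr_q"] <= params.fdr_cutoff
        )
        results.append(
            MasterRegulatorResult(
                node=node,
                reached_inputs=reached,
                score=float(row["score"]),
                z_score=float(row["z_score"]),
                fdr_q=float(row["fdr_q"]),
                passes=bool(passes),
                network_fraction=pct_half_up(len(reached), len(inputs)),
            )
        )
    results.sort(key=lambda r: (not r.passes, -r.score, -r.z_score, r.node))
    return results


def results_table(results: Sequence[MasterRegulatorResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.node, r.score, r.z_score, r.fdr_q, r.passes, len(r.reached_inputs), r.network_fraction)
            for r in results
        ],
        columns=["node", "score", "z_score", "fdr_q", "passes", "n_reached", "pct_of_inputs"],
    )


def export_subnetwork(
    net: nx.DiGraph,
    regulator: str,
    input_genes: Iterable[str],
    params: MRParams,
    dot_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Edges of the regulator's downstream cone (<= max_radius), DOT/TSV export."""
    dist = downstream_distances(net, regulator, params.max_radius)
    keep = set(dist) | {regulator}
    sub = net.subgraph(keep)
    inputs = set(input_genes)
    rows = [(u, v, d["type"]) for u, v, d in sub.edges(data=True)]
    df = pd.DataFrame(rows, columns=["source", "target", "type"])
    if tsv_path:
        df.to_csv(tsv_path, sep="\t", index=False)
    if dot_path:
        lines = ["digraph subnetwork {"]
        for n in sorted(keep):
            role = "regulator" if n == regulator else ("input" if n in inputs else "connector")
            lines.append(f'  "{n}" [role={role}];')
        arrow = {"activation": "normal", "inhibition": "tee", "regulation": "vee"}
        for u, v, t in rows:
            lines.append(f'  "{u}" -> "{v}" [arrowhead={arrow[t]}];')
        lines.append("}")
        Path(dot_path).write_text("\n".join(lines) + "\n")
    return df
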