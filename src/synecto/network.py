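"""Proteomic candidate filtering and Markov clustering of interaction networks.

The candidate set is defined by label-free quantitation (LFQ) fold change
between the +ligand and -ligand conditions: a protein is kept when its
linear fold change is at least the threshold (default 3.35, i.e. 1.75 in
log2) in every independent experiment.  MaxQuant-style zero inflation is
handled explicitly: detected in + and missing in - means infinite
enrichment (kept); missing in + means no enrichment (kept only when
two-sided filtering on depletion is requested).

Module structure of a confidence-scored interaction network is found with
the Markov Cluster algorithm (MCL): alternating expansion (matrix square)
and inflation (entrywise power + column normalization) of the
column-stochastic transition matrix until convergence, reading clusters
off the attractor structure of the limit matrix.  Deterministic for a
fixed input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_FC_THRESHOLD = 3.35
DEFAULT_INFLATION = 2.5
DEFAULT_MIN_MODULE_SIZE = 3


# --------------------------------------------------------------------------
# Fold-change filter

def fold_changes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein, per-experiment linear fold change plus/minus.

    ``table`` columns: protein, condition ('plus'/'minus'), experiment,
    lfq (NaN = not detected).  Missing in both conditions -> NaN fold
    change; missing only in minus -> +inf; missing only in plus -> 0.
    """
    wide = table.pivot_table(index=["protein", "experiment"],
                             columns="condition", values="lfq",
                             aggfunc="mean", dropna=False)
    plus = wide.get("plus")
    minus = wide.get("minus")
    if plus is None or minus is None:
        raise ValueError("table must contain 'plus' and 'minus' conditions")
    fc = np.where(plus.isna() & minus.isna(), np.nan,
                  np.where(minus.isna() | (minus == 0),
                           np.where(plus.isna() | (plus == 0), np.nan, np.inf),
                           np.where(plus.isna(), 0.0, plus / minus)))
    out = wide.reset_index()[["protein", "experiment"]]
    out["fold_change"] = fc
    return out


def fold_change_filter(table: pd.DataFrame,
                       threshold: float = DEFAULT_FC_THRESHOLD,
                       require_all_experiments: bool = True,
                       two_sided: bool = False) -> list[str]:
    """Candidate proteins enriched at least ``threshold``-fold.

    With ``require_all_experiments`` the criterion must hold in every
    experiment in which the protein appears (and it must appear in all).
    ``two_sided`` also keeps proteins depleted by the same factor
    (|log2 FC| >= log2(threshold)).  Proteins missing everywhere are
    excluded.  Returns ids in input order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fc = fold_changes(table)
    n_experiments = table["experiment"].nunique()

    def passes(x: float) -> bool:
        if np.isnan(x):
            return False
        if x == np.inf:
            return True
        if x <= 0:
            return bool(two_sided)  # total depletion
        if two_sided:
            return abs(np.log2(x)) >= np.log2(threshold)
        return x >= threshold

    kept = []
    for protein, sub in fc.groupby("protein", sort=False):
        vals = sub["fold_change"].to_numpy()
        if np.all(np.isnan(vals)):
            continue
        ok = [passes(v) for v in vals]
        if require_all_experiments:
            if len(vals) == n_experiments and all(ok):
                kept.append(protein)
        elif any(ok):
            kept.append(protein)
    order = {p: i for i, p in enumerate(pd.unique(table["protein"]))}
    return sorted(kept, key=lambda p: order[p])


# --------------------------------------------------------------------------
# Markov clustering

@dataclass
class ModulePartition:
    assignment: dict[str, int]     # protein -> module id
    inflation: float
    n_iterations: int

    @property
    def modules(self) -> list[list[str]]:
        by_id: dict[int, list[str]] = {}
        for node, mid in self.assignment.items():
            by_id.setdefault(mid, []).append(node)
        return [sorted(v) for _, v in sorted(by_id.items())]

    def sizes(self) -> list[int]:
        return sorted((len(m) for m in self.modules), reverse=True)


def load_edge_list(df: pd.DataFrame, min_score: float = 0.4,
                   max_score: float = 0.999) -> nx.Graph:
    """Undirected confidence-weighted graph from an (a, b, score) table.

    Self-loops are dropped; edges outside [min_score, max_score] are
    filtered out, mirroring the STRING confidence-score window.
    """
    g = nx.Graph()
    for _, row in df.iterrows():
        a, b, s = row.iloc[0], row.iloc[1], float(row.iloc[2])
        if a == b or not (min_score <= s <= max_score):
            continue
        g.add_edge(a, b, weight=s)
    return g


def mcl(graph: nx.Graph, inflation: float = DEFAULT_INFLATION,
        expansion: int = 2, prune_threshold: float = 1e-6,
        max_iterations: int = 200, tol: float = 1e-8,
        self_loops: float = 1.0) -> ModulePartition:
    """Markov Cluster algorithm on a weighted undirected graph.

    Edge confidence scores are used as transition weights; ``self_loops``
    adds a uniform diagonal before normalization (the standard MCL
    regularization ensuring convergence).  Raises ``RuntimeError`` when
    the iteration does not converge within ``max_iterations``.
    """
    nodes = sorted(graph.nodes())
    if not nodes:
        raise ValueError("edge list is empty")
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        M[index[a], index[b]] = w
        M[index[b], index[a]] = w
    M += self_loops * np.eye(n)
    M /= M.sum(axis=0, keepdims=True)

    for it in range(1, max_iterations + 1):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iterations} iterations "
            f"(residual {np.abs(M - prev).max():.2e})")

    # clusters: attractors are rows with nonzero diagonal; each attractor's
    # support (columns it attracts) forms a cluster; overlaps are merged
    attractors = np.nonzero(np.diag(M) > prune_threshold)[0]
    cover = nx.Graph()
    cover.add_nodes_from(range(n))
    for a in attractors:
        cols = np.nonzero(M[a] > prune_threshold)[0]
        for c in cols:
            cover.add_edge(int(a), int(c))
    assignment: dict[str, int] = {}
    for mid, comp in enumerate(sorted(nx.connected_components(cover),
                                      key=lambda s: (-len(s), min(s)))):
        for i in comp:
            assignment[nodes[i]] = mid
    return ModulePartition(assignment, inflation, it)


def module_filter(partition: ModulePartition,
                  min_size: int = DEFAULT_MIN_MODULE_SIZE) -> list[list[str]]:
    """Modules with at least ``min_size`` members, largest first."""
    mods = [m for m in partition.modules if len(m) >= min_size]
    return sorted(mods, key=lambda m: (-len(m), m[0] if m else ""))
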