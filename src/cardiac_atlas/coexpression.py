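"""Stage-profile co-expression network: Spearman correlation of 5-point
stage-mean profiles over the marker ∪ cancer-gene universe, BH-FDR filtering,
and network topology summaries.

With only five ordered stages the attainable Spearman values on untied
profiles are spaced 0.1 apart, so the retention rule rho > 0.99 keeps exactly
the pairs with perfectly concordant rank profiles (rho = 1).  P-values use
the t-approximation, under which rho = 1 maps to p = 0; an exact permutation
p on five points is bounded below by 1/120 and could never survive FDR
control at q < 0.01 over millions of pairs, so the approximation is the only
convention under which any edge can be retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from ._util import logger
from .cancer import GeneCatalog


@dataclass
class NetworkConfig:
    rho_threshold: float = 0.99
    fdr_threshold: float = 0.01
    # pair counting is reported ordered-with-self (n^2, the published
    # convention); tests and edges always use unordered non-self pairs
    pair_convention: str = "ordered_with_self"

    def __post_init__(self) -> None:
        if not (0 < self.rho_threshold < 1 and 0 < self.fdr_threshold < 1):
            raise ValueError("thresholds must be in (0,1)")
        if self.pair_convention not in ("ordered_with_self", "unordered_no_self"):
            raise ValueError(f"unknown pair convention: {self.pair_convention}")


def build_universe(
    markers, catalog: GeneCatalog, profile: pd.DataFrame
) -> list[str]:
    """Marker ∪ oncogene ∪ TSG symbols restricted to genes expressed in the
    data (some nonzero stage mean), deterministically ordered."""
    wanted = set(markers.marker_symbols) | catalog.union
    expressed = profile.index[(profile.to_numpy() > 0).any(axis=1)]
    universe = sorted(wanted & set(expressed))
    if not universe:
        raise ValueError("empty gene universe")
    return universe


def evaluated_pair_count(universe, cfg: NetworkConfig | None = None) -> int:
    """Number of evaluated expression pairs under the configured convention."""
    cfg = cfg or NetworkConfig()
    n = len(universe)
    if cfg.pair_convention == "ordered_with_self":
        return n * n
    return n * (n - 1) // 2


def spearman_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-approximation; |rho| = 1 gives p = 0."""
    rho = np.clip(np.asarray(rho, dtype=float), -1.0, 1.0)
    p = np.zeros_like(rho)
    inner = np.abs(rho) < 1.0
    tt = rho[inner] * np.sqrt((n - 2) / (1.0 - rho[inner] ** 2))
    p[inner] = 2.0 * t_dist.sf(np.abs(tt), df=n - 2)
    return p


def pairwise_spearman(
    profile: pd.DataFrame, universe: list[str], cfg: NetworkConfig | None = None
) -> pd.DataFrame:
    """Spearman correlation over ordered stage means for every unordered
    non-self gene pair, BH adjustment over all pairs, then filtering to
    rho > rho_threshold and q < fdr_threshold.

    Ties get average ranks.  Constant profiles have undefined rank
    correlation; those genes are excluded from testing and logged.
    """
    cfg = cfg or NetworkConfig()
    n_stages = profile.shape[1]
    if n_stages < 4:
        raise ValueError("need at least 4 stages for a meaningful correlation")
    sub = profile.loc[universe]
    x = sub.to_numpy(float)
    constant = np.ptp(x, axis=1) == 0
    if constant.any():
        dropped = list(sub.index[constant])
        logger.warning(
            "excluding %d constant stage profiles from correlation: %s",
            len(dropped), dropped[:10],
        )
    genes = list(sub.index[~constant])
    x = x[~constant]
    if len(genes) < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "rho", "p", "q"])

    ranks = np.apply_along_axis(rankdata, 1, x)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    rho = (ranks @ ranks.T) / np.outer(norms, norms)
    rho = np.clip(rho, -1.0, 1.0)
    # snap float noise so perfectly concordant/discordant profiles give
    # exactly |rho| = 1 (and hence p = 0)
    rho[np.abs(rho) > 1.0 - 1e-12] = np.sign(rho[np.abs(rho) > 1.0 - 1e-12])

    iu, ju = np.triu_indices(len(genes), k=1)
    rho_flat = rho[iu, ju]
    p_flat = spearman_pvalue(rho_flat, n_stages)
    _, q_flat, _, _ = multipletests(p_flat, method="fdr_bh")
    keep = (rho_flat > cfg.rho_threshold) & (q_flat < cfg.fdr_threshold)
    # genes is lexicographically sorted and iu < ju, so gene_a < gene_b holds
    ga = np.array(genes)[iu[keep]]
    gb = np.array(genes)[ju[keep]]
    edges = pd.DataFrame(
        {"gene_a": ga, "gene_b": gb, "rho": rho_flat[keep], "p": p_flat[keep],
         "q": q_flat[keep]}
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    return edges


def network_topology(edges: pd.DataFrame, marker_symbols=()) -> dict:
    """Topology of the simple undirected co-expression graph: node/edge
    counts, degree histogram and the shortest-path-length histogram within
    connected components."""
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["gene_a"], row["gene_b"])
    degree_hist: dict[int, int] = {}
    for _, d in g.degree():
        degree_hist[d] = degree_hist.get(d, 0) + 1
    path_hist: dict[int, int] = {}
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, length in lengths.items():
            if length > 0 and src < dst:  # each unordered pair once
                path_hist[length] = path_hist.get(length, 0) + 1
    marker_set = {str(s).upper() for s in marker_symbols}
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_marker_nodes": sum(1 for v in g.nodes if str(v).upper() in marker_set),
        "degree_histogram": dict(sorted(degree_hist.items())),
        "path_length_histogram": dict(sorted(path_hist.items())),
    }


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_graphml(edges: pd.DataFrame, path) -> None:
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["gene_a"], row["gene_b"], rho=float(row["rho"]),
                   q=float(row["q"]))
    nx.write_graphml(g, path)
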