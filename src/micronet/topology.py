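"""Centrality profiles and the topological-niche statistic.

A taxon's role in the interaction network is summarised by three directed
centralities at each interaction-strength level S (the sub-network of the S
strongest reliable edges): indegree (how many taxa influence it), betweenness
(how often it sits on shortest directed paths) and eigenvector centrality
(reporting only).  Indegree is normalized by n-1 and betweenness by
(n-1)(n-2) so values are comparable across sub-networks of different size;
taxa absent from a sub-network score 0 there.

The topological-niche score of taxon i for a centrality is

    Niche_i = sum_S (Centrality_i,S^B - Centrality_i,S^C) / max_j |raw_j|

i.e. the across-level sum of bioaugmented-minus-control centrality
differences, normalized by the largest absolute sum over taxa so the score
lies in [-1, 1].  Scores inside the +-0.1 band are non-influential; both
scores above 0.1 place a taxon's niche in the perturbed community, both
below -0.1 in the control, and opposite out-of-band signs are ambiguous.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "centralities",
    "niche_scores",
    "niche_classify",
    "niche_table",
]

CENTRALITY_COLUMNS = ("indegree_norm", "betweenness_norm", "eigenvector")


def centralities(network: nx.DiGraph, taxa: Sequence[str]) -> pd.DataFrame:
    """Normalized indegree, betweenness and eigenvector per taxon.

    ``taxa`` fixes the row universe; taxa not in the network get 0.
    """
    if len(taxa) == 0:
        raise ValueError("empty taxon universe")
    out = pd.DataFrame(
        0.0, index=list(taxa), columns=list(CENTRALITY_COLUMNS)
    )
    n = network.number_of_nodes()
    if n == 0:
        return out
    nodes = [v for v in network.nodes if v in out.index]
    if n > 1:
        for v in nodes:
            out.at[v, "indegree_norm"] = network.in_degree(v) / (n - 1)
    if n > 2:
        btw = nx.betweenness_centrality(network, normalized=True)
        for v in nodes:
            out.at[v, "betweenness_norm"] = btw[v]
    try:
        eig = nx.eigenvector_centrality_numpy(network.reverse(copy=False))
        for v in nodes:
            out.at[v, "eigenvector"] = abs(eig[v])
    except Exception:
        pass  # reporting-only measure; undefined on degenerate graphs
    return out


def niche_scores(
    profiles_b: Mapping[object, pd.DataFrame],
    profiles_c: Mapping[object, pd.DataFrame],
    column: str = "indegree_norm",
    per_taxon_denominator: bool = False,
) -> pd.Series:
    """Niche score per taxon from per-strength-level centrality profiles.

    ``profiles_b`` / ``profiles_c`` map strength level -> centrality frame
    (same taxa, same levels on both sides).  The default normalization
    divides the per-taxon raw sums by the maximum absolute raw sum across
    taxa, forcing the [-1, 1] range; ``per_taxon_denominator`` switches to
    the literal per-taxon maximum difference across levels.
    """
    if set(profiles_b) != set(profiles_c):
        raise ValueError("strength grids differ between conditions")
    if not profiles_b:
        raise ValueError("empty strength grid")
    levels = list(profiles_b)
    index = profiles_b[levels[0]].index
    diffs = pd.DataFrame(
        {s: profiles_b[s][column] - profiles_c[s][column] for s in levels},
        index=index,
    )
    raw = diffs.sum(axis=1)
    if per_taxon_denominator:
        denom = diffs.abs().max(axis=1)
        return pd.Series(
            np.where(denom > 0, raw / denom.replace(0, 1.0), 0.0), index=index
        )
    m = raw.abs().max()
    if m == 0:
        return pd.Series(0.0, index=index)
    return raw / m


def niche_classify(niche_indegree: float, niche_betweenness: float) -> str:
    """Four-way niche classification from the two scores (+-0.1 band).

    Both > 0.1: bioaug_niche; both < -0.1: control_niche; both inside the
    band: none; opposite out-of-band signs: ambiguous; one in-band and one
    out: none (conservative default for the uncovered mixed case).
    """
    a, b = float(niche_indegree), float(niche_betweenness)
    for v in (a, b):
        if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
            raise ValueError("niche scores must lie in [-1, 1]")
    if a > 0.1 and b > 0.1:
        return "bioaug_niche"
    if a < -0.1 and b < -0.1:
        return "control_niche"
    if abs(a) > 0.1 and abs(b) > 0.1:
        return "ambiguous"
    return "none"


def niche_table(
    profiles_b: Mapping[object, pd.DataFrame],
    profiles_c: Mapping[object, pd.DataFrame],
    per_taxon_denominator: bool = False,
) -> pd.DataFrame:
    """Per-taxon niche scores (indegree, betweenness) and classification."""
    ni = niche_scores(profiles_b, profiles_c, "indegree_norm", per_taxon_denominator)
    nb = niche_scores(profiles_b, profiles_c, "betweenness_norm", per_taxon_denominator)
    out = pd.DataFrame({"niche_indegree": ni, "niche_betweenness": nb})
    out["niche_class"] = [
        niche_classify(a, b) for a, b in zip(out["niche_indegree"], out["niche_betweenness"])
    ]
    return out
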