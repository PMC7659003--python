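"""Correlated abundance patterns and co-occurrence clusters.

Two Pearson correlations drive this stage.  The self-correlation r_CiBi of a
taxon's control trajectory against its bioaugmented trajectory identifies
taxa whose abundance pattern is conserved across the perturbation; the
within-condition correlations r_CiCj / r_BiBj then pull in taxa that track
one of those conserved "anchor" taxa before or after the perturbation.

Clusters are built in three steps: (1) average-linkage hierarchical
clustering of the concatenated C+B profiles under correlation distance
(1 - r); (2) within each cluster, keep only pairs whose within-condition
correlation is significant and in which at least one member is an anchor
(significant r_CiBi); (3) tag each retained link as "before" or "after" by
which condition's correlation is significant.  Members with no retained link
are dropped.

Trajectory shapes (ascent / descent / convex) are assigned by a quadratic
least-squares fit: a cluster of taxa that rise then fall together is
"convex" in the sense used for digester communities (a mid-series peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.special import gammaln

from .abundance import AbundanceTable, align_conditions

__all__ = [
    "CorrelationRecord",
    "CooccurrenceCluster",
    "corr_self",
    "corr_pair",
    "r_critical",
    "build_cooccurrence_clusters",
    "trend_pattern",
    "feature_association",
]


@dataclass(frozen=True)
class CorrelationRecord:
    """One Pearson correlation with its two-sided significance.

    ``kind`` is "self" (r_CiBi), "within-C" (r_CiCj) or "within-B" (r_BiBj).
    Degenerate (zero-variance) inputs carry r = nan and are never
    significant.
    """

    kind: str
    taxon_i: str
    taxon_j: str
    r: float
    p: float
    significant: bool


@dataclass
class CooccurrenceCluster:
    label: str
    members: list[str]
    anchors: list[str]
    pattern: str
    epochs: dict[str, str]  # member -> before | after | both
    links: list[tuple[str, str, str]] = field(default_factory=list)


def _pearson(x: np.ndarray, y: np.ndarray, alpha: float) -> tuple[float, float, bool]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), 1.0, False
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return r, p, p < alpha


def corr_self(
    c_profile: Sequence[float],
    b_profile: Sequence[float],
    taxon: str = "",
    alpha: float = 0.05,
) -> CorrelationRecord:
    """r_CiBi: Pearson correlation of one taxon's C vs B trajectory."""
    r, p, sig = _pearson(np.asarray(c_profile), np.asarray(b_profile), alpha)
    return CorrelationRecord("self", taxon, taxon, r, p, sig)


def corr_pair(
    profile_i: Sequence[float],
    profile_j: Sequence[float],
    condition: str = "C",
    taxon_i: str = "",
    taxon_j: str = "",
    alpha: float = 0.05,
) -> CorrelationRecord:
    """r_CiCj / r_BiBj: within-condition correlation of two taxa."""
    kind = "within-C" if condition == "C" else "within-B"
    r, p, sig = _pearson(np.asarray(profile_i), np.asarray(profile_j), alpha)
    return CorrelationRecord(kind, taxon_i, taxon_j, r, p, sig)


def r_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical |r| for a Pearson correlation on n pairs.

    Inverts the t transform with n - 2 degrees of freedom; at n = 7 and
    alpha = 0.05 this is about 0.7545.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    t = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(t / np.sqrt(t * t + n - 2))


# ---------------------------------------------------------------------------
# Cluster construction
# ---------------------------------------------------------------------------

def build_cooccurrence_clusters(
    table_c: AbundanceTable,
    table_b: AbundanceTable,
    alpha: float = 0.05,
    cut_distance: float | None = None,
    min_members: int = 2,
) -> list[CooccurrenceCluster]:
    """Three-step co-occurrence clustering of a paired C/B dataset.

    Average-linkage agglomeration on 1 - Pearson r over the concatenated
    C+B profiles, cut at ``cut_distance`` (default 1 - r_critical at the
    combined sample count); then the anchor/link filter described in the
    module docstring.  Output is deterministic: clusters are ordered by
    (size desc, first member) and labelled G1, G2, ...
    """
    vc, vb = align_conditions(table_c, table_b)
    taxa = list(vc.index)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa to cluster")
    combined = np.hstack([vc.to_numpy(dtype=float), vb.to_numpy(dtype=float)])
    # zero-variance rows cannot enter a correlation distance
    variable = combined.std(axis=1) > 0
    taxa_v = [t for t, keep in zip(taxa, variable) if keep]
    x = combined[variable]
    if len(taxa_v) < 2:
        return []
    if cut_distance is None:
        cut_distance = 1.0 - r_critical(combined.shape[1], alpha)
    dist = pdist(x, metric="correlation")
    tree = hierarchy.linkage(dist, method="average")
    flat = hierarchy.fcluster(tree, t=cut_distance, criterion="distance")

    anchors = {
        t
        for t, row_c, row_b in zip(taxa, vc.to_numpy(), vb.to_numpy())
        if corr_self(row_c, row_b, t, alpha).significant
    }

    clusters: list[CooccurrenceCluster] = []
    for cl in sorted(set(flat)):
        group = [t for t, g in zip(taxa_v, flat) if g == cl]
        links: list[tuple[str, str, str]] = []
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                ti, tj = group[a], group[b]
                if ti not in anchors and tj not in anchors:
                    continue
                sig_c = corr_pair(
                    vc.loc[ti], vc.loc[tj], "C", ti, tj, alpha
                ).significant
                sig_b = corr_pair(
                    vb.loc[ti], vb.loc[tj], "B", ti, tj, alpha
                ).significant
                if sig_c and sig_b:
                    links.append((ti, tj, "both"))
                elif sig_c:
                    links.append((ti, tj, "before"))
                elif sig_b:
                    links.append((ti, tj, "after"))
        if not links:
            continue
        epochs: dict[str, str] = {}
        for ti, tj, epoch in links:
            for t in (ti, tj):
                prev = epochs.get(t)
                if prev is None:
                    epochs[t] = epoch
                elif prev != epoch:
                    epochs[t] = "both"
        members = sorted(epochs)
        if len(members) < min_members:
            continue
        mean_profiles = (vc.loc[members].to_numpy() + vb.loc[members].to_numpy()) / 2.0
        patterns = [trend_pattern(row) for row in mean_profiles]
        modal = max(sorted(set(patterns)), key=patterns.count)
        clusters.append(
            CooccurrenceCluster(
                label="",
                members=members,
                anchors=sorted(set(members) & anchors),
                pattern=modal,
                epochs=epochs,
                links=links,
            )
        )
    clusters.sort(key=lambda c: (-len(c.members), c.members[0]))
    for i, c in enumerate(clusters, start=1):
        c.label = f"G{i}"
    return clusters


def clusters_frame(clusters: Iterable[CooccurrenceCluster]) -> pd.DataFrame:
    """Flat per-member view of a cluster list (for the clusters TSV)."""
    rows = []
    for c in clusters:
        for t in c.members:
            rows.append(
                {
                    "cluster": c.label,
                    "taxon": t,
                    "anchor": t in c.anchors,
                    "pattern": c.pattern,
                    "epoch": c.epochs[t],
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "taxon", "anchor", "pattern", "epoch"])


# ---------------------------------------------------------------------------
# Trajectory shape
# ---------------------------------------------------------------------------

def trend_pattern(profile: Sequence[float], alpha: float = 0.05) -> str:
    """Classify a trajectory as ascent, descent or convex (mid-series peak).

    Fits abundance ~ quadratic in the date index.  The convex label requires
    a negative quadratic coefficient, a vertex strictly inside the observed
    range, and the quadratic term to improve on the linear fit (partial
    F-test, p < alpha).  Otherwise the sign of the linear slope decides
    ascent vs descent (a constant profile degenerates to descent).
    """
    y = np.asarray(profile, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 time points")
    t = np.arange(n, dtype=float)
    lin = np.polyfit(t, y, 1)
    quad = np.polyfit(t, y, 2)
    sse_lin = float(((y - np.polyval(lin, t)) ** 2).sum())
    sse_quad = float(((y - np.polyval(quad, t)) ** 2).sum())
    c2, c1, _ = quad
    if sse_quad > 0 and n > 3:
        f = (sse_lin - sse_quad) / (sse_quad / (n - 3))
        p_quad = float(stats.f.sf(f, 1, n - 3))
    else:
        # quadratic fits exactly; improvement is total unless already linear
        p_quad = 1.0 if sse_lin <= 1e-30 else 0.0
    if c2 < 0 and p_quad < alpha:
        vertex = -c1 / (2.0 * c2)
        if 0.0 < vertex < n - 1:
            return "convex"
    return "ascent" if lin[0] > 0 else "descent"


# ---------------------------------------------------------------------------
# Feature association
# ---------------------------------------------------------------------------

def feature_association(
    labels_a: Sequence,
    labels_b: Sequence,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Association between two categorical per-taxon labellings.

    Cross-tabulates the labels and tests independence: exact hypergeometric
    (Fisher) for a 2x2 table, Monte Carlo Fisher (permutation of one margin,
    ordering tables by their conditional hypergeometric probability) for
    anything larger.  Returns (contingency table, two-sided p).
    """
    a = pd.Series(list(labels_a), name="A")
    b = pd.Series(list(labels_b), name="B")
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    table = pd.crosstab(a, b)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("each labelling needs at least 2 categories")
    if table.shape == (2, 2):
        p = float(stats.fisher_exact(table.to_numpy())[1])
        return table, p
    codes_a = a.astype("category").cat.codes.to_numpy()
    codes_b = b.astype("category").cat.codes.to_numpy()
    ka, kb = codes_a.max() + 1, codes_b.max() + 1
    rng = np.random.default_rng(seed)

    def log_prob(flat_counts: np.ndarray) -> float:
        # conditional probability of the table given its margins
        m = flat_counts.reshape(ka, kb)
        row = m.sum(axis=1)
        col = m.sum(axis=0)
        n = m.sum()
        return float(
            gammaln(row + 1).sum()
            + gammaln(col + 1).sum()
            - gammaln(n + 1)
            - gammaln(m + 1).sum()
        )

    obs = np.bincount(codes_a * kb + codes_b, minlength=ka * kb)
    lp_obs = log_prob(obs)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(codes_b)
        cnt = np.bincount(codes_a * kb + perm, minlength=ka * kb)
        if log_prob(cnt) <= lp_obs + 1e-12:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    return table, float(p)
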