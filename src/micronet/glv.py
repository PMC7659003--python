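"""Ensemble generalized Lotka-Volterra network inference.

The community model is discrete-time gLV: per-capita log growth of taxon i
between consecutive samples is b_i + sum_j a_ij x_j, so the coefficient
a_ij is the directed, signed influence of taxon j on taxon i (edge j -> i).
Fitting is gradient matching: y_i(k) = ln(x_i(k+1)/x_i(k)) / dt regressed on
(1, x_1(k), ..., x_N(k)) by ridge-regularized least squares.  With many taxa
and few transitions the regression is underdetermined, which is exactly why
the protocol is an *ensemble*: many fits on random 90% subsets of the taxa,
keeping only interactions whose sign is coherent across fits.

An interaction is reliable when its modal sign occurs in at least
``coherence_threshold`` (default 90%) of the fits observing the pair *and*
an exact one-sided binomial test rejects sign-coin-flipping at alpha.
Downstream analyses slice the reliable network at the strongest k edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis

from .abundance import AbundanceTable

__all__ = [
    "GLVModel",
    "InteractionEdge",
    "EnsembleStats",
    "fit_glv",
    "ensemble_infer",
    "reliability_filter",
    "to_digraph",
    "top_k_edges",
    "simulation_fit_score",
]

MAGNITUDE_FLOOR = 1e-10


@dataclass
class GLVModel:
    """Growth rates b (per unit time) and interaction matrix A.

    ``interactions[i, j]`` is the effect of taxon j on taxon i per abundance
    unit per unit time.  ``taxa`` names the rows/columns; ``flagged`` lists
    taxa whose regression had no usable transition (their rows are zero).
    """

    growth: np.ndarray
    interactions: np.ndarray
    taxa: tuple[str, ...] = ()
    flagged: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.growth = np.asarray(self.growth, dtype=float)
        self.interactions = np.asarray(self.interactions, dtype=float)
        n = self.growth.size
        if self.interactions.shape != (n, n):
            raise ValueError("growth/interaction dimensions mismatch")
        if not (np.isfinite(self.growth).all() and np.isfinite(self.interactions).all()):
            raise ValueError("non-finite model entries")
        if self.taxa and len(self.taxa) != n:
            raise ValueError("taxa labels do not match dimension")


def _transitions(table: AbundanceTable) -> tuple[np.ndarray, np.ndarray]:
    """(values matrix taxa x time ordered by date, dt per transition)."""
    order = table.meta.sort_values("date_index")
    x = table.values[list(order.index)].to_numpy(dtype=float)
    dts = np.diff(order["date_index"].to_numpy(dtype=float))
    return x, dts


def _ridge_solve(z: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    """min ||Zs beta - y||^2 + ridge ||beta||^2 on the column-equilibrated
    design (min-norm least squares when ridge = 0); coefficients are
    returned on the original scale."""
    m, p = z.shape
    norms = np.linalg.norm(z, axis=0)
    norms[norms == 0] = 1.0
    zs = z / norms
    if ridge <= 0:
        beta = np.linalg.lstsq(zs, y, rcond=None)[0]
        # one round of iterative refinement: recovers digits lost to the
        # ill-conditioned design when the system is (near-)consistent
        beta += np.linalg.lstsq(zs, y - zs @ beta, rcond=None)[0]
    elif m < p:  # dual form: one m x m solve instead of p x p
        beta = zs.T @ np.linalg.solve(zs @ zs.T + ridge * np.eye(m), y)
    else:
        beta = np.linalg.solve(zs.T @ zs + ridge * np.eye(p), zs.T @ y)
    return beta / norms


def _fit_arrays(
    segments: list[tuple[np.ndarray, np.ndarray]],
    ridge: float,
    taxa: tuple[str, ...],
    pseudo_abundance: bool = False,
) -> GLVModel:
    """Gradient-matching fit over one or more (values, dts) series."""
    n = segments[0][0].shape[0]
    total_transitions = sum(x.shape[1] - 1 for x, _ in segments)
    if total_transitions < 2:
        raise ValueError("need at least 3 time points across the series")
    pred_rows = []
    resp_rows = []  # per-taxon response with a validity mask
    for x, dts in segments:
        if pseudo_abundance:
            pos = x[x > 0]
            if pos.size:
                x = np.where(x > 0, x, pos.min() / 2.0)
        pred_rows.append(x[:, :-1].T)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.log(x[:, 1:] / x[:, :-1]) / dts
        resp_rows.append(y)
    predictors = np.vstack(pred_rows)  # (m, n)
    responses = np.hstack(resp_rows)  # (n, m)
    growth = np.zeros(n)
    a = np.zeros((n, n))
    flagged: list[str] = []
    for i in range(n):
        usable = np.isfinite(responses[i])
        if not usable.any():
            flagged.append(taxa[i])
            continue
        y = responses[i][usable]
        # center predictors for conditioning; the intercept is unshifted after
        zx = predictors[usable]
        means = zx.mean(axis=0)
        design = np.hstack([np.ones((zx.shape[0], 1)), zx - means])
        beta = _ridge_solve(design, y, ridge)
        growth[i] = beta[0] - beta[1:] @ means
        a[i, :] = beta[1:]
    return GLVModel(growth, a, taxa=taxa, flagged=tuple(flagged))


def fit_glv(
    table: AbundanceTable | Sequence[AbundanceTable],
    ridge: float = 1e-3,
    pseudo_abundance: bool = False,
) -> GLVModel:
    """Fit one gLV model to a time series (or replicate series).

    A sequence of tables is treated as replicate reactors sampled from the
    same community model: their transitions are pooled into one regression
    (transitions never span a replicate boundary).  Transitions where taxon
    i is absent at either endpoint are skipped for taxon i's regression
    (its log growth is undefined there); with ``pseudo_abundance`` zeros
    are instead replaced by half the smallest positive value.  A taxon with
    no usable transition gets an all-zero row and is flagged on the
    returned model.
    """
    tables = [table] if isinstance(table, AbundanceTable) else list(table)
    taxa = tuple(tables[0].taxa)
    for t in tables[1:]:
        if tuple(t.taxa) != taxa:
            raise ValueError("replicate tables have different taxon universes")
    segments = [_transitions(t) for t in tables]
    return _fit_arrays(segments, ridge, taxa, pseudo_abundance)


# ---------------------------------------------------------------------------
# Ensemble protocol
# ---------------------------------------------------------------------------

@dataclass
class EnsembleStats:
    """Per-ordered-pair aggregates over an ensemble of subsampled gLV fits."""

    taxa: tuple[str, ...]
    n_networks: int
    member_frac: float
    pos_count: np.ndarray  # runs with a_ij > floor
    neg_count: np.ndarray  # runs with a_ij < -floor
    n_observed: np.ndarray  # runs containing both taxa
    inclusion: np.ndarray | None = None  # runs containing each taxon
    values: dict[tuple[int, int], list[float]] = field(repr=False, default_factory=dict)


def ensemble_infer(
    table: AbundanceTable | Sequence[AbundanceTable],
    n_networks: int = 1000,
    member_frac: float = 0.9,
    ridge: float = 1e-3,
    seed: int | None = None,
    magnitude_floor: float = MAGNITUDE_FLOOR,
) -> EnsembleStats:
    """Fit gLV models on random taxon subsets and pool the coefficient signs.

    Each run draws floor(member_frac * N) taxa without replacement and fits
    the sub-table (replicate series are pooled as in :func:`fit_glv`); for
    every ordered pair present in the run the signed coefficient is
    recorded when its magnitude clears ``magnitude_floor``.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    if not 0 < member_frac <= 1:
        raise ValueError("member_frac must be in (0, 1]")
    tables = [table] if isinstance(table, AbundanceTable) else list(table)
    taxa = tuple(tables[0].taxa)
    for tb in tables[1:]:
        if tuple(tb.taxa) != taxa:
            raise ValueError("replicate tables have different taxon universes")
    n = len(taxa)
    m = int(np.floor(member_frac * n))
    if m < 2:
        raise ValueError("member_frac leaves fewer than 2 taxa per run")
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, n), dtype=np.int64)
    neg = np.zeros((n, n), dtype=np.int64)
    obs = np.zeros((n, n), dtype=np.int64)
    inclusion = np.zeros(n, dtype=np.int64)
    values: dict[tuple[int, int], list[float]] = {}
    segments = [_transitions(tb) for tb in tables]
    for _ in range(n_networks):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        inclusion[idx] += 1
        sub_taxa = tuple(taxa[i] for i in idx)
        model = _fit_arrays(
            [(x[idx], dts) for x, dts in segments], ridge, sub_taxa
        )
        a = model.interactions
        obs[np.ix_(idx, idx)] += 1
        for ii, gi in enumerate(idx):
            row = a[ii]
            for jj, gj in enumerate(idx):
                if gi == gj:
                    continue
                v = row[jj]
                if v > magnitude_floor:
                    pos[gi, gj] += 1
                elif v < -magnitude_floor:
                    neg[gi, gj] += 1
                else:
                    continue
                values.setdefault((gi, gj), []).append(float(v))
    np.fill_diagonal(obs, 0)
    return EnsembleStats(taxa, n_networks, member_frac, pos, neg, obs,
                         inclusion, values)


@dataclass(frozen=True)
class InteractionEdge:
    """Directed signed interaction j -> i with ensemble support."""

    source: str
    target: str
    sign: int  # +1 / -1
    strength: float  # ensemble median |a_ij| over modal-sign runs
    coherence: float
    n_observed: int
    p: float
    reliable: bool


def reliability_filter(
    ens: EnsembleStats,
    coherence_threshold: float = 0.9,
    alpha: float = 0.05,
) -> list[InteractionEdge]:
    """All signed edges with coherence, proportion-test p and reliability flag.

    Coherence is the modal-sign fraction among runs that produced a signed
    outcome for the pair; an edge is reliable iff coherence >=
    ``coherence_threshold`` and an exact one-sided binomial test of the modal
    count against proportion 0.5 gives p < alpha.  Ties break positive, which
    can never be reliable (coherence 0.5).
    """
    if not 0.5 < coherence_threshold <= 1:
        raise ValueError("coherence_threshold must be in (0.5, 1]")
    edges: list[InteractionEdge] = []
    n = len(ens.taxa)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            np_, nn = int(ens.pos_count[i, j]), int(ens.neg_count[i, j])
            total = np_ + nn
            if total == 0:
                continue
            sign = 1 if np_ >= nn else -1
            modal = max(np_, nn)
            coherence = modal / total
            p = float(stats.binom.sf(modal - 1, total, 0.5))
            vals = np.asarray(ens.values[(i, j)])
            modal_vals = vals[vals > 0] if sign > 0 else vals[vals < 0]
            strength = float(np.median(np.abs(modal_vals)))
            reliable = coherence >= coherence_threshold and p < alpha
            edges.append(
                InteractionEdge(
                    source=ens.taxa[j],
                    target=ens.taxa[i],
                    sign=sign,
                    strength=strength,
                    coherence=coherence,
                    n_observed=int(ens.n_observed[i, j]),
                    p=p,
                    reliable=reliable,
                )
            )
    return edges


def to_digraph(edges: Iterable[InteractionEdge], reliable_only: bool = True) -> nx.DiGraph:
    """Edge list -> networkx DiGraph (source -> target, sign/strength attrs)."""
    g = nx.DiGraph()
    for e in edges:
        if reliable_only and not e.reliable:
            continue
        g.add_edge(e.source, e.target, sign=e.sign, strength=e.strength,
                   coherence=e.coherence)
    return g


def top_k_edges(
    edges: Sequence[InteractionEdge], k: int, reliable_only: bool = True
) -> list[InteractionEdge]:
    """The k strongest (reliable) edges; ties break by (source, target)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pool = [e for e in edges if e.reliable] if reliable_only else list(edges)
    pool.sort(key=lambda e: (-e.strength, e.source, e.target))
    return pool[:k]


def edges_frame(edges: Iterable[InteractionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "sign": "+" if e.sign > 0 else "-",
                "strength": e.strength,
                "coherence": e.coherence,
                "n_observed": e.n_observed,
                "p": e.p,
                "reliable": e.reliable,
            }
            for e in edges
        ],
        columns=["source", "target", "sign", "strength", "coherence",
                 "n_observed", "p", "reliable"],
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def simulation_fit_score(model: GLVModel, table: AbundanceTable) -> float:
    """Bray-Curtis agreement between a forward simulation and the data.

    Simulates the discrete gLV recursion from the first observed sample and
    scores 1 - mean Bray-Curtis dissimilarity over the remaining time
    points (1 is a perfect fit).  A diverging simulation scores 0.
    """
    x, dts = _transitions(table)
    n, t = x.shape
    if model.growth.size != n:
        raise ValueError("model/table dimension mismatch")
    sim = np.zeros_like(x)
    sim[:, 0] = x[:, 0]
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(t - 1):
            growth = model.growth + model.interactions @ sim[:, k]
            sim[:, k + 1] = sim[:, k] * np.exp(dts[k] * growth)
    if not np.isfinite(sim).all():
        warnings.warn("gLV simulation diverged; fit score set to 0")
        return 0.0
    dissim = []
    for k in range(1, t):
        if sim[:, k].sum() == 0 and x[:, k].sum() == 0:
            dissim.append(0.0)
        elif sim[:, k].sum() == 0 or x[:, k].sum() == 0:
            dissim.append(1.0)
        else:
            dissim.append(float(braycurtis(sim[:, k], x[:, k])))
    return float(np.clip(1.0 - np.mean(dissim), 0.0, 1.0))
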