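"""Ground-truth-annotated synthetic paired microbiome time series.

The generator emulates the shape of a family-level 16S time series from a
pair of anaerobic digesters: ~113 families, 7 paired sampling dates per
condition (14 samples), sequencing depth ~19,392 +- 982 reads, and the
statistical structure the analysis is built to detect --

* community dynamics follow a discrete-time gLV recursion with a known
  sparse interaction matrix (the same forward model the inference stage
  assumes, so noiseless recovery is an algebraic identity);
* planted trajectory groups (ascent / descent / convex templates applied
  congruently in both conditions, so their cross-condition correlation is
  high by construction);
* planted differentially abundant taxa whose perturbed-condition abundance
  is shifted by a configurable multiple of the within-date difference sd;
* condition-specific rare taxa, including an "invader" standing in for the
  bioaugmented strain, which stays at a constant low relative abundance
  (~0.4%) in the perturbed condition and is absent from the control;
* multinomial count sampling at normally distributed depths.

Everything is deterministic under the master seed, and the returned
:class:`SyntheticTruth` is sufficient to recompute every planted label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, COUNTS, RELATIVE
from .glv import GLVModel

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "gen_interactions",
    "simulate_glv",
    "plant_patterns",
    "sample_counts",
    "generate_dataset",
]

PATTERNS = ("ascent", "descent", "convex")


def gen_interactions(
    n_taxa: int,
    density: float = 0.1,
    negative_fraction: float = 0.6,
    magnitude_scale: float = 0.4,
    self_limitation: float = 0.5,
    growth_low: float = 0.3,
    growth_high: float = 0.7,
    dominance: float = 0.8,
    seed: int | None = None,
) -> GLVModel:
    """Random sparse gLV model with stabilizing self-limitation.

    Off-diagonal entries are Bernoulli(density) with half-normal magnitudes
    (scale ``magnitude_scale``) and a ``negative_fraction`` share of
    negative signs; the diagonal is strictly negative (self-limitation) and
    each row's off-diagonal magnitudes are capped at ``dominance`` times the
    diagonal, the standard diagonal-dominance construction for communities
    that fluctuate around a feasible equilibrium instead of exploding.
    Interactions are deliberately of the same order as self-limitation:
    weaker couplings are statistically invisible against demographic noise
    at realistic series lengths.  Growth rates are uniform on
    [growth_low, growth_high] per unit time.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    a = np.zeros((n_taxa, n_taxa))
    mask = rng.random((n_taxa, n_taxa)) < density
    np.fill_diagonal(mask, False)
    mags = np.abs(rng.normal(0.0, magnitude_scale, size=(n_taxa, n_taxa)))
    signs = np.where(rng.random((n_taxa, n_taxa)) < negative_fraction, -1.0, 1.0)
    a[mask] = (mags * signs)[mask]
    np.fill_diagonal(a, -np.abs(rng.normal(self_limitation, self_limitation / 4, n_taxa)) - 1e-4)
    if dominance > 0:
        for i in range(n_taxa):
            row = np.abs(a[i]).sum() - np.abs(a[i, i])
            cap = dominance * np.abs(a[i, i])
            if row > cap:
                scale = cap / row
                a[i] *= scale
                a[i, i] /= scale
    b = rng.uniform(growth_low, growth_high, n_taxa)
    return GLVModel(b, a)


def simulate_glv(
    model: GLVModel,
    x0: Sequence[float],
    n_steps: int,
    dt: float = 1.0,
    process_noise_sd: float = 0.0,
    extinction_floor: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Discrete-time gLV trajectory, taxa x (n_steps + 1).

    x_i(k+1) = x_i(k) * exp(dt * (b_i + sum_j a_ij x_j(k)) + eps) with
    eps ~ Normal(0, process_noise_sd); values below ``extinction_floor``
    are set to 0.  Exponents are truncated at +-50 (with a warning) to keep
    runaway trajectories finite.
    """
    x0 = np.asarray(x0, dtype=float)
    if (x0 <= 0).any():
        raise ValueError("x0 must be strictly positive")
    n = x0.size
    if model.growth.size != n:
        raise ValueError("model/x0 dimension mismatch")
    rng = np.random.default_rng(seed)
    out = np.zeros((n, n_steps + 1))
    out[:, 0] = x0
    truncated = False
    for k in range(n_steps):
        arg = dt * (model.growth + model.interactions @ out[:, k])
        if process_noise_sd > 0:
            arg = arg + rng.normal(0.0, process_noise_sd, n)
        if (np.abs(arg) > 50).any():
            truncated = True
            arg = np.clip(arg, -50, 50)
        nxt = out[:, k] * np.exp(arg)
        nxt[nxt < extinction_floor] = 0.0
        out[:, k + 1] = nxt
    if truncated:
        warnings.warn("gLV simulation overflow; exponent truncated at +-50")
    return out


def _template(pattern: str, n_points: int) -> np.ndarray:
    """Unit-mean shape template over the sampling dates (range ~ +-50%)."""
    t = np.linspace(0.0, 1.0, n_points)
    if pattern == "ascent":
        shape = t
    elif pattern == "descent":
        shape = 1.0 - t
    elif pattern == "convex":  # symmetric mid-series peak
        shape = 1.0 - (2.0 * t - 1.0) ** 2
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    shape = shape - shape.mean()
    return 1.0 + shape / (np.abs(shape).max() * 2.0)


def plant_patterns(
    trajectories: np.ndarray,
    groups: dict[str, Sequence[int]],
    noise_sd: float = 0.0,
    seed: int | None = None,
    min_level: float = 0.0,
) -> np.ndarray:
    """Replace designated rows with shape templates plus Gaussian noise.

    ``groups`` maps a pattern name to the row indices it claims (disjoint).
    Each planted row keeps its original mean magnitude (raised to at least
    ``min_level`` so the shape stays measurable at finite sequencing
    depth); the multiplicative noise has sd ``noise_sd`` relative to that
    magnitude.
    """
    idx_all = [i for idxs in groups.values() for i in idxs]
    if len(idx_all) != len(set(idx_all)):
        raise ValueError("pattern groups overlap")
    n_points = trajectories.shape[1]
    out = trajectories.copy()
    rng = np.random.default_rng(seed)
    for pattern, idxs in groups.items():
        base = _template(pattern, n_points)
        for i in idxs:
            level = max(out[i].mean(), min_level) if out[i].mean() > 0 else max(min_level, 1.0)
            noise = rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else 0.0
            out[i] = np.maximum(level * (base + noise), level * 1e-3)
    return out


def sample_counts(
    relative: np.ndarray,
    depth_mean: float = 19392.0,
    depth_sd: float = 982.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial read counts per sample at normally distributed depths.

    ``relative`` is taxa x samples in percent (columns sum to 100).  Depths
    are drawn Normal(depth_mean, depth_sd), truncated at 1 and rounded;
    multinomial sampling makes each column sum exactly to its depth.
    Returns (counts, depths).
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    n_taxa, n_samples = relative.shape
    depths = np.maximum(np.round(rng.normal(depth_mean, depth_sd, n_samples)), 1).astype(int)
    counts = np.zeros((n_taxa, n_samples), dtype=int)
    for k in range(n_samples):
        p = relative[:, k] / relative[:, k].sum()
        counts[:, k] = rng.multinomial(depths[k], p)
    return counts, depths


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Study-shaped defaults for the paired synthetic community.

    113 families over 7 paired dates; 25 planted correlated taxa in three
    pattern groups (9 ascent, 8 descent, 8 convex); 20 planted Diff_UP and
    13 Diff_DN taxa at 3-sd effects; 12 condition-specific rare taxa (5
    control-only, 7 perturbed-only including the invader at ~0.4%); read
    depth 19,392 +- 982.
    """

    n_taxa: int = 113
    n_dates: int = 7
    density: float = 0.1
    negative_fraction: float = 0.6
    magnitude_scale: float = 0.01
    process_noise_sd: float = 0.05
    pattern_group_sizes: tuple[int, int, int] = (9, 8, 8)
    pattern_noise_sd: float = 0.05
    pattern_min_level: float = 0.5  # raw-abundance floor for planted shapes
    diff_min_abundance: float = 0.1  # percent; differential taxa drawn above this
    n_diff_up: int = 20
    n_diff_dn: int = 13
    diff_effect_sd: float = 3.0
    n_c_only: int = 5
    n_b_only: int = 7  # includes the invader
    invader_abundance: float = 0.4  # percent
    n_perturbed_rows: int = 10
    growth_shift_sd: float = 0.15  # community-wide B-condition growth jitter
    burn_in_steps: int = 50  # noiseless settling before the sampled window
    depth_mean: float = 19392.0
    depth_sd: float = 982.0
    counts: bool = True  # False returns relative-percent tables directly


@dataclass
class SyntheticTruth:
    """Everything needed to recompute every planted label."""

    seed: int
    taxa: list[str]
    growth: list[float]
    interactions: list[list[float]]
    pattern_groups: dict[str, list[str]]
    diff_up: list[str]
    diff_dn: list[str]
    c_only: list[str]
    b_only: list[str]
    invader: str
    perturbed_rows: list[str]
    depth_mean: float
    depth_sd: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))

    @property
    def correlated_taxa(self) -> set[str]:
        return {t for members in self.pattern_groups.values() for t in members}


def _make_table(values: np.ndarray, taxa: list[str], condition: str,
                units: str) -> AbundanceTable:
    n_dates = values.shape[1]
    cols = [f"{condition}{d}" for d in range(1, n_dates + 1)]
    meta = pd.DataFrame(
        {"condition": condition, "date_index": range(1, n_dates + 1)}, index=cols
    )
    return AbundanceTable(pd.DataFrame(values, index=taxa, columns=cols), meta, units)


def generate_dataset(
    config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[AbundanceTable, AbundanceTable, SyntheticTruth]:
    """Paired (control, bioaugmented) tables plus the generating truth."""
    cfg = config or SyntheticConfig()
    n, t = cfg.n_taxa, cfg.n_dates
    n_planted = (
        sum(cfg.pattern_group_sizes)
        + cfg.n_diff_up + cfg.n_diff_dn + cfg.n_c_only + cfg.n_b_only
    )
    if n_planted > n:
        raise ValueError("planted sets exceed the taxon count")
    ss = np.random.SeedSequence(seed)
    (s_model, s_simc, s_simb, s_pat, s_countc, s_countb,
     s_assign, s_perturb) = [np.random.default_rng(c) for c in ss.spawn(8)]

    taxa = [f"F{i + 1:03d}" for i in range(n)]
    model = gen_interactions(
        n, cfg.density, cfg.negative_fraction, cfg.magnitude_scale,
        seed=s_model,
    )
    x0 = np.abs(s_model.lognormal(mean=0.0, sigma=1.0, size=n)) + 0.05

    # disjoint planted index sets
    order = s_assign.permutation(n)
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        out = order[cursor:cursor + k].tolist()
        cursor += k
        return out

    groups_idx = {
        p: take(k) for p, k in zip(PATTERNS, cfg.pattern_group_sizes)
    }
    c_only_idx = take(cfg.n_c_only)
    b_only_idx = take(cfg.n_b_only)
    invader_idx = b_only_idx[0] if b_only_idx else None

    # perturbed-condition model: a community-wide growth shift (the added
    # strain's broad compositional footprint) plus a few rewired rows
    model_b = GLVModel(model.growth.copy(), model.interactions.copy())
    if cfg.growth_shift_sd > 0:
        model_b.growth = model_b.growth * np.exp(
            s_perturb.normal(0.0, cfg.growth_shift_sd, n)
        )
    perturbed_rows = s_perturb.choice(n, size=min(cfg.n_perturbed_rows, n),
                                      replace=False).tolist()
    for i in perturbed_rows:
        scale = s_perturb.uniform(0.5, 1.5)
        model_b.interactions[i, :] *= scale
        model_b.growth[i] *= s_perturb.uniform(0.8, 1.2)

    # the study samples established digesters: burn in to each condition's
    # (perturbed) steady state before the observed window
    if cfg.burn_in_steps > 0:
        x0_c = simulate_glv(model, x0, cfg.burn_in_steps)[:, -1]
        x0_b = simulate_glv(model_b, x0, cfg.burn_in_steps)[:, -1]
        floor = x0.min() * 1e-3
        x0_c, x0_b = np.maximum(x0_c, floor), np.maximum(x0_b, floor)
    else:
        x0_c = x0_b = x0
    traj_c = simulate_glv(model, x0_c, t - 1, process_noise_sd=cfg.process_noise_sd,
                          seed=s_simc)
    traj_b = simulate_glv(model_b, x0_b, t - 1, process_noise_sd=cfg.process_noise_sd,
                          seed=s_simb)

    # congruent pattern planting (same template, independent small noise)
    pat_kwargs = dict(noise_sd=cfg.pattern_noise_sd, min_level=cfg.pattern_min_level)
    traj_c = plant_patterns(traj_c, groups_idx, seed=s_pat, **pat_kwargs)
    traj_b = plant_patterns(traj_b, groups_idx, seed=s_pat, **pat_kwargs)

    def relative(m: np.ndarray) -> np.ndarray:
        return m / m.sum(axis=0) * 100.0

    rel_c, rel_b = relative(traj_c), relative(traj_b)

    # condition-specific rare taxa (overwrite simulated rows)
    for i in c_only_idx:
        rel_b[i] = 0.0
        rel_c[i] = s_assign.uniform(0.01, 0.08, t)
    for i in b_only_idx:
        rel_c[i] = 0.0
        if i == invader_idx:
            rel_b[i] = cfg.invader_abundance * (1 + s_assign.normal(0, 0.05, t))
        else:
            rel_b[i] = s_assign.uniform(0.01, 0.08, t)

    # differential taxa: drawn (deterministically, in permutation order) from
    # the unplanted taxa abundant enough for a shift to be measurable
    eligible = [
        i for i in order[cursor:]
        if rel_c[i].mean() >= cfg.diff_min_abundance
        and rel_b[i].mean() >= cfg.diff_min_abundance
    ]
    if len(eligible) < cfg.n_diff_up + cfg.n_diff_dn:
        raise ValueError("not enough sufficiently abundant taxa for the "
                         "planted differential sets")
    diff_up_idx = eligible[: cfg.n_diff_up]
    diff_dn_idx = eligible[cfg.n_diff_up: cfg.n_diff_up + cfg.n_diff_dn]

    # multiplicative shift making the mean B-C difference exactly
    # +-diff_effect_sd times the full within-date difference sd (process
    # noise plus, in counts mode, the multinomial sampling noise)
    for idxs, direction in ((diff_up_idx, 1.0), (diff_dn_idx, -1.0)):
        for i in idxs:
            d = rel_b[i] - rel_c[i]
            var = float(d.var(ddof=1))
            if cfg.counts:
                var += 2.0 * 100.0 * max(rel_b[i].mean(), 1e-9) / cfg.depth_mean
            sd = np.sqrt(var)
            if sd == 0:
                sd = 0.05 * max(rel_b[i].mean(), 1e-6)
            mean_b = rel_b[i].mean()
            target = direction * cfg.diff_effect_sd * sd
            factor = 1.0 + (target - d.mean()) / mean_b
            rel_b[i] = rel_b[i] * max(factor, 0.05)

    rel_c, rel_b = relative(rel_c), relative(rel_b)

    if cfg.counts:
        counts_c, _ = sample_counts(rel_c, cfg.depth_mean, cfg.depth_sd, seed=s_countc)
        counts_b, _ = sample_counts(rel_b, cfg.depth_mean, cfg.depth_sd, seed=s_countb)
        table_c = _make_table(counts_c, taxa, "C", COUNTS)
        table_b = _make_table(counts_b, taxa, "B", COUNTS)
    else:
        table_c = _make_table(rel_c, taxa, "C", RELATIVE)
        table_b = _make_table(rel_b, taxa, "B", RELATIVE)

    truth = SyntheticTruth(
        seed=seed,
        taxa=taxa,
        growth=model.growth.tolist(),
        interactions=model.interactions.tolist(),
        pattern_groups={p: [taxa[i] for i in idxs] for p, idxs in groups_idx.items()},
        diff_up=[taxa[i] for i in diff_up_idx],
        diff_dn=[taxa[i] for i in diff_dn_idx],
        c_only=[taxa[i] for i in c_only_idx],
        b_only=[taxa[i] for i in b_only_idx],
        invader=taxa[invader_idx] if invader_idx is not None else "",
        perturbed_rows=[taxa[i] for i in perturbed_rows],
        depth_mean=cfg.depth_mean,
        depth_sd=cfg.depth_sd,
    )
    return table_c, table_b, truth
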