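"""Abundance tables and per-taxon abundance features.

The unit of analysis is a family-level abundance table over time-series
samples collected under two paired conditions: a control digester ("C") and a
bioaugmented digester ("B") sampled on the same dates.  Each taxon is
classified along three axes that together describe how a community responds to
a subtle perturbation:

* abundance level -- high (H, mean > 1%), low (L, 0.1--1%) or rare
  (R, mean < 0.1%), where the mean is taken over the samples in which the
  taxon is present (the zero samples do not dilute the mean);
* core status -- present in every sample (core) versus rare-with-gaps (nR);
* differential status -- paired t-test on same-date samples, significantly
  up (Diff_UP) or down (Diff_DN) after the perturbation, or the
  non-significant counterparts NDiff_UP / NDiff_DN.

Alpha-diversity indices (Shannon, inverse Simpson, Chao1) are provided for
the contrast the method is built around: diversity is typically blind to a
subtle perturbation that network structure can still detect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceTable",
    "TaxonAnnotation",
    "read_abundance_table",
    "normalize_counts",
    "to_relative",
    "mean_nonzero",
    "classify_level",
    "diversity_indices",
    "paired_diff_test",
    "presence_partition",
    "annotate_taxa",
]

COUNTS = "counts"
RELATIVE = "relative_percent"

_CONDITIONS = ("C", "B")


class AbundanceTableError(ValueError):
    """Raised when an abundance table violates its structural contract."""


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix with per-sample metadata.

    ``values`` is a DataFrame indexed by taxon ID with one column per sample;
    ``meta`` is indexed by the same sample names and carries ``condition``
    (``"C"`` or ``"B"``) and an integer ``date_index``.  ``units`` is either
    ``"counts"`` or ``"relative_percent"``; in the latter mode every sample
    column sums to 100 (within 1e-6).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    units: str = COUNTS

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.units not in (COUNTS, RELATIVE):
            raise AbundanceTableError(f"unknown units {self.units!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise AbundanceTableError(f"duplicate taxon IDs: {dupes}")
        if not set(self.values.columns) <= set(self.meta.index):
            missing = sorted(set(self.values.columns) - set(self.meta.index))
            raise AbundanceTableError(f"samples without metadata: {missing}")
        self.meta = self.meta.loc[list(self.values.columns)]
        bad_cond = set(self.meta["condition"]) - set(_CONDITIONS)
        if bad_cond:
            raise AbundanceTableError(f"unknown conditions: {sorted(bad_cond)}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise AbundanceTableError(
                f"missing value at taxon {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise AbundanceTableError(
                f"negative abundance at taxon {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        pairs = list(zip(self.meta["condition"], self.meta["date_index"]))
        if len(pairs) != len(set(pairs)):
            raise AbundanceTableError("duplicate (condition, date_index) pair")
        if self.units == RELATIVE:
            sums = arr.sum(axis=0)
            if not np.allclose(sums, 100.0, atol=1e-6):
                bad = self.values.columns[np.argmax(np.abs(sums - 100.0))]
                raise AbundanceTableError(
                    f"relative sample {bad!r} sums to {sums.max():.6g}, not 100"
                )

    # -- accessors --------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_taxa(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    def condition(self, cond: str) -> "AbundanceTable":
        """Sub-table for one condition, samples ordered by date_index."""
        if cond not in _CONDITIONS:
            raise AbundanceTableError(f"unknown condition {cond!r}")
        sel = self.meta[self.meta["condition"] == cond].sort_values("date_index")
        return AbundanceTable(self.values[list(sel.index)], sel.copy(), self.units)

    def date_order(self) -> list[str]:
        return list(self.meta.sort_values(["condition", "date_index"]).index)

    def profile(self, taxon: str) -> np.ndarray:
        return self.values.loc[taxon].to_numpy(dtype=float)


def merge_tables(table_c: AbundanceTable, table_b: AbundanceTable) -> AbundanceTable:
    """Join a C/B pair into one table over the union of samples.

    Used so depth normalization and the taxon-discard rule act on the whole
    dataset at once: a taxon present only under one condition keeps its zero
    row under the other instead of being dropped per-condition.
    """
    if list(table_c.values.index) != list(table_b.values.index):
        raise AbundanceTableError("tables have different taxon universes")
    if table_c.units != table_b.units:
        raise AbundanceTableError("tables have different units")
    values = pd.concat([table_c.values, table_b.values], axis=1)
    meta = pd.concat([table_c.meta, table_b.meta], axis=0)
    return AbundanceTable(values, meta, table_c.units)


def align_conditions(
    table_c: AbundanceTable, table_b: AbundanceTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Date-aligned value frames for a C/B pair (shared dates, same taxa)."""
    if list(table_c.values.index) != list(table_b.values.index):
        raise AbundanceTableError("tables have different taxon universes")
    c = table_c.condition("C")
    b = table_b.condition("B")
    dates_c = list(c.meta["date_index"])
    dates_b = list(b.meta["date_index"])
    shared = [d for d in dates_c if d in dates_b]
    if not shared:
        raise AbundanceTableError("no shared date_index between conditions")
    cols_c = [c.meta.index[dates_c.index(d)] for d in shared]
    cols_b = [b.meta.index[dates_b.index(d)] for d in shared]
    return c.values[cols_c], b.values[cols_b]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_abundance_table(
    path: str | Path,
    metadata: str | Path | pd.DataFrame | dict,
    units: str = COUNTS,
) -> AbundanceTable:
    """Read a taxa-by-samples TSV plus sample metadata.

    The TSV has taxon IDs in the first column and one column per sample.
    ``metadata`` is a 3-column TSV (sample, condition, date_index), a mapping
    ``{sample: (condition, date_index)}``, or an equivalent DataFrame.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    if isinstance(metadata, (str, Path)):
        meta = pd.read_csv(metadata, sep="\t")
        meta = meta.set_index(meta.columns[0])
    elif isinstance(metadata, dict):
        meta = pd.DataFrame.from_dict(
            metadata, orient="index", columns=["condition", "date_index"]
        )
    else:
        meta = metadata.copy()
        if "condition" not in meta.columns:
            meta = meta.set_index(meta.columns[0])
    meta.index = meta.index.astype(str)
    meta["date_index"] = meta["date_index"].astype(int)
    values.columns = values.columns.astype(str)
    return AbundanceTable(values, meta, units)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="taxon")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_counts(
    table: AbundanceTable,
) -> tuple[AbundanceTable, list[str]]:
    """Depth-normalize a count table and discard vanishing taxa.

    Every sample column is rescaled to the minimum total depth across
    samples (counts times min_depth / sample_depth), putting all samples on
    the scale of the shallowest library; a taxon is then discarded only if
    its adjusted value falls below 1 read in *every* sample.  Returns the
    adjusted table and the list of discarded taxa.
    """
    if table.units != COUNTS:
        raise AbundanceTableError("normalize_counts requires a counts table")
    depths = table.values.sum(axis=0)
    if (depths <= 0).any():
        bad = depths.index[depths <= 0][0]
        raise AbundanceTableError(f"sample {bad!r} has zero depth")
    adjusted = table.values * (float(depths.min()) / depths)
    keep = (adjusted >= 1).any(axis=1)
    discarded = list(adjusted.index[~keep])
    out = AbundanceTable(adjusted.loc[keep], table.meta.copy(), COUNTS)
    return out, discarded


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Rescale every sample column to sum to 100 (relative percent)."""
    if table.n_taxa == 0:
        raise AbundanceTableError("empty table")
    sums = table.values.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise AbundanceTableError(f"all-zero sample column {bad!r}")
    return AbundanceTable(table.values.div(sums, axis=1) * 100.0, table.meta.copy(), RELATIVE)


# ---------------------------------------------------------------------------
# Per-taxon features
# ---------------------------------------------------------------------------

def mean_nonzero(profile: Sequence[float] | np.ndarray) -> float:
    """Mean abundance over the samples where the taxon is present.

    The sum of the profile divided by the number of strictly positive
    entries; an all-zero profile maps to 0 so that condition-specific rare
    taxa stay well-defined.
    """
    x = np.asarray(profile, dtype=float)
    if x.size == 0:
        raise ValueError("empty profile")
    npos = int((x > 0).sum())
    if npos == 0:
        return 0.0
    return float(x.sum() / npos)


def classify_level(
    mean_nz: float, profile: Sequence[float] | np.ndarray
) -> tuple[str, bool, bool]:
    """(level, core, nR) from the presence-mean and the raw profile.

    Level H above 1% strictly, R below 0.1% strictly, L on the closed band
    [0.1, 1].  Core means present in every sample; nR flags rare taxa with at
    least one absence.
    """
    x = np.asarray(profile, dtype=float)
    if mean_nz > 1.0:
        level = "H"
    elif mean_nz < 0.1:
        level = "R"
    else:
        level = "L"
    core = bool((x > 0).all())
    nr = level == "R" and not core
    return level, core, nr


def diversity_indices(
    relative: Sequence[float] | np.ndarray,
    counts: Sequence[float] | np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(Shannon, inverse Simpson, Chao1) for one sample.

    Shannon and inverse Simpson use the relative abundances (natural log);
    Chao1 uses integer counts (defaulting to the relative vector if counts
    are not supplied, in which case singleton/doubleton detection only makes
    sense for integer input).  Chao1 is the classic estimator
    S_obs + F1^2 / (2 F2), with the F2 = 0 fallback S_obs + F1(F1-1)/2.
    """
    p = np.asarray(relative, dtype=float)
    if p.size == 0 or p.sum() <= 0:
        raise ValueError("empty sample")
    p = p[p > 0]
    p = p / p.sum()
    shannon = float(-(p * np.log(p)).sum())
    inv_simpson = float(1.0 / (p**2).sum())
    c = np.asarray(relative if counts is None else counts, dtype=float)
    c = c[c > 0]
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        chao1 = s_obs + f1 * f1 / (2.0 * f2)
    else:
        chao1 = s_obs + f1 * (f1 - 1) / 2.0
    return shannon, inv_simpson, float(chao1)


def paired_diff_test(
    c_profile: Sequence[float] | np.ndarray,
    b_profile: Sequence[float] | np.ndarray,
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Paired t-test on date-aligned C/B abundances -> (diff_status, p).

    Status is Diff_UP/Diff_DN when two-sided p < alpha, by the sign of the
    mean B-C difference; otherwise NDiff_UP/NDiff_DN by the same sign.
    Identically zero differences give p = 1 and NDiff_DN (no evidence, tie
    broken downward).
    """
    c = np.asarray(c_profile, dtype=float)
    b = np.asarray(b_profile, dtype=float)
    if c.shape != b.shape:
        raise ValueError(f"length mismatch: {c.shape} vs {b.shape}")
    if c.size < 2:
        raise ValueError("need at least 2 paired samples")
    d = b - c
    if np.allclose(d.std(ddof=1), 0.0):
        p = 1.0
    else:
        p = float(stats.ttest_rel(b, c).pvalue)
    up = d.mean() > 0
    if p < alpha:
        return ("Diff_UP" if up else "Diff_DN"), p
    return ("NDiff_UP" if up else "NDiff_DN"), p


def presence_partition(
    table_c: AbundanceTable, table_b: AbundanceTable
) -> tuple[set[str], set[str], set[str]]:
    """Venn partition of taxa present in C and/or B.

    A taxon is present in a condition if it is nonzero in at least one of
    that condition's samples.  Returns (shared, C-only, B-only).
    """
    if set(table_c.taxa) != set(table_b.taxa):
        raise AbundanceTableError("tables have different taxon universes")
    in_c = {t for t in table_c.taxa if (table_c.profile(t) > 0).any()}
    in_b = {t for t in table_b.taxa if (table_b.profile(t) > 0).any()}
    return in_c & in_b, in_c - in_b, in_b - in_c


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

@dataclass
class TaxonAnnotation:
    taxon: str
    mean_nonzero: float
    level: str
    core: bool
    nR: bool
    diff_status: str
    diff_p: float

    def __post_init__(self) -> None:
        if self.nR and (self.level != "R" or self.core):
            raise ValueError("nR implies level R and not core")


def annotate_taxa(
    table_c: AbundanceTable,
    table_b: AbundanceTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-taxon feature table for a paired relative-abundance dataset.

    Level/core/nR are computed on the concatenated C+B samples; the
    differential status from the paired per-date t-test.  Columns: taxon
    (index), mean_nonzero, level, core, nR, diff_status, diff_p.
    """
    if table_c.units != RELATIVE or table_b.units != RELATIVE:
        raise AbundanceTableError("annotation requires relative_percent tables")
    vc, vb = align_conditions(table_c, table_b)
    rows = []
    for taxon in table_c.taxa:
        combined = np.concatenate(
            [table_c.profile(taxon), table_b.profile(taxon)]
        )
        mnz = mean_nonzero(combined)
        level, core, nr = classify_level(mnz, combined)
        status, p = paired_diff_test(
            vc.loc[taxon].to_numpy(), vb.loc[taxon].to_numpy(), alpha=alpha
        )
        rows.append(
            {
                "taxon": taxon,
                "mean_nonzero": mnz,
                "level": level,
                "core": core,
                "nR": nr,
                "diff_status": status,
                "diff_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("taxon")
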