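"""Orthogroup count-matrix screen: filtering, Mann-Whitney enrichment, BH, and
group-wise genomic-feature comparisons.

The central object is a species x family matrix of non-negative integer gene
counts (a pandas DataFrame with species as the index).  Species are split
into a ``focal`` group (the symbiotic algae of interest) and ``other``; each
retained family is tested with a two-sided Mann-Whitney-Wilcoxon test on its
per-species counts, exactly (full enumeration of group assignments with
mid-ranks for ties) when the assignment count is small, otherwise with the
tie-corrected normal approximation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "load_matrix",
    "save_matrix",
    "load_groups",
    "filter_families",
    "wilcoxon_two_sided",
    "enrichment_scan",
    "bh_adjust",
    "group_feature_compare",
]

EXACT_ENUMERATION_LIMIT = 200_000


def load_matrix(path, orientation: str = "species_by_family") -> pd.DataFrame:
    """Load a count matrix TSV (header = family ids, first column = species).

    ``orientation`` must be declared: ``species_by_family`` (rows are species)
    or ``family_by_species`` (rows are families; the matrix is transposed on
    load).  Cells must be non-negative integers.
    """
    if orientation not in ("species_by_family", "family_by_species"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("no data rows in matrix file")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals % 1 != 0)]
        if len(bad):
            raise ValueError(
                f"non-integer or negative count at row {bad[0]!r}, column {col!r}"
            )
    df = df.astype(np.int64)
    if orientation == "family_by_species":
        df = df.T
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate species or family labels in matrix")
    return df


def save_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def load_groups(path) -> pd.Series:
    """Load a two-column TSV (species, group in {focal, other})."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise ValueError("group table must have exactly two columns")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    bad = sorted(set(ser.unique()) - {"focal", "other"})
    if bad:
        raise ValueError(f"unknown group labels {bad}; expected focal/other")
    return ser


def filter_families(matrix: pd.DataFrame, min_species: int = 3) -> pd.DataFrame:
    """Retain families present (count >= 1) in at least ``min_species`` species.

    The default of 3 removes species-specific and two-species families.
    """
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    keep = (matrix > 0).sum(axis=0) >= min_species
    return matrix.loc[:, keep]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x (mid-ranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    return float(ranks[:n].sum() - n * (n + 1) / 2.0)


def wilcoxon_two_sided(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns (U of x, p).

    When the number of group assignments C(n+m, n) is at most 200,000 the
    exact null distribution is built by full enumeration (doubled one-sided
    tail, capped at 1); otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return u_obs, 1.0
    if math.comb(n + m, n) <= EXACT_ENUMERATION_LIMIT:
        ranks = stats.rankdata(pooled)
        offset = n * (n + 1) / 2.0
        total = 0
        le = 0
        ge = 0
        eps = 1e-9
        for combo in itertools.combinations(range(n + m), n):
            u = ranks[list(combo)].sum() - offset
            total += 1
            if u <= u_obs + eps:
                le += 1
            if u >= u_obs - eps:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return u_obs, p
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u_obs, float(res.pvalue)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # family, U, p, p_adj (optional), direction, significant
    alpha: float
    adjust: str

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def enrichment_scan(
    matrix: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.01,
    adjust: str = "none",
) -> EnrichmentResult:
    """Per-family two-sided Mann-Whitney scan of focal vs other counts.

    With ``adjust="none"`` (default) significance is ``p < alpha`` on raw
    p-values; ``adjust="BH"`` thresholds Benjamini-Hochberg-adjusted values
    instead.  Families that are constant across the tested species (e.g.
    all-zero after subsetting) are dropped with a warning.  Direction is
    defined by mean-rank comparison, consistent with the statistic.
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"adjust must be 'none' or 'BH', got {adjust!r}")
    groups = groups.reindex(matrix.index).dropna()
    focal = matrix.index[groups == "focal"]
    other = matrix.index[groups == "other"]
    if len(focal) == 0 or len(other) == 0:
        raise ValueError("both focal and other groups must be non-empty on the matrix")
    sub = matrix.loc[focal.append(other)]
    constant = sub.columns[(sub.max(axis=0) == sub.min(axis=0))]
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant families (no defined test)",
            stacklevel=2,
        )
    tested = [c for c in sub.columns if c not in set(constant)]
    n_f = len(focal)
    rows = []
    for fam in tested:
        xv = sub.loc[focal, fam].to_numpy(dtype=float)
        yv = sub.loc[other, fam].to_numpy(dtype=float)
        u, p = wilcoxon_two_sided(xv, yv)
        mean_rank_focal = (u + n_f * (n_f + 1) / 2.0) / n_f
        mean_rank_other = (len(xv) * len(yv) - u + len(yv) * (len(yv) + 1) / 2.0) / len(yv)
        if mean_rank_focal > mean_rank_other:
            direction = "focal_enriched"
        elif mean_rank_focal < mean_rank_other:
            direction = "other_enriched"
        else:
            direction = "none"
        rows.append((fam, u, p, direction))
    table = pd.DataFrame(rows, columns=["family", "U", "p", "direction"]).set_index(
        "family"
    )
    if adjust == "BH":
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["p_adj"] < alpha
    else:
        table["p_adj"] = np.nan
        table["significant"] = table["p"] < alpha
    return EnrichmentResult(table=table, alpha=alpha, adjust=adjust)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_feature_compare(
    features: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Two-sided Wilcoxon comparison of numeric genomic features by group.

    Missing values are excluded per feature; a feature with fewer than two
    non-missing species in either group raises (single-species group) or is
    skipped with a warning (entirely missing group).  Group medians are
    reported so direction is explicit.
    """
    groups = groups.reindex(features.index).dropna()
    focal = features.index[groups == "focal"]
    other = features.index[groups == "other"]
    rows = []
    for feat in features.columns:
        xv = features.loc[focal, feat].dropna()
        yv = features.loc[other, feat].dropna()
        if len(xv) == 0 or len(yv) == 0:
            warnings.warn(f"feature {feat!r} entirely missing in one group; skipped")
            continue
        if len(xv) < 2 or len(yv) < 2:
            raise ValueError(
                f"feature {feat!r}: each group needs >= 2 species with data"
            )
        u, p = wilcoxon_two_sided(xv.to_numpy(), yv.to_numpy())
        rows.append((feat, u, p, float(xv.median()), float(yv.median())))
    return pd.DataFrame(
        rows, columns=["feature", "U", "p", "median_focal", "median_other"]
    ).set_index("feature")
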