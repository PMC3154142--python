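"""Group-mean methylation profiles, sample correlations, 1-r clustering and
the per-probe t-test census.

Samples cluster by 1 - r, where r is the Pearson correlation between their
beta profiles; correlation distance is the field's standard for comparing
methylation arrays because it ignores global intensity shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats as sps

from .errors import UndefinedValueError, ValidationError
from .io import BetaMatrix


@dataclass
class GroupProfile:
    """Per-probe mean beta within one study group."""

    group: str
    mean_beta: pd.Series


@dataclass
class Dendrogram:
    """Agglomerative merge history over samples at 1-r heights."""

    merges: list[tuple[int, int, float]]  # scipy cluster indices and merge height
    leaves: list[str]
    linkage_matrix: np.ndarray

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node):
            if node.is_leaf():
                return self.leaves[node.id]
            left, right = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def group_means(bm: BetaMatrix, sheet: pd.DataFrame) -> list[GroupProfile]:
    """Per-probe arithmetic mean beta within each group of the sample sheet.

    Missing cells are excluded from that probe's mean.  Every sample in the
    matrix must be assigned a group; an empty group raises an error naming it.
    """
    unassigned = [s for s in bm.samples if s not in sheet.index]
    if unassigned:
        raise ValidationError(f"samples without group assignment: {unassigned}")
    profiles = []
    for group, members in sheet.loc[list(bm.samples)].groupby("group", sort=True):
        cols = [s for s in members.index if s in bm.samples]
        if not cols:
            raise ValidationError(f"group {group!r} has no samples in the matrix")
        profiles.append(GroupProfile(group, bm.beta[cols].mean(axis=1, skipna=True)))
    for group in sheet["group"].unique():
        if group not in {p.group for p in profiles}:
            raise ValidationError(f"group {group!r} has no samples in the matrix")
    return profiles


def group_mean_frame(bm: BetaMatrix, sheet: pd.DataFrame) -> pd.DataFrame:
    """Group means as a probes x groups DataFrame."""
    profiles = group_means(bm, sheet)
    return pd.DataFrame({p.group: p.mean_beta for p in profiles})


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation on pairwise-complete observations.

    Requires >= 3 complete pairs and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError("need >= 3 pairwise-complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedValueError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_distance_matrix(bm: BetaMatrix) -> pd.DataFrame:
    """Symmetric matrix of d(i, j) = 1 - pearson_r(sample i, sample j)."""
    samples = sorted(bm.samples)  # lexicographic order makes ties deterministic
    n = len(samples)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = pearson_r(bm.beta[samples[i]], bm.beta[samples[j]])
            except UndefinedValueError as exc:
                raise UndefinedValueError(
                    f"correlation undefined for pair ({samples[i]}, {samples[j]})"
                ) from exc
            dist[i, j] = dist[j, i] = 1.0 - r
    return pd.DataFrame(dist, index=samples, columns=samples)


def cluster_samples(bm: BetaMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of samples under 1-r correlation distance.

    Deterministic: samples are taken in lexicographic order so equal-distance
    merges resolve by smallest member id.  ``linkage`` is any scipy method
    (default ``average``; ``complete`` is the common alternative).
    """
    if bm.shape[1] < 2:
        raise ValidationError("need at least two samples to cluster")
    dist = correlation_distance_matrix(bm)
    condensed = squareform(np.maximum(dist.to_numpy(), 0.0), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return Dendrogram(merges=merges, leaves=list(dist.index), linkage_matrix=Z)


def ttest_census(
    bm: BetaMatrix,
    sheet: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.01,
    equal_var: bool = False,
) -> tuple[pd.Series, int]:
    """Welch two-sample t-test per probe; returns (p-values, count with p < alpha).

    Probes constant in both groups with equal means get p = 1 (no evidence);
    zero-variance probes with unequal means get p = 0.  Set ``equal_var`` for
    the pooled-variance variant.
    """
    a_cols = sheet.index[sheet["group"] == group_a]
    b_cols = sheet.index[sheet["group"] == group_b]
    a_cols = [s for s in a_cols if s in bm.samples]
    b_cols = [s for s in b_cols if s in bm.samples]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValidationError("each group needs >= 2 samples for the t-test")
    A = bm.beta[a_cols].to_numpy()
    B = bm.beta[b_cols].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(A, B, axis=1, equal_var=equal_var, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    undef = np.isnan(p)
    if undef.any():
        mean_a = np.nanmean(A[undef], axis=1)
        mean_b = np.nanmean(B[undef], axis=1)
        p[undef] = np.where(np.isclose(mean_a, mean_b), 1.0, 0.0)
    pvals = pd.Series(p, index=bm.probes, name="p_value")
    return pvals, int((pvals < alpha).sum())
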