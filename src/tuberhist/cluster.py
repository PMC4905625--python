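"""Pattern discovery: log transform, Ward clustering, per-feature ANOVA.

The tuber patterns were originally found by agglomerative clustering of
three markers (mTORC1 activation via pS6 area %, dysmorphic neurons via
SMI32 density, giant cells via vimentin density) using Ward's minimum
variance criterion on squared Euclidean distances, after log-transforming
the left-skewed marker distributions. One-way ANOVA across the resulting
clusters identifies which features discriminate them.

Columns are z-standardized before the distance computation so that
percentage-scale and count-scale features contribute comparably.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
from scipy.spatial.distance import pdist

from .errors import DegenerateGroupError, InvalidInputError
from .stats import StatTestResult

#: Offset added before taking logs so zero densities stay finite.
LOG_EPSILON = 1e-3

#: Features clustered by default (the skewed trio).
DEFAULT_CLUSTER_FEATURES = ("ps6_pct", "smi32_density", "vimentin_density")


@dataclass
class FeatureMatrix:
    """Sample-by-feature table plus a record of log-transformed columns."""

    data: pd.DataFrame
    transform_log: set = dc_field(default_factory=set)

    @property
    def n(self) -> int:
        return len(self.data)


@dataclass
class LinkageTree:
    """Agglomeration history in scipy linkage form.

    ``merges`` has one row per merge: (left node, right node, height,
    cluster size). Heights are Ward distances, nondecreasing along the
    agglomeration.
    """

    merges: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        return sch.leaves_list(self.merges)


def log_skew_transform(
    m: FeatureMatrix,
    columns: Sequence[str],
    eps: float = LOG_EPSILON,
) -> FeatureMatrix:
    """Replace each value x in the named columns by ln(x + eps).

    Strictly monotone per column, so rank order is preserved. Columns
    already transformed are refused to prevent silent double application.
    """
    data = m.data.copy()
    done = set(m.transform_log)
    for col in columns:
        if col in done:
            raise InvalidInputError(f"column {col!r} already log-transformed")
        vals = data[col].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise InvalidInputError(f"column {col!r} has negative values")
        data[col] = np.log(vals + eps)
        done.add(col)
    return FeatureMatrix(data=data, transform_log=done)


def _standardized(m: FeatureMatrix, columns: Sequence[str]) -> np.ndarray:
    X = m.data.loc[:, list(columns)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise InvalidInputError("clustered columns contain missing values")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant column carries no distance information
    return (X - mu) / sd


def ward_linkage(
    m: FeatureMatrix, columns: Optional[Sequence[str]] = None
) -> LinkageTree:
    """Ward's-method agglomeration of the z-standardized feature columns."""
    columns = columns or [c for c in m.data.columns]
    X = _standardized(m, columns)
    if len(X) < 2:
        raise InvalidInputError("need at least 2 samples to build a tree")
    # condensed distances make the observation-matrix interpretation explicit
    return LinkageTree(merges=sch.linkage(pdist(X), method="ward"))


def ward_cluster(
    m: FeatureMatrix,
    k: int = 3,
    columns: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, LinkageTree]:
    """Cluster samples into k groups by Ward's method.

    Returns integer labels in 1..k and the linkage tree. Deterministic:
    scipy's agglomeration breaks ties by cluster index.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if m.n < k:
        raise InvalidInputError(f"cannot cut {m.n} samples into {k} clusters")
    if k == 1 or m.n == 1:
        return np.ones(m.n, dtype=int), (
            ward_linkage(m, columns) if m.n >= 2 else LinkageTree(np.empty((0, 4)))
        )
    tree = ward_linkage(m, columns)
    labels = sch.fcluster(tree.merges, t=k, criterion="maxclust")
    return labels.astype(int), tree


def auto_cluster_count(tree: LinkageTree, kmax: int = 10) -> int:
    """Choose the number of clusters at the largest merge-height gap.

    The gap between consecutive Ward heights — measured on the log scale,
    i.e. the largest height *ratio* — is evaluated for cuts giving 2..kmax
    clusters; the cut just below the largest gap wins (smaller k on ties).
    The relative gap is scale-invariant and, unlike the absolute gap (raw
    or squared), does not let the final merge dominate when cluster sizes
    are unbalanced.
    """
    h = tree.heights
    n_merges = len(h)
    if n_merges < 2:
        return max(1, n_merges)
    kmax = min(kmax, n_merges)
    # cutting between merge (n_merges - k) and (n_merges - k + 1) yields k clusters
    gaps = {
        k: h[n_merges - k + 1] / max(h[n_merges - k], 1e-12)
        for k in range(2, kmax + 1)
    }
    best = max(sorted(gaps), key=lambda k: gaps[k])
    return int(best)


def anova_feature_discrimination(
    m: FeatureMatrix,
    labels: Sequence,
    columns: Optional[Sequence[str]] = None,
) -> dict[str, StatTestResult]:
    """One-way ANOVA of every feature across cluster labels.

    Returns per-feature F statistics with (between, within) degrees of
    freedom and the p-value from the F distribution.
    """
    labels = np.asarray(labels)
    if len(labels) != m.n:
        raise InvalidInputError("labels must match the number of samples")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise InvalidInputError("need at least 2 groups for ANOVA")
    for g in uniq:
        if np.count_nonzero(labels == g) < 2:
            raise DegenerateGroupError(f"group {g!r} has fewer than 2 samples")
    columns = columns or [c for c in m.data.columns]
    out: dict[str, StatTestResult] = {}
    n = m.n
    k = uniq.size
    for col in columns:
        x = m.data[col].to_numpy(dtype=float)
        grand = x.mean()
        ssb = ssw = 0.0
        for g in uniq:
            xg = x[labels == g]
            ssb += xg.size * (xg.mean() - grand) ** 2
            ssw += float(np.sum((xg - xg.mean()) ** 2))
        dfb, dfw = k - 1, n - k
        msb, msw = ssb / dfb, ssw / dfw
        if msw == 0.0:
            F = 0.0 if msb == 0.0 else float("inf")
            p = 1.0 if msb == 0.0 else 0.0
        else:
            F = msb / msw
            p = float(ss.f.sf(F, dfb, dfw))
        out[col] = StatTestResult(
            "one-way-anova", float(F), (dfb, dfw), p, n,
            extra={"ms_between": msb, "ms_within": msw},
        )
    return out
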