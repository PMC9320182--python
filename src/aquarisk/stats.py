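"""Descriptive statistics, correlation matrices and hierarchical clustering.

Descriptives follow the campaign-report convention: mean, sample SD (n-1
denominator) and the coefficient of variation CV = SD/mean * 100, classified
low (<=15%), intermediate or high (>=35%).  Correlations are Pearson by
default (Spearman selectable) on pairwise-complete observations, with
two-sided p-values from the t transform of r.  Metal clustering standardises
each variable to z-scores and applies Ward (default) or average linkage on
Euclidean distances between variable profiles, the common recipe for
water-chemistry dendrograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .reference import classify

__all__ = [
    "DescriptiveRow",
    "LinkageTree",
    "describe",
    "describe_table",
    "correlation_matrix",
    "cluster_metals",
]


@dataclass(frozen=True)
class DescriptiveRow:
    variable: str
    group: str
    n: int
    mean: float
    sd: float
    cv: float | None  # %, None when mean == 0 with sd > 0
    cv_label: str


def describe(values: Sequence[float], variable: str = "", group: str = "") -> DescriptiveRow:
    """Mean, sample SD and CV class of one variable in one group."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 1:
        raise ValueError("describe needs at least one value")
    mean = float(v.mean())
    if v.size == 1:
        warnings.warn("single observation: SD undefined under n-1, reported as 0")
        sd = 0.0
    else:
        sd = float(v.std(ddof=1))
    if mean > 0:
        cv = sd / mean * 100.0
        label = classify("CV", cv)
    elif sd == 0.0:
        cv = 0.0
        label = classify("CV", 0.0)
    else:
        cv, label = None, "n/a"
    return DescriptiveRow(variable=variable, group=group, n=int(v.size),
                          mean=mean, sd=sd, cv=cv, cv_label=label)


def describe_table(df: pd.DataFrame, variables: Sequence[str],
                   group_col: str | None = None) -> pd.DataFrame:
    """Descriptives for many variables, optionally per group (long format)."""
    rows = []
    groups = [("all", df)] if group_col is None else list(df.groupby(group_col, sort=False))
    for gname, gdf in groups:
        for var in variables:
            r = describe(gdf[var].dropna().to_numpy(), variable=var, group=str(gname))
            rows.append(vars(r))
    return pd.DataFrame(rows)


def correlation_matrix(
    df: pd.DataFrame,
    variables: Sequence[str],
    method: str = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation matrix with two-sided p-values on pairwise-complete pairs.

    Returns ``(r, p)`` DataFrames; the diagonal of ``r`` is exactly 1 and the
    matrix is symmetric.  Cells with fewer than 3 complete pairs or a
    zero-variance variable are NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    corr = sps.pearsonr if method == "pearson" else sps.spearmanr
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    cols = {v: df[v].to_numpy(dtype=float) for v in variables}
    for i, vi in enumerate(variables):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            vj = variables[j]
            a, b = cols[vi], cols[vj]
            mask = np.isfinite(a) & np.isfinite(b)
            if mask.sum() < 3:
                continue
            aa, bb = a[mask], b[mask]
            if np.ptp(aa) == 0.0 or np.ptp(bb) == 0.0:
                warnings.warn(f"zero variance in {vi!r} or {vj!r}: cell undefined")
                continue
            res = corr(aa, bb)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=list(variables), columns=list(variables))
    pdf = pd.DataFrame(p, index=list(variables), columns=list(variables))
    return rdf, pdf


def correlation_long(r: pd.DataFrame, p: pd.DataFrame,
                     alpha: tuple[float, float] = (0.05, 0.01)) -> pd.DataFrame:
    """Long-format (var1, var2, r, p, stars) for the upper triangle."""
    rows = []
    cols = list(r.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pv = p.loc[a, b]
            stars = "**" if pv < alpha[1] else "*" if pv < alpha[0] else ""
            rows.append({"var1": a, "var2": b, "r": r.loc[a, b], "p": pv, "stars": stars})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge history over variables (metals).

    ``merges`` is the scipy linkage matrix: row t merges nodes merges[t,0]
    and merges[t,1] (leaves are 0..n-1, internal nodes n+t) at height
    merges[t,2].  ``labels`` names the leaves.
    """

    merges: np.ndarray
    labels: tuple[str, ...]

    def cut(self, k: int) -> dict[str, int]:
        """Cluster id per leaf label when the tree is cut into k clusters."""
        assignments = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assignments)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["node_a", "node_b", "height", "size"])


def cluster_metals(
    df: pd.DataFrame,
    variables: Sequence[str],
    linkage: str = "ward",
) -> LinkageTree:
    """Hierarchical clustering of variables from their z-scored sample profiles.

    Distance is Euclidean between standardized variable columns (variables are
    the observations being clustered); zero-variance variables are excluded
    with a warning.  Deterministic given input order; scipy breaks ties by
    lowest index first.
    """
    if linkage not in ("ward", "average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    keep, profiles = [], []
    for v in variables:
        col = df[v].to_numpy(dtype=float)
        col = col[np.isfinite(col)]
        if col.size < 2 or np.ptp(col) == 0.0:
            warnings.warn(f"excluding zero-variance variable {v!r} from clustering")
            continue
        keep.append(v)
        profiles.append((col - col.mean()) / col.std(ddof=1))
    if len(keep) < 2:
        raise ValueError("need at least 2 variables with variance to cluster")
    lengths = {p.size for p in profiles}
    if len(lengths) != 1:
        raise ValueError("variables have unequal complete-case lengths")
    X = np.vstack(profiles)  # one row per variable
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    return LinkageTree(merges=Z, labels=tuple(keep))
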