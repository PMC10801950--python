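"""Correlated-variable group identification.

Variables measured on the same subjects cluster into blocks of strong
positive pairwise correlation (cartilage thicknesses, functional scores,
pain scores, EV subpopulations).  This module computes the pairwise Pearson
correlation matrix, cuts a Ward tree on the distance d = 1 − r into k core
groups, and collects variables that associate weakly with their own cluster
into a residual group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort import ZScoreTable
from .stats import StatsError, pearson_correlation

RESIDUAL = "residual"


class GroupingError(ValueError):
    """Invalid input to variable grouping."""


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with per-pair significance.

    ``r`` and ``p`` are symmetric DataFrames over the variables (unit
    diagonal in ``r``); ``n`` records the pairwise-complete sample size of
    each entry.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def variables(self) -> list[str]:
        return list(self.r.columns)


@dataclass
class GroupAssignment:
    """Variable → group mapping: core groups 1..k plus a residual group.

    ``mean_within_r`` is each variable's mean correlation with the other
    members of the cluster it was first placed in (the quantity the residual
    rule thresholds).
    """

    assignment: dict
    k: int
    mean_within_r: dict

    def group_members(self) -> dict:
        out: dict = {}
        for var, gid in self.assignment.items():
            out.setdefault(gid, []).append(var)
        return out

    def labels_for(self, variables) -> list:
        return [self.assignment[v] for v in variables]


def correlation_matrix(table: ZScoreTable) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation matrix of the variables.

    Every variable pair needs ≥ 3 complete paired observations; offending
    pairs are listed in the error.
    """
    data = table.data
    cols = list(data.columns)
    m = len(cols)
    idx = pd.Index(cols, name="variable")
    if not data.isna().any().any():
        # complete data: vectorized r and t-transform p-values
        x = data.to_numpy(dtype=float)
        nobs = len(data)
        if nobs < 3:
            raise GroupingError("need >=3 complete observations for correlations")
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [cols[i] for i in np.nonzero(sd == 0)[0]]
            raise GroupingError(f"zero-variance variables: {bad}")
        r = np.corrcoef(x, rowvar=False)
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        rr = np.clip(np.abs(r), 0.0, 1.0 - 1e-15)
        t = rr * np.sqrt((nobs - 2) / (1.0 - rr**2))
        p = 2.0 * sps.t.sf(t, df=nobs - 2)
        np.fill_diagonal(p, 0.0)
        n = np.full((m, m), nobs)
        return CorrelationMatrix(
            r=pd.DataFrame(r, index=idx, columns=idx),
            p=pd.DataFrame(p, index=idx, columns=idx),
            n=pd.DataFrame(n, index=idx, columns=idx),
        )
    r = np.eye(m)
    p = np.zeros((m, m))
    n = np.full((m, m), len(data))
    too_few = []
    for i in range(m):
        for j in range(i + 1, m):
            pair = data[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                too_few.append((cols[i], cols[j]))
                continue
            try:
                res = pearson_correlation(pair.iloc[:, 0], pair.iloc[:, 1])
            except StatsError as exc:
                raise GroupingError(
                    f"correlation undefined for pair ({cols[i]}, {cols[j]}): {exc}"
                ) from exc
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.p_value
    if too_few:
        raise GroupingError(f"pairs with <3 complete observations: {too_few}")
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


def cluster_variables(
    corr: CorrelationMatrix, k: int = 5, residual_threshold: float = 0.4
) -> GroupAssignment:
    """Cut a Ward tree on d = 1 − r into k core groups plus a residual group.

    The signed distance (1 − r, not 1 − |r|) keeps anticorrelated variables
    apart: the planted structure is blocks of *positive* correlation.  After
    each flat cut into k clusters, every variable whose mean correlation
    with the other members of its cluster falls below ``residual_threshold``
    moves to the residual group (singleton clusters count as below
    threshold), and the remaining core variables are re-cut — iterating
    until no variable is exiled, so weakly associated variables cannot hold
    tree cuts hostage and force genuine groups to merge.  Variables are
    processed in name order, so the result is independent of input order;
    surviving core clusters are renumbered 1..k' by each cluster's
    alphabetically first member.
    """
    if k < 2:
        raise GroupingError(f"k must be >= 2, got {k}")
    if not 0.0 < residual_threshold < 1.0:
        raise GroupingError(f"residual_threshold must be in (0, 1), got {residual_threshold}")
    variables = sorted(corr.variables)
    if k > len(variables):
        raise GroupingError(f"k={k} exceeds the {len(variables)} variables")
    r = corr.r.loc[variables, variables].to_numpy(dtype=float)

    mean_within: dict = {}
    core = list(range(len(variables)))
    residual: list[int] = []
    flat = np.array([], dtype=int)
    while len(core) >= k:
        d = np.clip(1.0 - r[np.ix_(core, core)], 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="ward")
        flat = fcluster(z, t=k, criterion="maxclust")
        exiled = []
        for pos, i in enumerate(core):
            mates = [core[q] for q in range(len(core)) if flat[q] == flat[pos] and q != pos]
            mw = float(np.mean(r[i, mates])) if mates else float("nan")
            mean_within[variables[i]] = mw
            if not mates or mw < residual_threshold:
                exiled.append(i)
        if not exiled:
            break
        residual.extend(exiled)
        core = [i for i in core if i not in exiled]
    else:
        # fewer core candidates than k: everything is residual
        residual.extend(core)
        core = []

    assignment: dict = {variables[i]: RESIDUAL for i in residual}
    for pos, i in enumerate(core):
        assignment[variables[i]] = int(flat[pos])

    # renumber surviving core clusters 1..k' by alphabetically first member
    order: dict = {}
    for var in variables:
        gid = assignment[var]
        if gid != RESIDUAL and gid not in order:
            order[gid] = len(order) + 1
    assignment = {
        v: (RESIDUAL if g == RESIDUAL else order[g]) for v, g in assignment.items()
    }
    return GroupAssignment(assignment=assignment, k=len(order), mean_within_r=mean_within)


def group_correlogram_export(
    corr: CorrelationMatrix,
    assignment: GroupAssignment | None = None,
    category_order=None,
    alpha: float = 0.05,
    matrix_path=None,
    stars_path=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export the correlogram ordered by group or by variable category.

    Returns (and optionally writes) the reordered correlation matrix and a
    boolean "star" matrix flagging significant correlations (p < ``alpha``).
    ``assignment`` orders variables by group id (residual last);
    ``category_order`` — a mapping variable → category plus a category
    list — orders by category instead.  Reordering permutes rows/columns
    only; the matrix content is unchanged.
    """
    variables = corr.variables
    if assignment is not None:
        if set(assignment.assignment) != set(variables):
            raise GroupingError("assignment does not cover the correlation matrix variables")
        def group_key(v):
            g = assignment.assignment[v]
            return (1, 0, v) if g == RESIDUAL else (0, g, v)
        ordered = sorted(variables, key=group_key)
    elif category_order is not None:
        categories, cat_of = category_order
        rank = {c: i for i, c in enumerate(categories)}
        ordered = sorted(variables, key=lambda v: (rank.get(cat_of[v], len(rank)), v))
    else:
        ordered = sorted(variables)
    r = corr.r.loc[ordered, ordered]
    stars = (corr.p.loc[ordered, ordered] < alpha) & ~np.eye(len(ordered), dtype=bool)
    if matrix_path is not None:
        r.to_csv(matrix_path)
    if stars_path is not None:
        stars.astype(int).to_csv(stars_path)
    return r, stars


def write_assignment(assignment: GroupAssignment, path) -> None:
    """Write the assignment CSV: ``variable,group_id,mean_within_r``."""
    pd.DataFrame(
        {
            "variable": list(assignment.assignment),
            "group_id": [assignment.assignment[v] for v in assignment.assignment],
            "mean_within_r": [assignment.mean_within_r[v] for v in assignment.assignment],
        }
    ).to_csv(path, index=False)


__all__ = [
    "RESIDUAL",
    "GroupingError",
    "CorrelationMatrix",
    "GroupAssignment",
    "correlation_matrix",
    "cluster_variables",
    "group_correlogram_export",
    "write_assignment",
]
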