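"""Phylogenetic generalized least squares and independent contrasts.

PGLS is GLS with residual covariance proportional to the shared-ancestry
matrix C (optionally lambda-scaled): on a star phylogeny (C = I) it is
ordinary least squares, and under fixed Brownian motion the simple-
regression slope equals the through-origin regression of independent
contrasts -- an identity used here as an internal oracle.

Categorical predictors are treatment-coded (evergreen / low-elevation
reference) and tested with the overall F against the intercept-only
nested model.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .evomodels import chol_with_jitter
from .phylo import PhyloCovariance, Tree

logger = logging.getLogger(__name__)

__all__ = [
    "PglsFit",
    "ContrastSet",
    "design_matrix",
    "pgls_fit",
    "pgls_correlation",
    "pgls_group_table",
    "pic",
]

MODES = ("fixed-bm", "lambda-ml")

_REFERENCE_LEVELS = {"habit": "evergreen", "elevation": "low"}


@dataclass(frozen=True)
class PglsFit:
    """GLS fit under a phylogenetic covariance.

    ``params``/``bse``/``tvalues``/``pvalues`` are per design column;
    ``fvalue``/``f_pvalue`` test all non-intercept terms against the
    intercept-only nested model; ``r_squared`` is 1 - RSS/RSS0 in the
    GLS metric; ``lam`` is the lambda actually used (1 for fixed-BM).
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fvalue: float
    f_pvalue: float
    sigma2: float
    r_squared: float
    loglik: float
    df_resid: int
    n: int
    mode: str
    lam: float


@dataclass(frozen=True)
class ContrastSet:
    """Standardized independent contrasts: n-1 values, the internal node
    producing each, and the expected variance each was standardized by."""

    contrasts: np.ndarray
    node_ids: tuple[int, ...]
    expected_variances: np.ndarray


def design_matrix(
    data: pd.DataFrame, predictors: Sequence[str]
) -> pd.DataFrame:
    """Build an intercept + treatment-coded design from a species-indexed
    frame.  Categorical columns use evergreen/low as reference levels
    (alphabetical fallback); numeric columns enter as-is."""
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}
    for name in predictors:
        col = data[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            ref = _REFERENCE_LEVELS.get(name)
            if ref in levels:
                levels = [ref] + [l for l in levels if l != ref]
            for level in levels[1:]:
                cols[f"{name}[{level}]"] = (col == level).astype(float).to_numpy()
        else:
            cols[name] = col.astype(float).to_numpy()
    return pd.DataFrame(cols, index=data.index)


def _gls(V: np.ndarray, y: np.ndarray, X: np.ndarray):
    """GLS core: returns (beta, cov_unscaled, rss, logdetV, solve)."""
    L = chol_with_jitter(V)
    solve = lambda b: linalg.cho_solve((L, True), b)
    XtiV = X.T @ solve(X)
    XtiVy = X.T @ solve(y)
    try:
        beta = linalg.solve(XtiV, XtiVy, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise ValueError("rank-deficient design (aliased columns)") from exc
    resid = y - X @ beta
    rss = float(resid @ solve(resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    cov_unscaled = np.linalg.inv(XtiV)
    return beta, cov_unscaled, rss, logdet


def _loglik(n: int, rss: float, logdet: float) -> float:
    s2 = max(rss / n, np.finfo(float).tiny)
    return -0.5 * (n * math.log(2.0 * math.pi * s2) + logdet + n)


def pgls_fit(
    y,
    X: pd.DataFrame,
    C: PhyloCovariance,
    *,
    mode: str = "fixed-bm",
) -> PglsFit:
    """Fit y = X beta + e with Cov(e) = sigma2 C(lambda).

    ``mode`` is ``"fixed-bm"`` (lambda = 1, the plain phylogenetic
    covariance) or ``"lambda-ml"`` (lambda estimated by ML on the
    regression residuals).  ``X`` must include the intercept column
    (see :func:`design_matrix`).  With C = I the result coincides with
    OLS coefficient-by-coefficient.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    yv = np.asarray(
        y.loc[list(C.labels)] if isinstance(y, pd.Series) else y, dtype=float
    )
    Xm = X.loc[list(C.labels)] if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
    Xv = Xm.to_numpy(dtype=float)
    names = list(Xm.columns)
    n, p = Xv.shape
    if n != C.n or len(yv) != n:
        raise ValueError("labels of y/X do not align with the covariance")
    if n - p <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    if np.linalg.matrix_rank(Xv) < p:
        # name the aliased columns for the error message
        _, R = np.linalg.qr(Xv)
        aliased = [names[i] for i in range(p) if abs(R[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    if mode == "fixed-bm":
        lam = 1.0
    else:
        def negll(l: float) -> float:
            _, _, rss, logdet = _gls(C.lambda_scaled(l), yv, Xv)
            return -_loglik(n, rss, logdet)

        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        cand = [(l, negll(l)) for l in grid]
        for lo, hi in zip(grid[:-1], grid[1:]):
            res = optimize.minimize_scalar(
                negll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
            )
            cand.append((float(res.x), float(res.fun)))
        lam = min(cand, key=lambda t: t[1])[0]

    V = C.lambda_scaled(lam)
    beta, cov_u, rss, logdet = _gls(V, yv, Xv)
    df = n - p
    sigma2 = rss / df
    bse = np.sqrt(sigma2 * np.diag(cov_u))
    tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    # intercept-only nested model in the same covariance
    _, _, rss0, _ = _gls(V, yv, np.ones((n, 1)))
    if p > 1:
        fval = ((rss0 - rss) / (p - 1)) / (rss / df)
        f_p = float(stats.f.sf(fval, p - 1, df))
    else:
        fval, f_p = 0.0, 1.0
    r2 = 1.0 - rss / rss0 if rss0 > 0 else 0.0

    return PglsFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        fvalue=float(fval),
        f_pvalue=f_p,
        sigma2=float(sigma2),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        loglik=_loglik(n, rss, logdet),
        df_resid=df,
        n=n,
        mode=mode,
        lam=float(lam),
    )


def pgls_correlation(x, y, C: PhyloCovariance, *, mode: str = "fixed-bm") -> float:
    """Phylogenetic correlation r = sign(slope) * sqrt(R^2).

    Computed from the symmetric GLS projection
    r = x'Py / sqrt(x'Px * y'Py) with P the covariance-weighted
    intercept-removing projector, so r(x, y) = r(y, x) exactly.  In
    ``lambda-ml`` mode lambda is first estimated from the y-on-x
    regression and then used in the symmetric formula.
    """
    xv = np.asarray(x.loc[list(C.labels)] if isinstance(x, pd.Series) else x, float)
    yv = np.asarray(y.loc[list(C.labels)] if isinstance(y, pd.Series) else y, float)
    lam = 1.0
    if mode == "lambda-ml":
        X = pd.DataFrame(
            {"Intercept": np.ones(C.n), "x": xv}, index=list(C.labels)
        )
        lam = pgls_fit(pd.Series(yv, index=list(C.labels)), X, C, mode=mode).lam
    V = C.lambda_scaled(lam)
    L = chol_with_jitter(V)
    solve = lambda b: linalg.cho_solve((L, True), b)
    ones = np.ones(C.n)
    iV1 = solve(ones)
    denom = float(ones @ iV1)

    def proj(v: np.ndarray) -> np.ndarray:
        return solve(v) - iV1 * (float(ones @ solve(v)) / denom)

    px, py = proj(xv), proj(yv)
    sxx = float(xv @ px)
    syy = float(yv @ py)
    if sxx <= 0 or syy <= 0:
        raise ValueError("zero phylogenetic variance in x or y")
    return float(xv @ py / math.sqrt(sxx * syy))


def pgls_group_table(
    table,
    C: PhyloCovariance,
    *,
    mode: str = "fixed-bm",
) -> pd.DataFrame:
    """Habit/elevation PGLS p-values plus raw-scale cell means and SDs.

    For each trait: the habit effect is tested within each elevation
    subset, and the elevation effect within each habit subset, each time
    restricting the covariance to the relevant species (equivalent to
    pruning the tree).  Fits use log10 values; the means/SDs shown are
    on the natural scale.  Subsets with n < 3 are flagged (NaN p), not
    computed.
    """
    from .traits import TRAIT_COLUMNS, log10_table

    logt = table if table.transformed else log10_table(table)
    raw = table  # natural-scale means are only meaningful untransformed
    rows = []
    habit = logt.habit()
    elev = logt.elevation()
    for trait in TRAIT_COLUMNS:
        row: dict[str, float | str] = {"trait": trait}
        for e in ("low", "middle", "high"):
            for h in ("evergreen", "deciduous"):
                sel = raw.data[(habit == h) & (elev == e)][trait]
                row[f"mean_{h}_{e}"] = float(sel.mean()) if len(sel) else np.nan
                row[f"sd_{h}_{e}"] = (
                    float(sel.std(ddof=1)) if len(sel) > 1 else np.nan
                )
            row[f"p_habit_{e}"] = _subset_p(logt, C, trait, elev == e, "habit", mode)
        for h in ("evergreen", "deciduous"):
            row[f"p_elevation_{h}"] = _subset_p(
                logt, C, trait, habit == h, "elevation", mode
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")


def _subset_p(logt, C, trait, mask, predictor, mode) -> float:
    labels = [s for s in C.labels if mask.get(s, False)]
    sub = logt.data.loc[labels]
    if len(labels) < 3 or sub[predictor].nunique() < 2:
        return np.nan
    Csub = C.subset(labels)
    X = design_matrix(sub, [predictor])
    fit = pgls_fit(sub[trait], X, Csub, mode=mode)
    return fit.f_pvalue


# ---------------------------------------------------------------------------
# Independent contrasts (internal oracle)

def _resolve_polytomies(tree: Tree) -> Tree:
    """Resolve polytomies with zero-length branches in input order."""
    parents = list(tree.parent)
    children = [list(ch) for ch in tree.children]
    lengths = list(tree.lengths)
    labels: list[str | None] = list(tree.labels)
    changed = False
    i = 0
    while i < len(children):
        ch = children[i]
        while len(ch) > 2:
            changed = True
            new = len(parents)
            first, second = ch[0], ch[1]
            parents.append(i)
            children.append([first, second])
            lengths.append(0.0)
            labels.append(None)
            parents[first] = new
            parents[second] = new
            ch[:2] = [new]
        i += 1
    if not changed:
        return tree
    logger.info("pic: resolved polytomies with zero-length branches")
    return Tree(
        parent=tuple(parents),
        children=tuple(tuple(c) for c in children),
        lengths=tuple(lengths),
        labels=tuple(labels),
        root=tree.root,
        arbitrarily_rooted=tree.arbitrarily_rooted,
    )


def pic(tree: Tree, x) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    Pruning pass: at each internal node the contrast is the difference
    of the two child values standardized by the square root of the
    summed (adjusted) branch lengths; the node value is the
    branch-length-weighted average of the children and its own branch is
    extended by v1 v2 / (v1 + v2).
    """
    tree = _resolve_polytomies(tree)
    tips = tree.tip_indices()
    if isinstance(x, pd.Series):
        values = {t: float(x[tree.labels[t]]) for t in tips}
    else:
        values = {t: float(v) for t, v in zip(tips, np.asarray(x, dtype=float))}
    vlen = {t: tree.lengths[t] for t in range(tree.n_nodes)}
    contrasts: list[float] = []
    variances: list[float] = []
    nodes: list[int] = []
    for node in tree.postorder():
        ch = tree.children[node]
        if not ch:
            continue
        assert len(ch) == 2
        a, b = ch
        va, vb = vlen[a], vlen[b]
        if va + vb <= 0:
            raise ValueError(
                f"zero combined branch length at internal node {node}"
            )
        contrasts.append((values[a] - values[b]) / math.sqrt(va + vb))
        variances.append(va + vb)
        nodes.append(node)
        values[node] = (vb * values[a] + va * values[b]) / (va + vb)
        vlen[node] = tree.lengths[node] + va * vb / (va + vb)
    return ContrastSet(
        contrasts=np.array(contrasts),
        node_ids=tuple(nodes),
        expected_variances=np.array(variances),
    )
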