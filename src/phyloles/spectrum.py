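"""Leaf economics spectrum: PCA, PASS scores and distance regressions.

The spectrum is the first principal axis of the correlation matrix of
the nine log10 traits.  Axis 1 is oriented so the Amass loading is
positive: acquisitive traits (Wm, Nmass, Pmass, Amass, Rmass, PNUE)
then load positively and conservative traits (LLS, LMA, CC) negatively,
and each species' oriented axis-1 score (PASS) is a scalar proxy for
its position on the acquisitive--conservative continuum.

PASS distance |PASS_A - PASS_B| between two species is a proxy for
economic/niche distance; regressing it on pairwise phylogenetic
distance asks whether economic divergence tracks evolutionary
divergence.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import DistanceMatrix
from .traits import TRAIT_COLUMNS, TraitTable

__all__ = [
    "SpectrumResult",
    "PairRegressionResult",
    "GroupPassSummary",
    "fit_spectrum",
    "build_pairs",
    "pass_distance",
    "distance_regression",
    "group_mean_pass",
]

PAIR_FILTERS = ("all", "intra_elevation_habit_cross")


@dataclass(frozen=True)
class SpectrumResult:
    """PCA of the nine log10 traits in the correlation metric.

    ``loadings``: trait x axis unit-norm eigenvectors;
    ``variance_fractions``: eigenvalues / 9 (sum to 1);
    ``scores``: z-scored data projected on the eigenvectors, so the
    per-axis score variance equals the eigenvalue;
    ``pass_scores``: oriented axis-1 scores (PASS).
    """

    loadings: pd.DataFrame
    variance_fractions: np.ndarray
    scores: pd.DataFrame
    pass_scores: pd.Series


@dataclass(frozen=True)
class PairRegressionResult:
    """OLS of economic distance on phylogenetic distance over species
    pairs, with Pearson r, the parametric p the source analyses report
    (pairs are not independent -- see ``note``), and an optional
    Mantel-style permutation p."""

    pairs: tuple[tuple[str, str], ...]
    pair_filter: str
    r: float
    p: float
    slope: float
    intercept: float
    n_pairs: int
    permutation_p: float | None = None
    n_permutations: int = 0
    note: str = (
        "parametric p treats pairs as independent; prefer permutation_p"
    )


@dataclass(frozen=True)
class GroupPassSummary:
    """Per habit x elevation PASS means/SDs plus the mean cross-habit
    PASS distance at each elevation (mean |PASS_e - PASS_d| over all
    evergreen x deciduous pairs at that elevation)."""

    cell_stats: pd.DataFrame
    cross_habit_distance: pd.Series


def fit_spectrum(table: TraitTable) -> SpectrumResult:
    """PCA on the correlation matrix of the nine log10 traits.

    Requires a log10-transformed table with >= 3 complete species.
    Columns are z-scored (sample SD); the correlation matrix is
    eigendecomposed; axis 1 is sign-oriented so the Amass loading is
    positive, later axes so their largest-magnitude loading is positive
    (a deterministic tie-break with no effect on the analysis).
    """
    if not table.transformed:
        raise ValueError("fit_spectrum expects a log10-transformed table")
    X = table.traits().to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 species, got {n}")
    if np.isnan(X).any():
        raise ValueError("missing trait values; apply complete_cases first")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [TRAIT_COLUMNS[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant trait column(s): {const}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    amass_idx = TRAIT_COLUMNS.index("Amass")
    if eigvec[amass_idx, 0] < 0:
        eigvec[:, 0] = -eigvec[:, 0]
    for k in range(1, p):
        if eigvec[np.argmax(np.abs(eigvec[:, k])), k] < 0:
            eigvec[:, k] = -eigvec[:, k]

    scores = Z @ eigvec
    axes = [f"PC{k + 1}" for k in range(p)]
    return SpectrumResult(
        loadings=pd.DataFrame(eigvec, index=list(TRAIT_COLUMNS), columns=axes),
        variance_fractions=eigval / eigval.sum(),
        scores=pd.DataFrame(scores, index=table.data.index, columns=axes),
        pass_scores=pd.Series(scores[:, 0], index=table.data.index, name="PASS"),
    )


def build_pairs(
    species: Sequence[str],
    *,
    pair_filter: str = "all",
    habit: pd.Series | None = None,
    elevation: pd.Series | None = None,
) -> list[tuple[str, str]]:
    """Unordered species pairs under a filter.

    ``all`` keeps every pair; ``intra_elevation_habit_cross`` keeps only
    pairs at the same elevation with one evergreen and one deciduous
    member (the co-occurring cross-habit comparisons).
    """
    if pair_filter not in PAIR_FILTERS:
        raise ValueError(f"unknown pair filter {pair_filter!r}")
    pairs = list(combinations(species, 2))
    if pair_filter == "intra_elevation_habit_cross":
        if habit is None or elevation is None:
            raise ValueError("habit and elevation required for this filter")
        pairs = [
            (a, b)
            for a, b in pairs
            if elevation[a] == elevation[b] and habit[a] != habit[b]
        ]
    if not pairs:
        raise ValueError(f"no pairs left under filter {pair_filter!r}")
    return pairs


def pass_distance(
    scores: pd.Series,
    pairs: Sequence[tuple[str, str]],
) -> np.ndarray:
    """|score_A - score_B| for each pair (a pseudometric in 1-D)."""
    missing = {s for p in pairs for s in p if s not in scores.index}
    if missing:
        raise KeyError(f"species without scores: {sorted(missing)}")
    return np.array([abs(scores[a] - scores[b]) for a, b in pairs])


def distance_regression(
    econ_dist: np.ndarray,
    phylo_dist: np.ndarray,
    pairs: Sequence[tuple[str, str]],
    *,
    pair_filter: str = "all",
    permutations: int = 0,
    scores: pd.Series | None = None,
    phylo_matrix: DistanceMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> PairRegressionResult:
    """Regress economic distance on phylogenetic distance over pairs.

    Reports the OLS slope/intercept, Pearson r and the parametric
    two-sided p.  If ``permutations`` > 0, a Mantel-style permutation p
    is added: species labels of the PASS vector are permuted,
    pair distances recomputed, and the two-sided tail counted with a
    (permutations + 1) denominator; this requires ``scores`` and
    ``phylo_matrix``.
    """
    econ = np.asarray(econ_dist, dtype=float)
    phylo = np.asarray(phylo_dist, dtype=float)
    if econ.shape != phylo.shape or len(econ) != len(pairs):
        raise ValueError("pair sets do not match")
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    if econ.std() == 0 or phylo.std() == 0:
        raise ValueError("zero variance in a distance vector")
    fit = stats.linregress(phylo, econ)
    r_obs, p_par = float(fit.rvalue), float(fit.pvalue)

    perm_p = None
    if permutations > 0:
        if scores is None or phylo_matrix is None:
            raise ValueError(
                "permutation test needs the PASS scores and the phylogenetic "
                "distance matrix"
            )
        rng = rng if rng is not None else np.random.default_rng(0)
        labels = list(scores.index)
        vals = scores.to_numpy()
        idx = {lab: k for k, lab in enumerate(labels)}
        ia = np.array([idx[a] for a, _ in pairs])
        ib = np.array([idx[b] for _, b in pairs])
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(len(labels))
            pv = vals[perm]
            econ_perm = np.abs(pv[ia] - pv[ib])
            if econ_perm.std() == 0:
                continue
            r_perm = np.corrcoef(phylo, econ_perm)[0, 1]
            if abs(r_perm) >= abs(r_obs):
                hits += 1
        perm_p = (hits + 1) / (permutations + 1)

    return PairRegressionResult(
        pairs=tuple(pairs),
        pair_filter=pair_filter,
        r=r_obs,
        p=p_par,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_pairs=len(pairs),
        permutation_p=perm_p,
        n_permutations=permutations,
    )


def group_mean_pass(scores: pd.Series, table: TraitTable) -> GroupPassSummary:
    """PASS means/SDs per habit x elevation cell and the mean cross-habit
    PASS distance per elevation.

    Empty cells are flagged with NaN statistics rather than raising.
    """
    habit = table.habit()
    elev = table.elevation()
    rows = []
    for e in ("low", "middle", "high"):
        for h in ("evergreen", "deciduous"):
            sel = scores[(habit == h) & (elev == e)]
            rows.append(
                {
                    "elevation": e,
                    "habit": h,
                    "n": len(sel),
                    "mean": float(sel.mean()) if len(sel) else np.nan,
                    "sd": float(sel.std(ddof=1)) if len(sel) > 1 else np.nan,
                }
            )
    cells = pd.DataFrame(rows)

    cross = {}
    for e in ("low", "middle", "high"):
        ever = scores[(habit == "evergreen") & (elev == e)].to_numpy()
        decid = scores[(habit == "deciduous") & (elev == e)].to_numpy()
        if len(ever) == 0 or len(decid) == 0:
            cross[e] = np.nan
        else:
            cross[e] = float(np.mean(np.abs(ever[:, None] - decid[None, :])))
    return GroupPassSummary(
        cell_stats=cells,
        cross_habit_distance=pd.Series(cross, name="cross_habit_pass_distance"),
    )
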