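"""Maximum-likelihood models of continuous trait evolution on a tree.

Three nested models of a single trait x observed at the tips:

* Brownian motion (BM): x ~ MVN(mu 1, sigma2 C) with C the
  shared-ancestry covariance; closed-form ML.
* Pagel's lambda: off-diagonals of C scaled by lambda in [0, 1];
  lambda = 0 is a star phylogeny (no signal), lambda = 1 is BM.
  Profiled over lambda by bounded 1-D optimisation with multistart.
* Single-optimum Ornstein--Uhlenbeck (OU): pull of strength alpha
  toward an optimum theta, root at the optimum.  For tips i, j with
  patristic distance d_ij and MRCA depth s_ij,

      V_ij = sigma2 / (2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha s_ij)),

  a form that does not assume an ultrametric tree.  Larger alpha means
  a stronger pull, faster effective evolution and weaker phylogenetic
  signal; alpha -> 0 recovers BM.

Likelihood-ratio tests use the chi-square(1) tail; the OU-vs-BM test
sits on the alpha = 0 boundary and is therefore conservative (noted in
the result).
"""
from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import PhyloCovariance

logger = logging.getLogger(__name__)

__all__ = [
    "EvoModelFit",
    "SignalTestResult",
    "LrtResult",
    "bm_fit",
    "lambda_fit",
    "ou_fit",
    "ou_covariance",
    "bm_vs_ou_lrt",
    "signal_rate_correlation",
]

_JITTER = 1e-10


def chol_with_jitter(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, retrying once with +1e-10 on the diagonal
    (logged); raises with a condition-number diagnostic if that fails."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        pass
    try:
        L = linalg.cholesky(V + _JITTER * np.eye(len(V)), lower=True)
        logger.debug("Cholesky needed +%g jitter on the diagonal", _JITTER)
        return L
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise np.linalg.LinAlgError(
            f"covariance not positive definite even with jitter "
            f"(condition number {cond:.3g})"
        ) from exc


@dataclass(frozen=True)
class EvoModelFit:
    """One fitted trait-evolution model.

    ``mu_or_theta`` is the root state mu (BM/lambda) or the optimum
    theta (OU); ``sigma2`` the rate in trait-units^2 per branch-length
    unit; ``lam``/``alpha`` are model-specific; ``loglik`` the maximised
    log-likelihood.
    """

    model: str  # "BM" | "lambda" | "OU"
    mu_or_theta: float
    sigma2: float
    loglik: float
    n_params: int
    lam: float | None = None
    alpha: float | None = None
    at_boundary: bool = False
    n: int = 0
    data_fingerprint: str = ""


@dataclass(frozen=True)
class SignalTestResult:
    """Pagel's lambda with likelihood-ratio tests against lambda = 0
    (no signal) and lambda = 1 (Brownian expectation)."""

    lambda_hat: float
    loglik: float
    p0: float
    p1: float
    fit: EvoModelFit


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    p_value: float
    note: str = ""


def _fingerprint(labels: Sequence[str], x: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update("\x00".join(labels).encode())
    h.update(np.ascontiguousarray(np.round(x, 12)).tobytes())
    return h.hexdigest()[:16]


def _align(C: PhyloCovariance, x) -> np.ndarray:
    """Order a trait vector to match the covariance labels."""
    if isinstance(x, pd.Series):
        missing = [lab for lab in C.labels if lab not in x.index]
        if missing:
            raise KeyError(f"trait values missing for: {missing}")
        return x.loc[list(C.labels)].to_numpy(dtype=float)
    if isinstance(x, Mapping):
        return np.array([float(x[lab]) for lab in C.labels])
    arr = np.asarray(x, dtype=float)
    if arr.shape != (C.n,):
        raise ValueError(f"trait vector has shape {arr.shape}, expected ({C.n},)")
    return arr


def _profile_mvn(V: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Closed-form profile ML of x ~ MVN(mu 1, sigma2 V) for fixed V.

    Returns (mu_hat, sigma2_hat, loglik) with sigma2_hat = Q/n (the ML
    divisor) and loglik = -0.5 (n log(2 pi sigma2) + log|V| + n).
    """
    n = len(x)
    L = chol_with_jitter(V)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ones = np.ones(n)
    iV1 = linalg.cho_solve((L, True), ones)
    iVx = linalg.cho_solve((L, True), x)
    mu = float(ones @ iVx) / float(ones @ iV1)
    r = x - mu
    q = float(r @ linalg.cho_solve((L, True), r))
    sigma2 = q / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return mu, sigma2, loglik


def bm_fit(C: PhyloCovariance, x) -> EvoModelFit:
    """Closed-form ML Brownian-motion fit of one trait."""
    xv = _align(C, x)
    if C.n < 2:
        raise ValueError("need at least 2 tips")
    mu, sigma2, ll = _profile_mvn(C.C, xv)
    return EvoModelFit(
        model="BM", mu_or_theta=mu, sigma2=sigma2, loglik=ll, n_params=2,
        n=C.n, data_fingerprint=_fingerprint(C.labels, xv),
    )


def lambda_fit(C: PhyloCovariance, x) -> SignalTestResult:
    """Profile-ML Pagel's lambda on [0, 1] with LRTs against 0 and 1.

    The profile log-likelihood is maximised by bounded Brent searches
    started from the brackets between {0, 0.25, 0.5, 0.75, 1}
    (tolerance 1e-8); endpoints are evaluated exactly so lnL(lambda=1)
    equals the BM log-likelihood.
    """
    xv = _align(C, x)
    if C.n < 3:
        raise ValueError("need at least 3 tips")

    def negll(lam: float) -> float:
        return -_profile_mvn(C.lambda_scaled(lam), xv)[2]

    starts = [0.0, 0.25, 0.5, 0.75, 1.0]
    cand: list[tuple[float, float]] = [(lam, negll(lam)) for lam in starts]
    for lo, hi in zip(starts[:-1], starts[1:]):
        res = optimize.minimize_scalar(
            negll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:
            raise RuntimeError(f"lambda optimisation failed in [{lo}, {hi}]: {res}")
        cand.append((float(res.x), float(res.fun)))
    lam_hat, nll_hat = min(cand, key=lambda t: t[1])
    ll_hat = -nll_hat
    mu, sigma2, _ = _profile_mvn(C.lambda_scaled(lam_hat), xv)

    ll0 = -negll(0.0)
    ll1 = -negll(1.0)
    p0 = float(stats.chi2.sf(max(0.0, 2.0 * (ll_hat - ll0)), df=1))
    p1 = float(stats.chi2.sf(max(0.0, 2.0 * (ll_hat - ll1)), df=1))
    fit = EvoModelFit(
        model="lambda", mu_or_theta=mu, sigma2=sigma2, loglik=ll_hat,
        n_params=3, lam=lam_hat,
        at_boundary=lam_hat in (0.0, 1.0),
        n=C.n, data_fingerprint=_fingerprint(C.labels, xv),
    )
    return SignalTestResult(lambda_hat=lam_hat, loglik=ll_hat, p0=p0, p1=p1, fit=fit)


def ou_covariance(C: PhyloCovariance, alpha: float, sigma2: float = 1.0) -> np.ndarray:
    """Single-optimum OU tip covariance (root at the optimum), valid for
    non-ultrametric trees."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    s = C.C  # MRCA depths
    d = C.patristic()
    return sigma2 / (2.0 * alpha) * np.exp(-alpha * d) * (1.0 - np.exp(-2.0 * alpha * s))


_OU_LOG_BOUNDS = (-6.0, 2.0)  # log10(alpha) search range


def ou_fit(C: PhyloCovariance, x) -> EvoModelFit:
    """Profile-ML single-optimum OU fit.

    For fixed alpha, theta and sigma2 have the closed GLS form; alpha is
    maximised on a log10 grid over [1e-6, 1e2] and refined by bounded
    Brent search (tolerance 1e-8 in log10 alpha).  A fit pinned at
    either bound is returned with ``at_boundary`` set.
    """
    xv = _align(C, x)
    if C.n < 3:
        raise ValueError("need at least 3 tips")

    def negll_log(la: float) -> float:
        return -_profile_mvn(ou_covariance(C, 10.0 ** la), xv)[2]

    lo, hi = _OU_LOG_BOUNDS
    grid = np.linspace(lo, hi, 33)
    vals = [negll_log(g) for g in grid]
    k = int(np.argmin(vals))
    blo = grid[max(0, k - 1)]
    bhi = grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(
        negll_log, bounds=(blo, bhi), method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:
        raise RuntimeError(f"alpha optimisation failed: {res}")
    cand = [(float(res.x), float(res.fun))] + list(zip(map(float, grid), map(float, vals)))
    la_hat, nll = min(cand, key=lambda t: t[1])
    alpha = 10.0 ** la_hat
    theta, sigma2, ll = _profile_mvn(ou_covariance(C, alpha), xv)
    at_bound = la_hat <= lo + 1e-6 or la_hat >= hi - 1e-6
    if at_bound:
        # the lower bound is the benign BM limit (alpha -> 0)
        level = logging.DEBUG if la_hat <= lo + 1e-6 else logging.WARNING
        logger.log(level, "ou_fit: alpha pinned at search bound (alpha=%.3g)", alpha)
    return EvoModelFit(
        model="OU", mu_or_theta=theta, sigma2=sigma2, loglik=ll, n_params=3,
        alpha=alpha, at_boundary=at_bound,
        n=C.n, data_fingerprint=_fingerprint(C.labels, xv),
    )


def bm_vs_ou_lrt(bm: EvoModelFit, ou: EvoModelFit) -> LrtResult:
    """Likelihood-ratio test of OU against nested BM.

    D = 2 (lnL_OU - lnL_BM) clipped at 0, referred to chi-square(1).
    The alpha = 0 null sits on the parameter boundary, making the test
    conservative; the note records this.
    """
    if bm.model != "BM" or ou.model != "OU":
        raise ValueError("expects a BM fit and an OU fit")
    if bm.data_fingerprint != ou.data_fingerprint:
        raise ValueError("fits come from different data (fingerprint mismatch)")
    D = max(0.0, 2.0 * (ou.loglik - bm.loglik))
    p = float(stats.chi2.sf(D, df=1))
    return LrtResult(
        statistic=D,
        p_value=p,
        note="alpha=0 boundary null: chi2(1) reference is conservative",
    )


def signal_rate_correlation(
    lambdas: Sequence[float],
    alphas: Sequence[float],
    *,
    log10_alpha: bool = False,
) -> tuple[float, float]:
    """Pearson correlation between per-trait lambda and alpha estimates
    (raw alpha by default; set ``log10_alpha`` for the log-scale
    variant).  Returns (r, two-sided p)."""
    lam = np.asarray(lambdas, dtype=float)
    al = np.asarray(alphas, dtype=float)
    if lam.shape != al.shape or len(lam) < 3:
        raise ValueError("need >= 3 paired (lambda, alpha) estimates")
    if log10_alpha:
        al = np.log10(al)
    if lam.std() == 0 or al.std() == 0:
        raise ValueError("zero variance in lambda or alpha estimates")
    r, p = stats.pearsonr(lam, al)
    return float(r), float(p)
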