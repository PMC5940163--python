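"""Genomic relationships, population structure, and genomic heritability.

* VanRaden (method 1) genomic relationship matrix G = ZZ' / (2 sum p_k q_k),
  with Z the allele-frequency-centered dosage matrix.
* PCA on G with a Patterson-style Tracy-Widom significance test for
  population structure.
* REML estimation of genomic heritability h2_g = sigma2_g / (sigma2_g +
  sigma2_e) under y = mu + g + e, g ~ N(0, G sigma2_g), solved exactly in
  the eigenbasis of G by 1-D profile-likelihood optimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .data_io import GenotypeMatrix

__all__ = [
    "GRM",
    "PCAResult",
    "HeritabilityEstimate",
    "StructureTest",
    "vanraden_grm",
    "pca_on_grm",
    "structure_significance",
    "genomic_heritability_reml",
    "write_grm",
    "read_grm",
]


@dataclass
class GRM:
    """Symmetric marker-derived relatedness matrix among lines."""

    line_ids: list[str]
    values: np.ndarray
    n_markers_used: int
    marker_subset_seed: int | None = None

    def __post_init__(self) -> None:
        G = np.asarray(self.values, dtype=float)
        if G.shape[0] != G.shape[1] or G.shape[0] != len(self.line_ids):
            raise ValueError("GRM must be square and match line_ids")
        if np.max(np.abs(G - G.T)) > 1e-10:
            raise ValueError("GRM must be symmetric")
        self.values = 0.5 * (G + G.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending, negatives clipped to 0
    variance_fraction: np.ndarray  # eigenvalue / trace
    scores: np.ndarray             # n x k, eigenvectors * sqrt(eigenvalue)
    line_ids: list[str]


@dataclass
class HeritabilityEstimate:
    h2g: float
    se: float
    sigma2_g: float
    sigma2_e: float
    converged: bool
    n_iterations: int
    loglik: float = float("nan")


@dataclass
class StructureTest:
    statistics: np.ndarray     # Tracy-Widom statistic per leading axis
    p_values: np.ndarray       # approximate upper-tail p-values
    significant: np.ndarray    # per-axis decision at alpha
    structured: bool           # any axis significant
    alpha: float
    n_markers_effective: float


def vanraden_grm(g: GenotypeMatrix, n_subset: int | None = None,
                 seed: int | None = None) -> GRM:
    """VanRaden method-1 GRM with allele frequencies from the sample.

    G = ZZ' / (2 sum_k p_k (1 - p_k)),  Z = M - 2P.

    If ``n_subset`` is smaller than the marker count, a uniform random
    subset (without replacement, under ``seed``) is used; the subset size
    and seed are recorded for reproducibility.
    """
    if g.missing_mask.any():
        raise ValueError("GRM requires complete dosages; impute first")
    M = g.dosage
    p_all = M.shape[1]
    if n_subset is not None and n_subset < p_all:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(p_all, size=n_subset, replace=False))
        M = M[:, idx]
    p_freq = M.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p_freq * (1.0 - p_freq)))
    if denom <= 0:
        raise ValueError("all markers in the subset are monomorphic")
    Z = M - 2.0 * p_freq[None, :]
    G = Z @ Z.T / denom
    return GRM(list(g.line_ids), G, M.shape[1], seed)


def pca_on_grm(grm: GRM, k: int | None = None) -> PCAResult:
    """Eigendecomposition of G; scores are eigenvectors scaled by sqrt(lambda)."""
    n = grm.n
    if k is None:
        k = n
    if k > n:
        raise ValueError(f"k={k} exceeds number of lines {n}")
    lam, V = np.linalg.eigh(grm.values)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    lam_clip = np.clip(lam, 0.0, None)
    total = lam_clip.sum()
    frac = lam_clip / total if total > 0 else np.zeros_like(lam_clip)
    scores = V[:, :k] * np.sqrt(lam_clip[:k])[None, :]
    return PCAResult(lam_clip, frac, scores, list(grm.line_ids))


# ---------------------------------------------------------------------------
# Tracy-Widom structure test
# ---------------------------------------------------------------------------

# Upper-tail quantiles of the Tracy-Widom (beta=1) distribution.
_TW1_CDF = np.array([0.50, 0.75, 0.90, 0.95, 0.975, 0.99, 0.995, 0.999])
_TW1_Q = np.array([-1.2686, -0.5923, 0.4501, 0.9793, 1.4538, 2.0234, 2.4224, 3.2724])


def _tw1_pvalue(x: float) -> float:
    """Approximate upper-tail p-value by interpolation of the TW1 table."""
    if x <= _TW1_Q[0]:
        return 1.0  # below the median: clearly non-significant
    if x >= _TW1_Q[-1]:
        # exponential tail extrapolation beyond the table
        return float((1.0 - _TW1_CDF[-1]) * np.exp(-(x - _TW1_Q[-1])))
    cdf = np.interp(x, _TW1_Q, _TW1_CDF)
    return float(1.0 - cdf)


def structure_significance(pca: PCAResult, n_markers: int, n_lines: int,
                           alpha: float = 0.01, n_axes: int = 10) -> StructureTest:
    """Patterson-style Tracy-Widom test for population structure.

    Each leading eigenvalue is tested against the Tracy-Widom (beta=1) null
    after removing previously tested axes; the effective marker count is
    re-estimated from the remaining spectrum at each step (moment estimator).
    The population is declared structured if any tested axis is significant
    at ``alpha``.
    """
    if n_lines < 3:
        raise ValueError("need at least 3 lines to test structure")
    lam_all = np.asarray(pca.eigenvalues, dtype=float)
    lam_all = lam_all[lam_all > 1e-12 * max(lam_all.max(), 1.0)]
    # at most n-1 informative axes (G is centered)
    m_axes = min(n_axes, max(len(lam_all) - 1, 1))
    stats = np.empty(m_axes)
    pvals = np.empty(m_axes)
    n_eff_first = float("nan")
    for i in range(m_axes):
        lam = lam_all[i:]
        nprime = len(lam)
        s1 = lam.sum()
        s2 = float(np.sum(lam ** 2))
        # moment estimator of the effective marker count: for a white
        # Wishart spectrum, E[s2/s1^2] = 1/n + 1/m, so 1/n_eff = s2/s1^2 - 1/m
        denom = nprime * s2 - s1 ** 2
        if denom <= 0:
            stats[i:] = -np.inf
            pvals[i:] = 1.0
            break
        n_eff = max(nprime * s1 ** 2 / denom, 2.0)
        if i == 0:
            n_eff_first = n_eff
        # normalize leading eigenvalue as in Patterson et al.
        ell = nprime * lam[0] / s1
        sq_n = np.sqrt(n_eff - 1.0)
        sq_p = np.sqrt(float(nprime))
        mu = (sq_n + sq_p) ** 2 / n_eff
        sigma = (sq_n + sq_p) / n_eff * (1.0 / sq_n + 1.0 / sq_p) ** (1.0 / 3.0)
        stats[i] = (ell - mu) / sigma
        pvals[i] = _tw1_pvalue(stats[i])
    sig = pvals < alpha
    return StructureTest(stats, pvals, sig, bool(sig.any()), alpha, n_eff_first)


# ---------------------------------------------------------------------------
# REML genomic heritability
# ---------------------------------------------------------------------------

def _reml_profile(h2: float, lam: np.ndarray, yt: np.ndarray,
                  xt: np.ndarray) -> tuple[float, float, float]:
    """Profiled REML log-likelihood of h2 (sigma2_p profiled out).

    Model in the eigenbasis of G: var(y~) = sigma2_p * (h2*lam + 1-h2).
    Returns (loglik, mu_hat, sigma2_p_hat).
    """
    n = yt.shape[0]
    wv = h2 * lam + (1.0 - h2)
    wv = np.maximum(wv, 1e-12)
    xx = float(np.sum(xt ** 2 / wv))
    xy = float(np.sum(xt * yt / wv))
    mu = xy / xx
    res = yt - mu * xt
    q = float(np.sum(res ** 2 / wv))
    s2p = q / (n - 1)
    ll = -0.5 * ((n - 1) * np.log(s2p) + float(np.sum(np.log(wv)))
                 + np.log(xx) + (n - 1))
    return ll, mu, s2p


def genomic_heritability_reml(y: np.ndarray, grm: GRM,
                              min_lines: int = 10) -> HeritabilityEstimate:
    """REML genomic heritability from y = mu + g + e, g ~ N(0, G sigma2_g).

    Solved exactly by eigendecomposition of G followed by bounded 1-D
    optimization of the profiled restricted likelihood over h2 in (0, 1).
    The SE comes from the curvature (observed information) of the profile
    at the optimum.  Non-convergence is flagged, not raised.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != grm.n:
        raise ValueError("y must align with the GRM line order")
    if y.shape[0] < min_lines:
        raise ValueError(f"need at least {min_lines} lines for REML")
    lam, U = np.linalg.eigh(grm.values)
    lam = np.maximum(lam, 1e-8)  # ridge on numerically negative eigenvalues
    # optimize on the standardized scale so h2 is exactly location/scale free
    y_sd = y.std(ddof=1)
    if y_sd <= 0:
        raise ValueError("y has zero variance")
    y_std = (y - y.mean()) / y_sd
    yt = U.T @ y_std
    xt = U.T @ np.ones_like(y)

    neg = lambda h: -_reml_profile(h, lam, yt, xt)[0]
    opt = minimize_scalar(neg, bounds=(1e-6, 1.0 - 1e-6), method="bounded",
                          options={"xatol": 1e-8, "maxiter": 500})
    # polish by golden section: Brent's bounded method stops at ~sqrt(eps)|x|,
    # which is too coarse for the scale-invariance contract on h2
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = max(float(opt.x) - 1e-6, 1e-7), min(float(opt.x) + 1e-6, 1 - 1e-7)
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = neg(c), neg(d)
    for _ in range(60):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = neg(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = neg(d)
    h2 = float(0.5 * (a + b))
    ll, _, s2p = _reml_profile(h2, lam, yt, xt)
    s2p *= y_sd ** 2  # back to the trait scale
    sigma2_g = h2 * s2p
    sigma2_e = (1.0 - h2) * s2p

    # SE from numerical curvature of the profile log-likelihood
    eps = 1e-4
    lo, hi = max(h2 - eps, 1e-7), min(h2 + eps, 1.0 - 1e-7)
    d2 = (_reml_profile(hi, lam, yt, xt)[0]
          - 2.0 * ll
          + _reml_profile(lo, lam, yt, xt)[0]) / ((hi - lo) / 2.0) ** 2
    se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else float("inf")

    return HeritabilityEstimate(
        h2g=h2, se=se, sigma2_g=float(sigma2_g), sigma2_e=float(sigma2_e),
        converged=bool(opt.success), n_iterations=int(opt.nfev),
        loglik=float(ll),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_grm(grm: GRM, path: str | Path) -> None:
    df = pd.DataFrame(grm.values, index=grm.line_ids, columns=grm.line_ids)
    df.index.name = "line"
    df.to_csv(path)


def read_grm(path: str | Path) -> GRM:
    df = pd.read_csv(path, index_col=0)
    return GRM(list(df.index.astype(str)), df.to_numpy(float), n_markers_used=0)


def write_pca_scores(pca: PCAResult, path: str | Path) -> None:
    k = pca.scores.shape[1]
    df = pd.DataFrame(pca.scores, index=pca.line_ids,
                      columns=[f"PC{i + 1}" for i in range(k)])
    df["variance_fraction"] = np.nan
    df.iloc[:k, -1] = pca.variance_fraction[:k]
    df.index.name = "line"
    df.to_csv(path)
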