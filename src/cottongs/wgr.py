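"""Bayesian whole-genome regression under five priors, via Gibbs sampling.

The base model is

    y = mu + X b + e,     e_i ~ N(0, sigma2_e / w_i)

with y the (optionally standardized) adjusted means, X the column-
standardized marker matrix and b the vector of marker effects.  The five
priors on b distinguish the models:

* ``BRR``    — b_k ~ N(0, sigma2_b), one common variance (Bayesian ridge);
* ``BayesA`` — b_k ~ N(0, sigma2_k), per-marker scaled-inv-chi2 variances
               (marginally a scaled-t);
* ``BayesB`` — spike-and-slab: b_k = 0 with prob. 1-pi, else N(0, sigma2_k)
               with per-marker variances;
* ``BayesC`` — spike-and-slab with one common slab variance;
* ``RKHS``   — kernel regression y = mu + u + e, u ~ N(0, K sigma2_u),
               sampled in the eigenbasis of K.

Unstated hyperparameters follow the conventions of standard Bayesian
genomic-regression software: scaled-inv-chi2 scales are set so the prior
mode allocates a fraction ``r2_prior`` of the phenotypic variance to the
markers (and 1 - r2_prior to the residual), with df0 = 5; the nonnull
proportion pi gets a Beta prior with mean ``pi0`` and weight ``pi_counts``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _samplers
from .data_io import StandardizedMatrix

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "FitResult",
    "fit_wgr",
    "compute_dic",
    "nonnull_proportion",
    "build_kernel",
    "predict_gebv",
    "save_fit",
]

MODELS = ("BRR", "BayesA", "BayesB", "BayesC", "RKHS")
_VAR_FLOOR = 1e-10  # numerical floor on sampled variances


@dataclass
class PriorSpec:
    """Prior family and hyperparameters for one whole-genome regression."""

    model: str = "BayesB"
    r2_prior: float = 0.5       # prior fraction of variance assigned to markers
    df0: float = 5.0            # scaled-inv-chi2 degrees of freedom
    pi0: float = 0.5            # prior mean nonnull probability (BayesB/C)
    pi_counts: float = 10.0     # prior weight on pi (Beta sample size)
    kernel: str = "gaussian"    # RKHS only: 'linear_G' or 'gaussian'
    bandwidth: float = 1.0      # RKHS gaussian kernel bandwidth h
    fixed_sigma2_b: float | None = None  # fix marker/kernel variance (no update)
    fixed_sigma2_e: float | None = None  # fix residual variance (no update)
    fixed_pi: float | None = None        # fix pi (BayesB/C)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if not 0 < self.r2_prior < 1:
            raise ValueError("r2_prior must lie in (0, 1)")
        if self.df0 <= 0:
            raise ValueError("df0 must be positive")
        if not 0 < self.pi0 < 1:
            raise ValueError("pi0 must lie in (0, 1)")


@dataclass
class MCMCSettings:
    """Gibbs chain length; defaults match the full-fidelity analysis."""

    n_iter: int = 210_000
    burn_in: int = 10_000
    thin: int = 20
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def fast(cls, seed: int = 0) -> "MCMCSettings":
        """Reduced settings for tests and CI (6,000 / 1,000 / thin 5)."""
        return cls(n_iter=6_000, burn_in=1_000, thin=5, seed=seed)


@dataclass
class FitResult:
    """Posterior summaries from one whole-genome regression fit."""

    model: str
    mu_hat: float
    b_hat: np.ndarray                   # posterior-mean marker effects (p,)
    gebv: np.ndarray                    # per-line genomic values (n,)
    sigma2_e_hat: float
    sigma2_e_sd: float
    dic: float
    d_bar: float
    p_d: float
    h2_implied: float = float("nan")    # E[var(genomic values) | y] / var(y)
    inclusion_prob: np.ndarray | None = None  # per-marker P(delta=1 | y)
    pi_hat: float | None = None
    pi_sd: float | None = None
    sigma2_b_hat: float | None = None   # common marker variance (BRR/BayesC slab)
    sigma2_u_hat: float | None = None   # kernel variance (RKHS)
    u_hat: np.ndarray | None = None     # kernel random effect (RKHS)
    alpha_hat: np.ndarray | None = None # K^{-1} u_hat, for kernel prediction
    chains: dict = field(default_factory=dict)  # retained draws (variances, pi, deviance)
    settings: dict = field(default_factory=dict)
    marker_ids: list = field(default_factory=list)
    line_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def build_kernel(X: np.ndarray | StandardizedMatrix, kernel: str = "gaussian",
                 bandwidth: float = 1.0, grm: np.ndarray | None = None) -> np.ndarray:
    """Build an n x n PSD kernel for RKHS regression.

    ``linear_G`` returns the supplied genomic relationship matrix;
    ``gaussian`` returns exp(-h * D2 / median(D2)) with D2 the squared
    Euclidean distance between standardized genotype rows.  A numerically
    non-PSD result has its negative eigenvalues clipped to zero.
    """
    if kernel == "linear_G":
        if grm is None:
            raise ValueError("linear_G kernel requires a GRM")
        K = np.asarray(grm, dtype=float)
    elif kernel == "gaussian":
        Xv = X.X if isinstance(X, StandardizedMatrix) else np.asarray(X, float)
        sq = (Xv ** 2).sum(axis=1)
        D2 = sq[:, None] + sq[None, :] - 2.0 * Xv @ Xv.T
        np.fill_diagonal(D2, 0.0)
        D2 = np.maximum(D2, 0.0)
        off = D2[np.triu_indices_from(D2, k=1)]
        med = np.median(off) if off.size else 1.0
        if med <= 0:
            med = 1.0
        K = np.exp(-bandwidth * D2 / med)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    K = 0.5 * (K + K.T)
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-8 * max(1.0, w.max()):
        import warnings
        warnings.warn("kernel not PSD; clipping negative eigenvalues")
        lam, V = np.linalg.eigh(K)
        K = (V * np.clip(lam, 0.0, None)) @ V.T
        K = 0.5 * (K + K.T)
    return K


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _prior_scales(var_y: float, p: int, prior: PriorSpec) -> tuple[float, float]:
    """Scaled-inv-chi2 scale sums (S_b, S_e): prior mode S/(df+2) hits the
    variance split implied by r2_prior (MSx = p for standardized X)."""
    r2 = prior.r2_prior
    df0 = prior.df0
    if prior.model in ("BayesB", "BayesC"):
        mode_b = var_y * r2 / (prior.pi0 * p)
    else:
        mode_b = var_y * r2 / p
    S_b = mode_b * (df0 + 2.0)
    S_e = var_y * (1.0 - r2) * (df0 + 2.0)
    return S_b, S_e


def fit_wgr(y: np.ndarray, X: StandardizedMatrix | np.ndarray, prior: PriorSpec,
            mcmc: MCMCSettings, weights: np.ndarray | None = None,
            grm: np.ndarray | None = None) -> FitResult:
    """Fit one Bayesian whole-genome regression by Gibbs sampling.

    Parameters
    ----------
    y:
        Trait values aligned to the rows of ``X``.
    X:
        Column-standardized genotypes (ignored for RKHS with linear_G,
        where ``grm`` supplies the kernel).
    weights:
        Optional positive per-record weights; the residual variance of
        record i is sigma2_e / w_i (inverse-squared-SE weighting of
        adjusted means).
    """
    if isinstance(X, StandardizedMatrix):
        marker_ids, line_ids, Xv = X.marker_ids, X.line_ids, X.X
    else:
        Xv = np.asarray(X, dtype=float)
        marker_ids, line_ids = [], []
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if np.isnan(y).any() or np.isnan(Xv).any():
        raise ValueError("NaN in y or X; filter/impute first")
    if Xv.shape[0] != n:
        raise ValueError("rows of X do not align with y")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w <= 0).any():
            raise ValueError("weights must be positive, one per record")

    if prior.model == "RKHS":
        K = build_kernel(Xv, prior.kernel, prior.bandwidth, grm=grm)
        lam, V = np.linalg.eigh(K)
        keep = lam > 1e-8 * lam.max()
        lam, V = lam[keep], V[:, keep]
        design = np.asfortranarray(V)
        p_eff = design.shape[1]
    else:
        design = np.asfortranarray(Xv)
        p_eff = design.shape[1]

    var_y = float(np.var(y, ddof=1)) if n > 1 else 1.0
    if var_y == 0.0:
        var_y = 1e-8
    S_b, S_e = _prior_scales(var_y, max(p_eff, 1), prior)
    if prior.model == "RKHS":
        # prior mode of sigma2_u targets r2_prior * var(y) on the kernel scale
        mean_diag = float(np.mean(np.sum(V ** 2 * lam, axis=1)))  # mean diag(K)
        S_b = var_y * prior.r2_prior / max(mean_diag, 1e-8) * (prior.df0 + 2.0)

    rng = np.random.default_rng(mcmc.seed)
    _samplers.seed_rng(int(rng.integers(0, 2**31 - 1)))

    # BayesA: the per-marker variance scale is itself unknown, with a Gamma
    # prior whose mode sits at the r2-derived value; its Gibbs update lets
    # the model adapt the overall shrinkage (BayesB/C adapt through pi, so
    # their slab scale stays fixed to keep pi identifiable)
    adapt_scale = prior.model == "BayesA" and prior.fixed_sigma2_b is None
    shape0 = 1.1
    rate0 = (shape0 - 1.0) / S_b if S_b > 0 else 1.0

    mu = float(np.average(y, weights=w))
    b = np.zeros(p_eff)
    delta = np.ones(p_eff, dtype=np.int64)
    sigma2_e = prior.fixed_sigma2_e if prior.fixed_sigma2_e is not None \
        else var_y * (1.0 - prior.r2_prior)
    sigma2_e = max(sigma2_e, _VAR_FLOOR)
    if prior.fixed_sigma2_b is not None:
        base_var = prior.fixed_sigma2_b
    else:
        base_var = S_b / (prior.df0 + 2.0)
    var_b = np.full(p_eff, max(base_var, _VAR_FLOOR))
    if prior.model == "RKHS":
        sigma2_u = max(base_var, _VAR_FLOOR)
        var_b = lam * sigma2_u
    pi = prior.fixed_pi if prior.fixed_pi is not None else prior.pi0
    a0 = prior.pi0 * prior.pi_counts
    b0 = (1.0 - prior.pi0) * prior.pi_counts
    spike_slab = prior.model in ("BayesB", "BayesC")

    r = y - mu - design @ b
    tau = w / sigma2_e

    n_ret = mcmc.n_retained
    b_sum = np.zeros(p_eff)
    incl_sum = np.zeros(p_eff)
    mu_sum = 0.0
    s2e_chain = np.empty(n_ret)
    s2b_chain = np.empty(n_ret)
    varg_chain = np.empty(n_ret)
    pi_chain = np.empty(n_ret) if spike_slab else None
    dev_chain = np.empty(n_ret)
    log_w = float(np.sum(np.log(w)))
    kept = 0

    for it in range(1, mcmc.n_iter + 1):
        # intercept (flat prior)
        prec_mu = tau.sum()
        mu_new = mu + r @ tau / prec_mu + rng.normal() / np.sqrt(prec_mu)
        r -= mu_new - mu
        mu = mu_new

        # coefficients
        if spike_slab:
            logit_pi = np.log(pi / (1.0 - pi))
            n_in = _samplers.sweep_spike_slab(design, r, b, delta, tau, var_b, logit_pi)
        else:
            _samplers.sweep_gaussian(design, r, b, tau, var_b)
            n_in = p_eff

        # marker / kernel variances
        if prior.fixed_sigma2_b is None:
            if prior.model == "BRR":
                s2 = (S_b + b @ b) / rng.chisquare(prior.df0 + p_eff)
                var_b[:] = max(s2, _VAR_FLOOR)
            elif prior.model == "BayesA":
                var_b[:] = np.maximum(
                    (S_b + b ** 2) / rng.chisquare(prior.df0 + 1.0, size=p_eff),
                    _VAR_FLOOR)
            elif prior.model == "BayesB":
                df_k = prior.df0 + delta
                var_b[:] = np.maximum(
                    (S_b + b ** 2) / rng.chisquare(df_k),
                    _VAR_FLOOR)
            elif prior.model == "BayesC":
                bsq = float(b @ b)
                s2 = (S_b + bsq) / rng.chisquare(prior.df0 + n_in)
                var_b[:] = max(s2, _VAR_FLOOR)
            elif prior.model == "RKHS":
                ss = float(np.sum(b ** 2 / lam))
                sigma2_u = max((S_b + ss) / rng.chisquare(prior.df0 + p_eff),
                               _VAR_FLOOR)
                var_b = lam * sigma2_u

        # adapt the scaled-inv-chi2 scale (BayesA/B)
        if adapt_scale:
            S_b = rng.gamma(shape0 + 0.5 * p_eff * prior.df0,
                            1.0 / (rate0 + 0.5 * float(np.sum(1.0 / var_b))))
            S_b = max(S_b, _VAR_FLOOR)

        # nonnull proportion
        if spike_slab and prior.fixed_pi is None:
            pi = rng.beta(a0 + n_in, b0 + (p_eff - n_in))
            pi = min(max(pi, 1e-6), 1.0 - 1e-6)

        # residual variance
        if prior.fixed_sigma2_e is None:
            sse = float(np.sum(w * r ** 2))
            sigma2_e = max((S_e + sse) / rng.chisquare(prior.df0 + n), _VAR_FLOOR)
        tau = w / sigma2_e

        if not (np.isfinite(sigma2_e) and np.isfinite(b).all()):
            raise FloatingPointError(f"divergent chain at iteration {it}")

        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            b_sum += b
            incl_sum += delta
            mu_sum += mu
            s2e_chain[kept] = sigma2_e
            s2b_chain[kept] = sigma2_u if prior.model == "RKHS" else float(var_b.mean())
            if spike_slab:
                pi_chain[kept] = pi
            # current-draw genomic values from the running residual: y - mu - r
            gv = y - mu - r
            varg_chain[kept] = gv.var(ddof=1) if n > 1 else 0.0
            # conditional Gaussian deviance given current state
            dev_chain[kept] = (n * np.log(2.0 * np.pi * sigma2_e) - log_w
                               + float(np.sum(w * r ** 2)) / sigma2_e)
            kept += 1

    if kept == 0:
        raise ValueError("no retained draws; lengthen the chain")
    b_hat = b_sum / kept
    mu_hat = mu_sum / kept
    incl = incl_sum / kept if spike_slab else None
    s2e_chain, s2b_chain, dev_chain = s2e_chain[:kept], s2b_chain[:kept], dev_chain[:kept]
    varg_chain = varg_chain[:kept]
    if pi_chain is not None:
        pi_chain = pi_chain[:kept]
    sigma2_e_hat = float(s2e_chain.mean())

    if prior.model == "RKHS":
        u_hat = design @ b_hat
        alpha_hat = (design / lam) @ b_hat  # V diag(1/lam) delta = K^{-1} u
        gebv = u_hat
        b_out = np.zeros(0)
    else:
        u_hat = alpha_hat = None
        gebv = design @ b_hat
        b_out = b_hat

    resid_hat = y - mu_hat - gebv
    d_at_mean = (n * np.log(2.0 * np.pi * sigma2_e_hat) - log_w
                 + float(np.sum(w * resid_hat ** 2)) / sigma2_e_hat)
    dic, d_bar, p_d = compute_dic(dev_chain, d_at_mean)

    chains = {"sigma2_e": s2e_chain, "sigma2_b": s2b_chain, "deviance": dev_chain,
              "var_g": varg_chain}
    if pi_chain is not None:
        chains["pi"] = pi_chain

    return FitResult(
        model=prior.model,
        mu_hat=float(mu_hat),
        b_hat=b_out,
        gebv=gebv,
        sigma2_e_hat=sigma2_e_hat,
        sigma2_e_sd=float(s2e_chain.std(ddof=1)) if kept > 1 else 0.0,
        dic=dic, d_bar=d_bar, p_d=p_d,
        h2_implied=float(varg_chain.mean() / var_y),
        inclusion_prob=incl,
        pi_hat=float(pi_chain.mean()) if pi_chain is not None else None,
        pi_sd=float(pi_chain.std(ddof=1)) if pi_chain is not None and kept > 1 else None,
        sigma2_b_hat=float(s2b_chain.mean()),
        sigma2_u_hat=float(s2b_chain.mean()) if prior.model == "RKHS" else None,
        u_hat=u_hat,
        alpha_hat=alpha_hat,
        chains=chains,
        settings={"prior": asdict(prior), "mcmc": asdict(mcmc)},
        marker_ids=list(marker_ids),
        line_ids=list(line_ids),
    )


def compute_dic(deviance_chain: np.ndarray,
                deviance_at_posterior_mean: float) -> tuple[float, float, float]:
    """DIC = D_bar + p_D with p_D = D_bar - D(theta_bar)."""
    dev = np.asarray(deviance_chain, dtype=float)
    if dev.size < 2:
        raise ValueError("need at least 2 retained deviance draws")
    d_bar = float(dev.mean())
    p_d = d_bar - float(deviance_at_posterior_mean)
    return d_bar + p_d, d_bar, p_d


def nonnull_proportion(fit: FitResult) -> float:
    """Posterior mean proportion of markers with nonnull effects.

    Defined only for the variable-selection priors (BayesB/BayesC), whose
    samplers carry explicit inclusion indicators.
    """
    if fit.pi_hat is None or "pi" not in fit.chains:
        raise ValueError(
            f"nonnull proportion undefined for model {fit.model!r}: "
            "no inclusion indicators (use BayesB or BayesC)"
        )
    return float(fit.pi_hat)


def predict_gebv(fit: FitResult, X_new: StandardizedMatrix | np.ndarray,
                 K_new_train: np.ndarray | None = None) -> np.ndarray:
    """Predict genomic values for new lines.

    Marker models require ``X_new`` standardized with the *training*
    column means/SDs and identical marker order.  Kernel (RKHS) models
    require ``K_new_train``, the kernel between new and training lines.
    """
    if fit.model == "RKHS":
        if K_new_train is None:
            raise ValueError("RKHS prediction requires K(new, train)")
        return np.asarray(K_new_train) @ fit.alpha_hat
    if isinstance(X_new, StandardizedMatrix):
        if fit.marker_ids and list(X_new.marker_ids) != list(fit.marker_ids):
            pairs = zip(X_new.marker_ids, fit.marker_ids)
            first = next(((a, b) for a, b in pairs if a != b), ("length", "mismatch"))
            raise ValueError(f"marker mismatch: got {first[0]!r}, expected {first[1]!r}")
        Xv = X_new.X
    else:
        Xv = np.asarray(X_new, dtype=float)
    if Xv.shape[1] != fit.b_hat.shape[0]:
        raise ValueError("marker count mismatch with fitted effects")
    return Xv @ fit.b_hat


def save_fit(fit: FitResult, outdir: str | Path) -> None:
    """Serialize a FitResult: effects.csv, chains.csv, summary.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eff = pd.DataFrame({
        "marker": fit.marker_ids if fit.marker_ids else np.arange(fit.b_hat.size),
        "b_hat": fit.b_hat,
    })
    if fit.inclusion_prob is not None:
        eff["inclusion_prob"] = fit.inclusion_prob
    eff.to_csv(outdir / "effects.csv", index=False)
    pd.DataFrame(fit.chains).to_csv(outdir / "chains.csv", index=False)
    summary = {
        "model": fit.model,
        "mu_hat": fit.mu_hat,
        "sigma2_e_hat": fit.sigma2_e_hat,
        "sigma2_e_sd": fit.sigma2_e_sd,
        "dic": fit.dic, "d_bar": fit.d_bar, "p_d": fit.p_d,
        "pi_hat": fit.pi_hat,
        "settings": fit.settings,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    pd.DataFrame({"line": fit.line_ids if fit.line_ids else np.arange(fit.gebv.size),
                  "gebv": fit.gebv}).to_csv(outdir / "gebv.csv", index=False)
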