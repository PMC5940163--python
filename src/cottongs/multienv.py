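"""Multi-site genomic prediction: single-site, across-site and M x E models.

Stacked data over J sites are modeled as

    y_j = 1 mu_j + X_j (b0 + b_j) + e_j,   e_j ~ N(0, I sigma2_e[j])

with heterogeneous per-site residual variances (D = diag(sigma2_e1..J)):

* single-site  — b0 = 0, independent fits per site (each its own b_j);
* across-site  — b_j = 0, one shared marker-effect vector b0;
* M x E        — both components: a main effect per marker plus per-site
  deviations, each with its own prior (and, under BayesB, its own nonnull
  proportion pi).

The joint samplers condition on observed (line, site) cells only, so
unbalanced designs and CV2-style masking work unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _samplers
from .data_io import PhenotypeTable, StandardizedMatrix
from .wgr import (MCMCSettings, PriorSpec, FitResult, fit_wgr, compute_dic,
                  _VAR_FLOOR, _prior_scales)

__all__ = [
    "MultiEnvData",
    "MxEFitResult",
    "fit_single_site_all",
    "fit_across_site",
    "fit_mxe",
    "site_correlations",
    "save_mxe_fit",
]


@dataclass
class MultiEnvData:
    """Stacked multi-site records over a shared standardized marker matrix.

    Records are stored sorted by site so each site occupies a contiguous
    block (the samplers rely on this).
    """

    sites: list[str]
    y_stacked: np.ndarray       # (n_records,)
    site_index: np.ndarray      # (n_records,) int, index into sites
    line_index: np.ndarray      # (n_records,) int, row index into X
    X: StandardizedMatrix       # union of lines

    def __post_init__(self) -> None:
        self.y_stacked = np.asarray(self.y_stacked, dtype=float)
        self.site_index = np.asarray(self.site_index, dtype=np.int64)
        self.line_index = np.asarray(self.line_index, dtype=np.int64)
        n = self.y_stacked.shape[0]
        if self.site_index.shape != (n,) or self.line_index.shape != (n,):
            raise ValueError("record index arrays must match y_stacked")
        if n and (self.site_index.min() < 0
                  or self.site_index.max() >= len(self.sites)):
            raise ValueError("site_index out of range")
        if n and (self.line_index.min() < 0
                  or self.line_index.max() >= self.X.n_lines):
            raise ValueError("line_index out of range")
        for s in range(len(self.sites)):
            lines = self.line_index[self.site_index == s]
            if len(np.unique(lines)) != len(lines):
                raise ValueError(f"line repeated within site {self.sites[s]!r}")
        order = np.argsort(self.site_index, kind="stable")
        self.y_stacked = self.y_stacked[order]
        self.site_index = self.site_index[order]
        self.line_index = self.line_index[order]

    @classmethod
    def from_tables(cls, phenotypes: PhenotypeTable, X: StandardizedMatrix,
                    trait: str, sites: list[str] | None = None) -> "MultiEnvData":
        rec = phenotypes.records
        rec = rec[rec["trait"] == trait]
        if sites is None:
            sites = sorted(rec["site"].unique())
        rec = rec[rec["site"].isin(sites)]
        line_pos = {l: i for i, l in enumerate(X.line_ids)}
        missing = set(rec["line"]) - set(line_pos)
        if missing:
            raise ValueError(f"phenotyped lines without genotypes: {sorted(missing)[:5]}")
        site_pos = {s: j for j, s in enumerate(sites)}
        return cls(
            sites=list(sites),
            y_stacked=rec["mean"].to_numpy(float),
            site_index=np.array([site_pos[s] for s in rec["site"]]),
            line_index=np.array([line_pos[l] for l in rec["line"]]),
            X=X,
        )

    @property
    def n_records(self) -> int:
        return self.y_stacked.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_records(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.site_index == j)

    def subset(self, record_mask: np.ndarray) -> "MultiEnvData":
        m = np.asarray(record_mask, dtype=bool)
        return MultiEnvData(list(self.sites), self.y_stacked[m],
                            self.site_index[m], self.line_index[m], self.X)

    def cells(self) -> pd.DataFrame:
        """One row per observed (line, site) cell."""
        return pd.DataFrame({
            "line": [self.X.line_ids[i] for i in self.line_index],
            "site": [self.sites[j] for j in self.site_index],
            "line_index": self.line_index,
            "site_index": self.site_index,
            "y": self.y_stacked,
        })


@dataclass
class MxEFitResult:
    """Posterior summaries from a joint multi-site fit.

    ``gebv_site[l, j] = X_l . (b0_hat + b_site_hat[j])`` excludes the site
    intercepts mu_site (correlation-based accuracy is location-invariant);
    add ``mu_site[j]`` for predictions on the trait scale.
    """

    model_class: str                    # 'across_site' or 'mxe'
    sites: list[str]
    b0_hat: np.ndarray                  # (p,) main marker effects
    b_site_hat: np.ndarray              # (J, p) site deviations (0 for across-site)
    mu_site: np.ndarray                 # (J,)
    sigma2_e_site: np.ndarray           # (J,)
    sigma2_e_site_sd: np.ndarray        # (J,)
    pi_main: float | None
    pi_site: np.ndarray | None          # (J,)
    gebv_site: np.ndarray               # (n_lines_union, J)
    dic: float
    d_bar: float
    p_d: float
    inclusion_main: np.ndarray | None = None
    chains: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)


def fit_single_site_all(data: MultiEnvData, prior: PriorSpec,
                        mcmc: MCMCSettings) -> dict[str, FitResult]:
    """Independent single-site fits (shared marker matrix, own mu_j, b_j,
    sigma2_ej); delegates to :func:`cottongs.wgr.fit_wgr` per site."""
    import warnings
    out: dict[str, FitResult] = {}
    for j, site in enumerate(data.sites):
        rows = data.site_records(j)
        if rows.size == 0:
            raise ValueError(f"site {site!r} has no records")
        if rows.size < 10:
            warnings.warn(f"site {site!r} has only {rows.size} records")
        Xj = StandardizedMatrix(
            data.X.X[data.line_index[rows]], data.X.col_means, data.X.col_sds,
            [data.X.line_ids[i] for i in data.line_index[rows]],
            list(data.X.marker_ids))
        site_mcmc = MCMCSettings(mcmc.n_iter, mcmc.burn_in, mcmc.thin,
                                 seed=mcmc.seed + j, n_chains=mcmc.n_chains)
        out[site] = fit_wgr(data.y_stacked[rows], Xj, prior, site_mcmc)
    return out


def fit_across_site(data: MultiEnvData, prior: PriorSpec,
                    mcmc: MCMCSettings) -> MxEFitResult:
    """Shared marker effects across sites with per-site intercepts and
    heterogeneous residual variances (b_j = 0)."""
    if data.n_sites < 2:
        raise ValueError("across-site model needs >= 2 sites; use the single-site path")
    return _fit_stacked(data, prior, mcmc, site_effects=False)


def fit_mxe(data: MultiEnvData, prior: PriorSpec, mcmc: MCMCSettings,
            fixed_var_site: float | None = None) -> MxEFitResult:
    """Marker main effects plus per-site deviations, each with its own prior.

    ``fixed_var_site`` pins the site-deviation prior variance (Gaussian
    component); near zero this collapses the model onto the across-site fit.
    """
    if data.n_sites < 2:
        raise ValueError("M x E model needs >= 2 sites")
    _check_connectivity(data)
    return _fit_stacked(data, prior, mcmc, site_effects=True,
                        fixed_var_site=fixed_var_site)


def _check_connectivity(data: MultiEnvData) -> None:
    line_sets = [set(data.line_index[data.site_records(j)])
                 for j in range(data.n_sites)]
    for j, s in enumerate(line_sets):
        if not any(s & t for i, t in enumerate(line_sets) if i != j):
            raise ValueError(
                f"site {data.sites[j]!r} shares no lines with any other site; "
                "interaction effects are unidentifiable")


def _fit_stacked(data: MultiEnvData, prior: PriorSpec, mcmc: MCMCSettings,
                 site_effects: bool, fixed_var_site: float | None = None
                 ) -> MxEFitResult:
    J = data.n_sites
    n = data.n_records
    p = data.X.n_markers
    y = data.y_stacked
    Xs = np.asfortranarray(data.X.X[data.line_index])  # records x markers
    blocks = [data.site_records(j) for j in range(J)]
    n_j = np.array([b.size for b in blocks])
    if (n_j == 0).any():
        raise ValueError("every site needs at least one record")
    # contiguity of site blocks (guaranteed by the sorted constructor)
    Xb = [np.asfortranarray(Xs[b]) for b in blocks]

    spike_slab = prior.model in ("BayesB", "BayesC")
    gaussian_site = fixed_var_site is not None
    var_y = float(np.var(y, ddof=1)) if n > 1 else 1.0
    # split the prior marker share of variance between main and site terms
    r2_main = prior.r2_prior * (0.5 if site_effects else 1.0)
    r2_site = prior.r2_prior * 0.5
    main_prior = PriorSpec(prior.model, r2_main, prior.df0, prior.pi0,
                           prior.pi_counts)
    S_b0, _ = _prior_scales(var_y, p, main_prior)
    site_prior = PriorSpec(prior.model, r2_site, prior.df0, prior.pi0,
                           prior.pi_counts)
    S_bj, _ = _prior_scales(var_y, p, site_prior)
    S_e = var_y * (1.0 - prior.r2_prior) * (prior.df0 + 2.0)

    rng = np.random.default_rng(mcmc.seed)
    _samplers.seed_rng(int(rng.integers(0, 2**31 - 1)))

    mu = np.array([float(y[b].mean()) for b in blocks])
    b0 = np.zeros(p)
    d0 = np.ones(p, dtype=np.int64)
    bj = np.zeros((J, p))
    dj = np.ones((J, p), dtype=np.int64)
    s2e = np.full(J, max(var_y * (1.0 - prior.r2_prior), _VAR_FLOOR))
    var_b0 = np.full(p, max(S_b0 / (prior.df0 + 2.0), _VAR_FLOOR))
    if gaussian_site:
        var_bj = [np.full(p, max(fixed_var_site, _VAR_FLOOR)) for _ in range(J)]
    else:
        var_bj = [np.full(p, max(S_bj / (prior.df0 + 2.0), _VAR_FLOOR))
                  for _ in range(J)]
    pi_main = prior.pi0
    pi_site = np.full(J, prior.pi0)
    a0 = prior.pi0 * prior.pi_counts
    c0 = (1.0 - prior.pi0) * prior.pi_counts

    r = y - mu[data.site_index]
    if site_effects:
        pass  # bj starts at zero
    tau = 1.0 / s2e[data.site_index]

    n_ret = mcmc.n_retained
    b0_sum = np.zeros(p)
    incl0_sum = np.zeros(p)
    bj_sum = np.zeros((J, p))
    mu_sum = np.zeros(J)
    s2e_chain = np.empty((n_ret, J))
    pi_main_chain = np.empty(n_ret)
    pi_site_chain = np.empty((n_ret, J))
    dev_chain = np.empty(n_ret)
    kept = 0

    for it in range(1, mcmc.n_iter + 1):
        # per-site intercepts
        for j, rows in enumerate(blocks):
            prec = n_j[j] / s2e[j]
            shift = float(r[rows].sum()) / s2e[j] / prec + rng.normal() / np.sqrt(prec)
            mu[j] += shift
            r[rows] -= shift

        # main effects (pooled over sites)
        if spike_slab:
            n_in0 = _samplers.sweep_spike_slab(
                Xs, r, b0, d0, tau, var_b0, np.log(pi_main / (1.0 - pi_main)))
        else:
            _samplers.sweep_gaussian(Xs, r, b0, tau, var_b0)
            n_in0 = p

        # site-specific deviations
        n_in_j = np.zeros(J, dtype=int)
        if site_effects:
            for j, rows in enumerate(blocks):
                rj = np.ascontiguousarray(r[rows])
                tj = np.full(rows.size, 1.0 / s2e[j])
                if spike_slab and not gaussian_site:
                    n_in_j[j] = _samplers.sweep_spike_slab(
                        Xb[j], rj, bj[j], dj[j], tj, var_bj[j],
                        np.log(pi_site[j] / (1.0 - pi_site[j])))
                else:
                    _samplers.sweep_gaussian(Xb[j], rj, bj[j], tj, var_bj[j])
                    n_in_j[j] = p
                r[rows] = rj

        # variance components and pi
        if prior.model == "BRR":
            var_b0[:] = max((S_b0 + b0 @ b0) / rng.chisquare(prior.df0 + p), _VAR_FLOOR)
        elif prior.model == "BayesA":
            var_b0[:] = np.maximum((S_b0 + b0 ** 2)
                                   / rng.chisquare(prior.df0 + 1.0, size=p), _VAR_FLOOR)
        elif prior.model == "BayesB":
            var_b0[:] = np.maximum((S_b0 + b0 ** 2)
                                   / rng.chisquare(prior.df0 + d0), _VAR_FLOOR)
        elif prior.model == "BayesC":
            var_b0[:] = max((S_b0 + float(b0 @ b0))
                            / rng.chisquare(prior.df0 + n_in0), _VAR_FLOOR)
        if spike_slab:
            pi_main = float(np.clip(rng.beta(a0 + n_in0, c0 + p - n_in0),
                                    1e-6, 1 - 1e-6))
        if site_effects and not gaussian_site:
            for j in range(J):
                if prior.model == "BRR":
                    var_bj[j][:] = max((S_bj + bj[j] @ bj[j])
                                       / rng.chisquare(prior.df0 + p), _VAR_FLOOR)
                elif prior.model == "BayesA":
                    var_bj[j][:] = np.maximum(
                        (S_bj + bj[j] ** 2) / rng.chisquare(prior.df0 + 1.0, size=p),
                        _VAR_FLOOR)
                elif prior.model == "BayesB":
                    var_bj[j][:] = np.maximum(
                        (S_bj + bj[j] ** 2) / rng.chisquare(prior.df0 + dj[j]),
                        _VAR_FLOOR)
                elif prior.model == "BayesC":
                    var_bj[j][:] = max(
                        (S_bj + float(bj[j] @ bj[j]))
                        / rng.chisquare(prior.df0 + n_in_j[j]), _VAR_FLOOR)
                if spike_slab:
                    pi_site[j] = np.clip(
                        rng.beta(a0 + n_in_j[j], c0 + p - n_in_j[j]),
                        1e-6, 1 - 1e-6)

        # per-site residual variances (scaled-inv-chi2)
        for j, rows in enumerate(blocks):
            sse = float(np.sum(r[rows] ** 2))
            s2e[j] = max((S_e + sse) / rng.chisquare(prior.df0 + n_j[j]), _VAR_FLOOR)
        tau = 1.0 / s2e[data.site_index]

        if not (np.isfinite(s2e).all() and np.isfinite(b0).all()):
            raise FloatingPointError(f"divergent chain at iteration {it}")

        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            b0_sum += b0
            incl0_sum += d0
            bj_sum += bj
            mu_sum += mu
            s2e_chain[kept] = s2e
            pi_main_chain[kept] = pi_main
            pi_site_chain[kept] = pi_site
            dev_chain[kept] = float(
                np.sum(n_j * np.log(2.0 * np.pi * s2e))
                + np.sum(r ** 2 / s2e[data.site_index]))
            kept += 1

    if kept == 0:
        raise ValueError("no retained draws; lengthen the chain")
    b0_hat = b0_sum / kept
    bj_hat = bj_sum / kept
    mu_hat = mu_sum / kept
    s2e_chain = s2e_chain[:kept]
    pi_main_chain = pi_main_chain[:kept]
    pi_site_chain = pi_site_chain[:kept]
    dev_chain = dev_chain[:kept]
    s2e_hat = s2e_chain.mean(axis=0)

    gebv_site = data.X.X @ (b0_hat[None, :] + bj_hat).T  # lines x sites
    fitted = (mu_hat[data.site_index]
              + gebv_site[data.line_index, data.site_index])
    resid = y - fitted
    d_at_mean = float(np.sum(n_j * np.log(2.0 * np.pi * s2e_hat))
                      + np.sum(resid ** 2 / s2e_hat[data.site_index]))
    dic, d_bar, p_d = compute_dic(dev_chain, d_at_mean)

    return MxEFitResult(
        model_class="mxe" if site_effects else "across_site",
        sites=list(data.sites),
        b0_hat=b0_hat,
        b_site_hat=bj_hat,
        mu_site=mu_hat,
        sigma2_e_site=s2e_hat,
        sigma2_e_site_sd=s2e_chain.std(axis=0, ddof=1),
        pi_main=float(pi_main_chain.mean()) if spike_slab else None,
        pi_site=(pi_site_chain.mean(axis=0)
                 if spike_slab and site_effects and not gaussian_site else None),
        gebv_site=gebv_site,
        dic=dic, d_bar=d_bar, p_d=p_d,
        inclusion_main=incl0_sum / kept if spike_slab else None,
        chains={"sigma2_e_site": s2e_chain, "pi_main": pi_main_chain,
                "pi_site": pi_site_chain, "deviance": dev_chain},
        settings={"prior": asdict(prior), "mcmc": asdict(mcmc),
                  "site_effects": site_effects},
    )


def site_correlations(data: MultiEnvData, min_common: int = 3
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of adjusted means between sites over common lines.

    Returns (r, se) DataFrames; SE = sqrt((1 - r^2) / (n - 2)).  Pairs with
    fewer than ``min_common`` shared lines are NaN.
    """
    J = data.n_sites
    r_mat = np.full((J, J), np.nan)
    se_mat = np.full((J, J), np.nan)
    per_site = {}
    for j in range(J):
        rows = data.site_records(j)
        per_site[j] = dict(zip(data.line_index[rows], data.y_stacked[rows]))
    for a in range(J):
        r_mat[a, a] = 1.0
        se_mat[a, a] = 0.0
        for b in range(a + 1, J):
            common = sorted(set(per_site[a]) & set(per_site[b]))
            if len(common) < min_common:
                continue
            ya = np.array([per_site[a][l] for l in common])
            yb = np.array([per_site[b][l] for l in common])
            if ya.std() == 0 or yb.std() == 0:
                continue
            rr = float(np.corrcoef(ya, yb)[0, 1])
            nn = len(common)
            r_mat[a, b] = r_mat[b, a] = rr
            se_mat[a, b] = se_mat[b, a] = np.sqrt(max(1.0 - rr ** 2, 0.0) / (nn - 2))
    r_df = pd.DataFrame(r_mat, index=data.sites, columns=data.sites)
    se_df = pd.DataFrame(se_mat, index=data.sites, columns=data.sites)
    return r_df, se_df


def save_mxe_fit(fit: MxEFitResult, outdir: str | Path) -> None:
    import json
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"marker": np.arange(fit.b0_hat.size), "b0_hat": fit.b0_hat}
                 ).to_csv(outdir / "main_effects.csv", index=False)
    for j, site in enumerate(fit.sites):
        pd.DataFrame({"marker": np.arange(fit.b0_hat.size),
                      "b_hat": fit.b_site_hat[j]}
                     ).to_csv(outdir / f"site_effects_{site}.csv", index=False)
    pd.DataFrame({"site": fit.sites, "sigma2_e": fit.sigma2_e_site,
                  "sd": fit.sigma2_e_site_sd}
                 ).to_csv(outdir / "variances.csv", index=False)
    rows = []
    if fit.pi_main is not None:
        rows.append(("main", fit.pi_main))
    if fit.pi_site is not None:
        rows += [(s, v) for s, v in zip(fit.sites, fit.pi_site)]
    pd.DataFrame(rows, columns=["component", "estimate"]
                 ).to_csv(outdir / "pi.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(fit.settings, indent=2))
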