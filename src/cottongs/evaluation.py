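"""Prediction-accuracy evaluation: TRN/TST partitions, CV1/CV2, accuracy,
bias and coincidence-index selection efficiency.

Accuracy is the Pearson correlation between predictions and observed
adjusted means, optionally divided by sqrt(h2) of the trait at that site
(the correlation with the phenotype understates the correlation with the
true breeding value by that factor).  Bias is the OLS slope of predicted
on observed values: slope >= 1 means no bias, < 1 biased overestimation.

The coincidence index chance-corrects the overlap between the top
``intensity`` fractions of two rankings:

    efficiency = (c - chance) / (n_sel - chance) * 100

with n_sel = round(intensity * n), chance = round(intensity * n_sel), and
c the number of coincident selections; e.g. with 116 lines at 20%
intensity, n_sel = 23, chance = 5, and c = 10 gives 28%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .multienv import (MultiEnvData, fit_across_site, fit_mxe,
                       fit_single_site_all)
from .wgr import MCMCSettings, PriorSpec
from .data_io import StandardizedMatrix

__all__ = [
    "PartitionScheme",
    "EvaluationReport",
    "make_partitions",
    "prediction_accuracy",
    "bias_slope",
    "selection_efficiency",
    "evaluate",
    "default_model_factories",
]

SCHEMES = ("single_site_random", "cv1", "cv2")


@dataclass
class PartitionScheme:
    """Replicated TRN/TST assignments.

    For line-level schemes (``single_site_random``, ``cv1``) ``masks`` is
    (n_reps, n_lines) boolean, True = training line.  For ``cv2`` it is
    (n_reps, n_cells) over the supplied cell table, True = training cell.
    """

    scheme: str
    n_reps: int
    frac_train: float
    seed: int
    masks: np.ndarray
    cell_table: pd.DataFrame | None = None  # cv2: (line, site) per column index


def make_partitions(n_lines: int | None = None, scheme: str = "single_site_random",
                    n_reps: int = 50, frac_train: float = 0.70, seed: int = 0,
                    cells: pd.DataFrame | None = None) -> PartitionScheme:
    """Generate seeded TRN/TST partitions.

    ``single_site_random`` and ``cv1`` assign whole lines to TRN or TST
    (CV1: a TST line is unobserved everywhere).  ``cv2`` masks individual
    (line, site) cells from the availability table ``cells`` (columns
    ``line``, ``site``) such that every TST line keeps at least one
    training site; site-level masking is balanced to within 5 percentage
    points of 1 - frac_train.
    """
    if not 0.0 < frac_train < 1.0:
        raise ValueError("frac_train must lie in (0, 1)")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    rng = np.random.default_rng(seed)

    if scheme in ("single_site_random", "cv1"):
        if n_lines is None:
            if cells is None:
                raise ValueError("need n_lines or a cell table")
            n_lines = cells["line"].nunique()
        if n_lines < 5:
            raise ValueError("need at least 5 lines")
        n_trn = int(round(frac_train * n_lines))
        n_trn = min(max(n_trn, 1), n_lines - 1)
        masks = np.zeros((n_reps, n_lines), dtype=bool)
        for r in range(n_reps):
            trn = rng.choice(n_lines, size=n_trn, replace=False)
            masks[r, trn] = True
        return PartitionScheme(scheme, n_reps, frac_train, seed, masks)

    if cells is None:
        raise ValueError("cv2 requires a (line, site) availability table")
    cells = cells.reset_index(drop=True)
    n_cells = len(cells)
    lines = cells["line"].to_numpy()
    sites = cells["site"].to_numpy()
    uniq_sites = pd.unique(sites)
    frac_mask = 1.0 - frac_train
    line_rows: dict = {l: np.flatnonzero(lines == l) for l in pd.unique(lines)}
    site_rows = {s: np.flatnonzero(sites == s) for s in uniq_sites}
    masks = np.zeros((n_reps, n_cells), dtype=bool)
    for r in range(n_reps):
        for _ in range(200):  # redraw until site balance holds
            tst = rng.random(n_cells) < frac_mask
            for l, rows in line_rows.items():
                if tst[rows].all():  # every line keeps >= 1 training site
                    keep = rng.choice(rows)
                    tst[keep] = False
            ok = all(abs(tst[rw].mean() - frac_mask) <= 0.05
                     for rw in site_rows.values())
            if ok:
                break
        masks[r] = ~tst
    return PartitionScheme(scheme, n_reps, frac_train, seed, masks,
                           cell_table=cells[["line", "site"]].copy())


def prediction_accuracy(predicted: np.ndarray, observed: np.ndarray,
                        h2: float = 1.0) -> tuple[float, float]:
    """(scaled accuracy, raw correlation) = (corr / sqrt(h2), corr).

    Returns (nan, nan) if either vector has zero variance (flagged missing
    rather than propagating a NaN correlation).
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("need equal-length vectors of >= 3 values")
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    if predicted.std() == 0.0 or observed.std() == 0.0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(predicted, observed)[0, 1])
    acc = r / np.sqrt(h2)
    if abs(acc) > 1.0:
        warnings.warn(f"scaled accuracy {acc:.3f} exceeds 1; reported as computed")
    return acc, r


def bias_slope(gebv_validation: np.ndarray, ebv: np.ndarray) -> float:
    """OLS slope of predicted genomic values on observed (E)BVs."""
    g = np.asarray(gebv_validation, float)
    e = np.asarray(ebv, float)
    if g.shape != e.shape or g.size < 3:
        raise ValueError("need equal-length vectors of >= 3 values")
    ve = e.var()
    if ve == 0.0:
        raise ValueError("degenerate EBV vector (zero variance)")
    return float(np.cov(g, e, ddof=0)[0, 1] / ve)


def selection_efficiency(scores_a: np.ndarray, scores_b: np.ndarray,
                         intensity: float = 0.20, higher_is_better: bool = True
                         ) -> float:
    """Coincidence-index selection efficiency (%) between two rankings.

    Chance-corrected overlap of the top ``intensity`` fractions; floored
    at 0 when the overlap does not beat chance.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need the same line set with >= 5 lines")
    n = a.size
    n_sel = int(round(intensity * n))
    chance = int(round(intensity * n_sel))
    if n_sel <= chance:
        raise ValueError(f"degenerate intensity: n_sel={n_sel} <= chance={chance}")
    sgn = -1.0 if higher_is_better else 1.0
    top_a = set(np.argsort(sgn * a, kind="stable")[:n_sel])
    top_b = set(np.argsort(sgn * b, kind="stable")[:n_sel])
    c = len(top_a & top_b)
    return max((c - chance) / (n_sel - chance) * 100.0, 0.0)


def coincidence_from_counts(n: int, coincident: int, intensity: float = 0.20
                            ) -> float:
    """Selection efficiency (%) directly from counts (n lines, c coincident)."""
    n_sel = int(round(intensity * n))
    chance = int(round(intensity * n_sel))
    if n_sel <= chance:
        raise ValueError(f"degenerate intensity: n_sel={n_sel} <= chance={chance}")
    return max((coincident - chance) / (n_sel - chance) * 100.0, 0.0)


# ---------------------------------------------------------------------------
# full evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-rep rows plus aggregates; SE of the mean = SD / sqrt(n_reps)."""

    per_rep: pd.DataFrame        # site, model, scheme, rep, corr, accuracy, bias
    summary: pd.DataFrame        # site, model, scheme, mean/se per statistic
    selection: pd.DataFrame      # model_a, model_b, site, efficiency_pct
    scheme: str
    h2_per_site: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    @staticmethod
    def aggregate(per_rep: pd.DataFrame) -> pd.DataFrame:
        g = per_rep.groupby(["site", "model", "scheme"], sort=True)
        out = g.agg(
            corr_mean=("corr", "mean"), corr_se=("corr", _sem),
            accuracy_mean=("accuracy", "mean"), accuracy_se=("accuracy", _sem),
            bias_mean=("bias", "mean"), bias_se=("bias", _sem),
            n_reps=("rep", "count"),
        ).reset_index()
        return out


def _sem(x: pd.Series) -> float:
    x = x.dropna()
    if len(x) < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(len(x)))


ModelFactory = Callable[[MultiEnvData], np.ndarray]


def default_model_factories(prior: PriorSpec, mcmc: MCMCSettings,
                            models: tuple[str, ...] = ("single_site",
                                                       "across_site", "mxe")
                            ) -> Mapping[str, ModelFactory]:
    """Factories mapping a training MultiEnvData to an (n_lines, n_sites)
    matrix of predicted genomic values (site intercepts excluded)."""

    def single_site(trn: MultiEnvData) -> np.ndarray:
        pred = np.full((trn.X.n_lines, trn.n_sites), np.nan)
        fits = fit_single_site_all(trn, prior, mcmc)
        for j, site in enumerate(trn.sites):
            pred[:, j] = trn.X.X @ fits[site].b_hat
        return pred

    def across_site(trn: MultiEnvData) -> np.ndarray:
        return fit_across_site(trn, prior, mcmc).gebv_site

    def mxe(trn: MultiEnvData) -> np.ndarray:
        return fit_mxe(trn, prior, mcmc).gebv_site

    table = {"single_site": single_site, "across_site": across_site, "mxe": mxe}
    unknown = set(models) - set(table)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}; valid: {sorted(table)}")
    return {m: table[m] for m in models}


def evaluate(models: Mapping[str, ModelFactory], data: MultiEnvData,
             partitions: PartitionScheme, h2_per_site: Mapping[str, float]
             | None = None, intensity: float = 0.20) -> EvaluationReport:
    """Run the replicated TRN/TST protocol.

    For every rep: refit each model on the training cells, predict the test
    cells, and record per-site raw correlation, h2-scaled accuracy and bias
    slope; aggregate mean +/- SE over reps and emit pairwise coincidence-
    index selection efficiencies between models (mean over reps, computed
    on each rep's per-site test lines).
    """
    h2_per_site = dict(h2_per_site or {})
    rows = []
    sel_acc: dict[tuple[str, str, str], list[float]] = {}
    log: list[str] = []
    cellwise = partitions.scheme == "cv2"
    if cellwise:
        # align partition cell table with data records
        key = list(zip(partitions.cell_table["line"], partitions.cell_table["site"]))
        data_key = list(zip((data.X.line_ids[i] for i in data.line_index),
                            (data.sites[j] for j in data.site_index)))
        pos = {k: i for i, k in enumerate(key)}
        try:
            order = np.array([pos[k] for k in data_key])
        except KeyError as e:
            raise ValueError(f"record {e} missing from partition cell table") from None

    for rep in range(partitions.n_reps):
        if cellwise:
            trn_mask = partitions.masks[rep][order]
        else:
            trn_lines = partitions.masks[rep]
            trn_mask = trn_lines[data.line_index]
        trn = data.subset(trn_mask)
        tst_rows = np.flatnonzero(~trn_mask)
        preds = {name: fac(trn) for name, fac in models.items()}
        for j, site in enumerate(data.sites):
            rows_j = tst_rows[data.site_index[tst_rows] == j]
            if rows_j.size < 3:
                log.append(f"rep {rep}: site {site} has {rows_j.size} test records; skipped")
                continue
            obs = data.y_stacked[rows_j]
            lid = data.line_index[rows_j]
            h2 = float(h2_per_site.get(site, 1.0))
            site_scores = {}
            for name, pred in preds.items():
                yhat = pred[lid, j]
                if np.isnan(yhat).all():
                    continue
                acc, r = prediction_accuracy(yhat, obs, h2)
                try:
                    slope = bias_slope(yhat, obs)
                except ValueError:
                    slope = float("nan")
                rows.append((site, name, partitions.scheme, rep, r, acc, slope))
                site_scores[name] = yhat
            names = sorted(site_scores)
            for a_i in range(len(names)):
                for b_i in range(a_i + 1, len(names)):
                    a, b = names[a_i], names[b_i]
                    if len(site_scores[a]) < 5:
                        continue
                    eff = selection_efficiency(site_scores[a], site_scores[b],
                                               intensity)
                    sel_acc.setdefault((a, b, site), []).append(eff)

    per_rep = pd.DataFrame(rows, columns=["site", "model", "scheme", "rep",
                                          "corr", "accuracy", "bias"])
    summary = EvaluationReport.aggregate(per_rep) if len(per_rep) else pd.DataFrame()
    sel = pd.DataFrame(
        [(a, b, s, float(np.mean(v))) for (a, b, s), v in sorted(sel_acc.items())],
        columns=["model_a", "model_b", "site", "efficiency_pct"])
    return EvaluationReport(per_rep, summary, sel, partitions.scheme,
                            h2_per_site, log)
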