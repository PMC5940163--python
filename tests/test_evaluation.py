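"""Partitions, accuracy/bias statistics, and coincidence-index efficiency."""

import numpy as np
import pandas as pd
import pytest

from cottongs.evaluation import (EvaluationReport, bias_slope,
                                 coincidence_from_counts, evaluate,
                                 default_model_factories, make_partitions,
                                 prediction_accuracy, selection_efficiency)
from cottongs.multienv import MultiEnvData
from cottongs.wgr import MCMCSettings, PriorSpec


def test_line_partition_sizes_and_disjointness():
    p = make_partitions(n_lines=10, scheme="single_site_random", n_reps=5,
                        frac_train=0.7, seed=1)
    assert p.masks.shape == (5, 10)
    assert (p.masks.sum(axis=1) == 7).all()


def test_partition_determinism():
    a = make_partitions(n_lines=50, scheme="cv1", n_reps=3, seed=4)
    b = make_partitions(n_lines=50, scheme="cv1", n_reps=3, seed=4)
    c = make_partitions(n_lines=50, scheme="cv1", n_reps=3, seed=5)
    np.testing.assert_array_equal(a.masks, b.masks)
    assert not np.array_equal(a.masks, c.masks)


def test_bad_frac_train():
    with pytest.raises(ValueError):
        make_partitions(n_lines=10, frac_train=1.2)


def test_cv2_partition_invariants():
    cells = pd.DataFrame([(f"L{i}", f"S{j}") for i in range(116)
                          for j in range(4)], columns=["line", "site"])
    p = make_partitions(scheme="cv2", n_reps=10, frac_train=0.70, seed=2,
                        cells=cells)
    for rep in range(10):
        trn = p.masks[rep]
        df = cells.assign(trn=trn)
        per_line = df.groupby("line")["trn"].agg(["sum", "count"])
        # every line keeps at least one training site
        assert (per_line["sum"] >= 1).all()
        masked = per_line["count"] - per_line["sum"]
        tst_lines = masked[masked > 0]
        assert tst_lines.between(1, 3).all()
        # overall and per-site masking near 30%
        frac = 1 - trn.mean()
        assert abs(frac - 0.30) < 0.06
        per_site = 1 - df.groupby("site")["trn"].mean()
        assert (np.abs(per_site - 0.30) <= 0.05 + 1e-12).all()


def test_prediction_accuracy_scaling():
    rng = np.random.default_rng(0)
    a = rng.normal(size=50)
    b = a + rng.normal(size=50)
    acc1, r1 = prediction_accuracy(a, b, h2=1.0)
    assert acc1 == pytest.approx(r1)
    acc, r = prediction_accuracy(a, b, h2=0.36)
    assert acc == pytest.approx(r / 0.6)
    acc_id, _ = prediction_accuracy(a, a, h2=1.0)
    assert acc_id == pytest.approx(1.0)


def test_prediction_accuracy_worked_example():
    # correlation 0.3 scaled by sqrt(0.36) gives 0.5
    assert 0.3 / np.sqrt(0.36) == pytest.approx(0.5)
    rng = np.random.default_rng(3)
    x = rng.normal(size=2000)
    y = 0.3 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.09) * rng.normal(size=2000)
    acc, r = prediction_accuracy(x, y, h2=0.36)
    assert acc == pytest.approx(r / 0.6)


def test_prediction_accuracy_zero_variance_flagged():
    acc, r = prediction_accuracy(np.ones(5), np.arange(5.0))
    assert np.isnan(acc) and np.isnan(r)


def test_prediction_accuracy_affine_invariance():
    rng = np.random.default_rng(7)
    a, b = rng.normal(size=30), rng.normal(size=30)
    acc, _ = prediction_accuracy(a, b, 0.5)
    acc2, _ = prediction_accuracy(3 * a + 1, -2 * b + 5, 0.5)
    assert abs(acc2) == pytest.approx(abs(acc), abs=1e-12)


def test_bias_slope_cases():
    e = np.array([1.0, 2.0, 3.0])
    assert bias_slope(e, e) == pytest.approx(1.0)
    assert bias_slope(np.array([0.5, 1.0, 1.5]), e) == pytest.approx(0.5)
    rng = np.random.default_rng(1)
    big_e = rng.normal(size=5000)
    assert abs(bias_slope(rng.normal(size=5000), big_e)) < 0.05
    with pytest.raises(ValueError):
        bias_slope(e, np.ones(3))


def test_selection_efficiency_worked_example():
    assert coincidence_from_counts(116, 10, 0.20) == pytest.approx(500 / 18)
    assert round(coincidence_from_counts(116, 10, 0.20)) == 28


def test_selection_efficiency_boundaries():
    rng = np.random.default_rng(2)
    a = rng.normal(size=116)
    assert selection_efficiency(a, a, 0.20) == pytest.approx(100.0)
    assert coincidence_from_counts(116, 5, 0.20) == 0.0   # c == chance
    assert coincidence_from_counts(116, 3, 0.20) == 0.0   # floored at 0
    with pytest.raises(ValueError):
        selection_efficiency(a, a, intensity=0.001)       # n_sel <= chance


def test_selection_efficiency_null_expectation():
    """Independent rankings: mean efficiency ~ 0 (it is floored at 0, so the
    unfloored coincidence count is compared with chance instead)."""
    rng = np.random.default_rng(11)
    n, n_sel = 100, 20
    chance = 4
    excess = []
    for _ in range(1000):
        a, b = rng.normal(size=n), rng.normal(size=n)
        top_a = set(np.argsort(-a)[:n_sel])
        top_b = set(np.argsort(-b)[:n_sel])
        excess.append(len(top_a & top_b) - chance)
    # E[c] = n_sel^2 / n = 4 = chance; 3 MC-SE band
    se = np.std(excess, ddof=1) / np.sqrt(len(excess))
    assert abs(np.mean(excess)) < 3 * se + 1e-9


def test_aggregate_recomputable_from_rows():
    rng = np.random.default_rng(5)
    rows = []
    for site in ("A", "B"):
        for rep in range(10):
            rows.append((site, "m", "cv1", rep, rng.random(), rng.random(),
                         rng.random()))
    per_rep = pd.DataFrame(rows, columns=["site", "model", "scheme", "rep",
                                          "corr", "accuracy", "bias"])
    summary = EvaluationReport.aggregate(per_rep)
    for _, row in summary.iterrows():
        sub = per_rep[(per_rep.site == row.site)]
        assert row.corr_mean == pytest.approx(sub["corr"].mean(), abs=1e-12)
        assert row.corr_se == pytest.approx(
            sub["corr"].std(ddof=1) / np.sqrt(len(sub)), abs=1e-12)


def test_evaluate_deterministic_and_structured(multisite_sim):
    g, phen, truth = multisite_sim
    data = MultiEnvData.from_tables(phen, truth.X, "trait")
    parts = make_partitions(n_lines=data.X.n_lines, scheme="cv1", n_reps=2,
                            frac_train=0.7, seed=8)
    mc = MCMCSettings(800, 200, 3, seed=4)
    facs = default_model_factories(PriorSpec("BayesC"), mc,
                                   models=("single_site", "across_site"))
    r1 = evaluate(facs, data, parts, h2_per_site={s: 0.5 for s in data.sites})
    r2 = evaluate(facs, data, parts, h2_per_site={s: 0.5 for s in data.sites})
    pd.testing.assert_frame_equal(r1.per_rep, r2.per_rep)
    # rows: sites x models x reps
    assert len(r1.per_rep) == 4 * 2 * 2
    # scaled accuracy = raw / sqrt(h2)
    np.testing.assert_allclose(r1.per_rep["accuracy"],
                               r1.per_rep["corr"] / np.sqrt(0.5))
    assert set(r1.selection.columns) == {"model_a", "model_b", "site",
                                         "efficiency_pct"}


def test_unknown_model_name_lists_valid():
    with pytest.raises(ValueError, match="single_site"):
        default_model_factories(PriorSpec("BRR"), MCMCSettings(100, 10, 1),
                                models=("nonsense",))
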