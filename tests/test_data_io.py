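"""Genotype/phenotype ingestion, filtering, imputation and scaling."""

import numpy as np
import pandas as pd
import pytest

from cottongs.data_io import (GenotypeMatrix, PhenotypeTable,
                              center_standardize, filter_markers,
                              impute_missing_mean, read_genotype_table,
                              read_phenotype_table, standardize_like,
                              write_genotype_table, write_phenotype_table)


def test_call_csv_code_map(tmp_path):
    f = tmp_path / "g.csv"
    f.write_text("line,M1,M2\nA,AA,AB\nB,BB,NA\n")
    g = read_genotype_table(f, dialect="call_csv")
    assert g.dosage[0, 0] == 0 and g.dosage[0, 1] == 1 and g.dosage[1, 0] == 2
    assert g.missing_mask.sum() == 1 and g.missing_mask[1, 1]


def test_dosage_out_of_range_names_cell(tmp_path):
    f = tmp_path / "g.csv"
    f.write_text("line,M1,M2\nA,0,3\n")
    with pytest.raises(ValueError, match="M2"):
        read_genotype_table(f, dialect="dosage_csv")


def test_malformed_call_names_cell(tmp_path):
    f = tmp_path / "g.csv"
    f.write_text("line,M1\nA,AC\n")
    with pytest.raises(ValueError, match="AC"):
        read_genotype_table(f, dialect="call_csv")


def test_duplicate_line_id_rejected():
    with pytest.raises(ValueError, match="duplicate line"):
        GenotypeMatrix(["A", "A"], ["M1"], np.zeros((2, 1)),
                       np.zeros((2, 1), bool))


def test_vcf_dialect(tmp_path):
    f = tmp_path / "g.vcf"
    f.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "1\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/0\t1/1\n"
        "1\t200\tsnp2\tA\tG\t.\t.\t.\tGT\t0/1\t./.\n")
    g = read_genotype_table(f, dialect="vcf")
    assert g.line_ids == ["S1", "S2"]
    assert g.dosage[0, 0] == 0 and g.dosage[1, 0] == 2 and g.dosage[0, 1] == 1
    assert g.missing_mask[1, 1]


def test_phenotype_round_trip_and_site_counts(tmp_path):
    # site layout mirroring an unbalanced multi-site trial series
    counts = {"MV": 215, "CO": 88, "BK": 125, "EM": 124, "SG": 128,
              "BR": 80, "DD": 99}
    rows = [(f"L{i:03d}", site, "length", float(i % 7), "")
            for site, n in counts.items() for i in range(n)]
    f = tmp_path / "p.csv"
    f.write_text("line,site,trait,mean,se\n"
                 + "\n".join(",".join(map(str, r)) for r in rows) + "\n")
    t = read_phenotype_table(f)
    got = t.records.groupby("site").size().to_dict()
    assert got == counts
    out = tmp_path / "out.csv"
    write_phenotype_table(t, out)
    t2 = read_phenotype_table(out)
    pd.testing.assert_frame_equal(
        t.records.reset_index(drop=True), t2.records.reset_index(drop=True))


def test_phenotype_duplicate_triple_rejected():
    df = pd.DataFrame({"line": ["A", "A"], "site": ["S", "S"],
                       "trait": ["t", "t"], "mean": [1.0, 2.0]})
    with pytest.raises(ValueError, match="duplicate"):
        PhenotypeTable(df)


def test_phenotype_non_numeric_mean(tmp_path):
    f = tmp_path / "p.csv"
    f.write_text("line,site,trait,mean\nA,S,t,abc\n")
    with pytest.raises(ValueError, match="non-numeric"):
        read_phenotype_table(f)


def test_genotype_round_trip(tmp_path, toy_genotypes):
    g = toy_genotypes
    g.dosage[0, 0] = np.nan
    g.missing_mask[0, 0] = True
    path = tmp_path / "g.csv"
    write_genotype_table(g, path)
    g2 = read_genotype_table(path)
    assert g2.line_ids == g.line_ids and g2.marker_ids == g.marker_ids
    np.testing.assert_array_equal(g2.missing_mask, g.missing_mask)
    m = ~g.missing_mask
    np.testing.assert_allclose(g2.dosage[m], g.dosage[m])


@pytest.mark.parametrize("dosages,missing,kept", [
    ([0, 2, 0, 2, 1], [0, 0, 0, 0, 0], True),    # cr 1.0, maf 0.5
    ([0, 2, 0, 2, 1], [1, 1, 0, 0, 0], False),   # call rate 0.6 <= 0.8
    ([0, 0, 0, 0, 0], [0, 0, 0, 0, 0], False),   # monomorphic
])
def test_filter_markers_single(dosages, missing, kept):
    d = np.array([dosages], float).T
    m = np.array([missing], bool).T
    d[m] = np.nan
    g = GenotypeMatrix([f"L{i}" for i in range(5)], ["M"], d, m)
    if kept:
        assert filter_markers(g).n_markers == 1
    else:
        with pytest.raises(ValueError):
            filter_markers(g)


def test_filter_markers_counts_by_brute_force(rng):
    n, p = 20, 10
    d = rng.binomial(2, rng.uniform(0.05, 0.5, p), size=(n, p)).astype(float)
    d[:, 0] = 0.0          # monomorphic
    d[:, 1] = 2.0
    d[:, 2] = 0.0
    m = np.zeros((n, p), bool)
    m[:15, 3] = True       # call rate 0.25
    d[m] = np.nan
    g = GenotypeMatrix([f"L{i}" for i in range(n)], [f"M{k}" for k in range(p)],
                       d, m)
    out = filter_markers(g)
    # independent per-marker check
    expect = []
    for k in range(p):
        col = d[:, k]
        obs = col[~m[:, k]]
        cr = len(obs) / n
        pfreq = obs.mean() / 2
        if cr > 0.8 and min(pfreq, 1 - pfreq) > 0.05:
            expect.append(f"M{k}")
    assert out.marker_ids == expect


def test_filter_allele_label_symmetry(toy_genotypes):
    g = toy_genotypes
    kept = filter_markers(g, 0.8, 0.05).marker_ids
    flipped = GenotypeMatrix(list(g.line_ids), list(g.marker_ids),
                             2.0 - g.dosage, g.missing_mask.copy())
    assert filter_markers(flipped, 0.8, 0.05).marker_ids == kept


def test_impute_mean_value():
    d = np.array([[0.0], [2.0], [np.nan], [2.0]])
    m = np.isnan(d)
    g = GenotypeMatrix(["a", "b", "c", "d"], ["M"], d, m)
    out = impute_missing_mean(g)
    assert out.dosage[2, 0] == pytest.approx(4.0 / 3.0)
    assert not out.missing_mask.any()
    # per-marker mean preserved
    assert out.dosage[:, 0].mean() != 0
    np.testing.assert_allclose(out.dosage[[0, 1, 3], 0], [0, 2, 2])


def test_impute_identity_when_complete(toy_genotypes):
    out = impute_missing_mean(toy_genotypes)
    np.testing.assert_array_equal(out.dosage, toy_genotypes.dosage)


def test_impute_preserves_marker_means(rng):
    d = rng.binomial(2, 0.5, size=(10, 5)).astype(float)
    m = rng.random((10, 5)) < 0.3
    m[:, 0] = False
    dd = d.copy()
    dd[m] = np.nan
    g = GenotypeMatrix([f"L{i}" for i in range(10)], [f"M{k}" for k in range(5)],
                       dd, m)
    pre = np.array([dd[~m[:, k], k].mean() for k in range(5)])
    out = impute_missing_mean(g)
    np.testing.assert_allclose(out.dosage.mean(axis=0), pre, atol=1e-12)


def test_center_standardize_basics():
    g = GenotypeMatrix(["a", "b", "c"], ["M"], np.array([[0.], [1.], [2.]]),
                       np.zeros((3, 1), bool))
    X = center_standardize(g)
    np.testing.assert_allclose(X.X[:, 0], [-1, 0, 1])
    assert abs(X.X.mean()) < 1e-10
    assert X.X.std(ddof=1) == pytest.approx(1.0)


def test_center_standardize_constant_column_errors():
    g = GenotypeMatrix(["a", "b"], ["M"], np.array([[1.], [1.]]),
                       np.zeros((2, 1), bool))
    with pytest.raises(ValueError, match="M"):
        center_standardize(g)


def test_pipeline_composition_gives_complete_matrix(rng):
    n, p = 30, 40
    d = rng.binomial(2, rng.uniform(0.1, 0.5, p), size=(n, p)).astype(float)
    m = rng.random((n, p)) < 0.05
    dd = d.copy()
    dd[m] = np.nan
    g = GenotypeMatrix([f"L{i}" for i in range(n)], [f"M{k}" for k in range(p)],
                       dd, m)
    X = center_standardize(impute_missing_mean(filter_markers(g)))
    assert not np.isnan(X.X).any()
    assert np.abs(X.X.mean(axis=0)).max() < 1e-10
    np.testing.assert_allclose(X.X.std(axis=0, ddof=1), 1.0, atol=1e-10)


def test_standardize_like_uses_training_scale(toy_genotypes):
    ref = center_standardize(toy_genotypes)
    new = GenotypeMatrix(["N1"], list(toy_genotypes.marker_ids),
                         toy_genotypes.dosage[:1].copy(),
                         np.zeros((1, toy_genotypes.n_markers), bool))
    out = standardize_like(new, ref)
    np.testing.assert_allclose(out.X[0], ref.X[0], atol=1e-12)
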