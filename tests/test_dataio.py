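import numpy as np
import pytest

from canetx.dataio import (
    AliasTable,
    OmicsMatrix,
    consolidate_duplicates,
    filter_missingness,
    harmonize_names,
    impute_knn,
    load_omics_table,
    log_transform,
    prepare,
    variance_filter_genes,
    write_omics_table,
)

from conftest import make_matrix


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestLoadOmicsTable:
    def test_parses_missing_cells(self, tmp_path):
        f = write_tsv(tmp_path / "t.tsv", "id\tm1\tm2\ns1\t1.0\t\ns2\t2.0\t3.0\ns3\t4.0\t5.0\n")
        m = load_omics_table(f, group_map={"s1": "cancer", "s2": "cancer", "s3": "control"})
        assert m.n_missing == 1
        assert np.isnan(m.values[0, 1])
        assert m.values[2, 1] == 5.0

    def test_row_and_column_orientation_agree(self, tmp_path):
        gm = {"s1": "cancer", "s2": "control"}
        fc = write_tsv(tmp_path / "c.tsv", "id\tm1\tm2\ns1\t1\t2\ns2\t3\t4\n")
        fr = write_tsv(tmp_path / "r.tsv", "id\ts1\ts2\nm1\t1\t3\nm2\t2\t4\n")
        a = load_omics_table(fc, group_map=gm)
        b = load_omics_table(fr, orientation="features_in_rows", group_map=gm)
        assert a.feature_ids == b.feature_ids and a.sample_ids == b.sample_ids
        np.testing.assert_array_equal(a.values, b.values)

    def test_roundtrip_through_writer(self, tmp_path):
        m = make_matrix([[1.5, np.nan], [2.0, 3.25], [0.5, 4.0]],
                        group=("cancer", "cancer", "control"))
        path = tmp_path / "rt.tsv"
        write_omics_table(m, path)
        gm = dict(zip(m.sample_ids, m.group))
        back = load_omics_table(path, group_map=gm)
        assert back.feature_ids == m.feature_ids
        np.testing.assert_array_equal(back.values, m.values)
        # second write is bit-identical
        path2 = tmp_path / "rt2.tsv"
        write_omics_table(back, path2)
        assert path.read_text() == path2.read_text()

    def test_errors(self, tmp_path):
        f = write_tsv(tmp_path / "bad.tsv", "id\tm1\ns1\tabc\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_omics_table(f, group_map={"s1": "cancer"})
        f2 = write_tsv(tmp_path / "miss.tsv", "id\tm1\ns1\t1\nsX\t2\n")
        with pytest.raises(ValueError, match="absent from group map"):
            load_omics_table(f2, group_map={"s1": "cancer"})


class TestHarmonize:
    def test_majority_vote(self):
        m = make_matrix(np.ones((2, 1)))
        m = OmicsMatrix(m.values, m.sample_ids, ("kegg:C1;hmdb:H1;pubchem:P1",), m.group)
        aliases = AliasTable((
            ("kegg", "C1", "glucose"),
            ("hmdb", "H1", "glucose"),
            ("pubchem", "P1", "D-glucose"),
        ))
        assert harmonize_names(m, aliases).feature_ids == ("glucose",)

    def test_unmatched_keeps_name(self):
        m = make_matrix(np.ones((2, 1)))
        aliases = AliasTable((("kegg", "C9", "x"),))
        assert harmonize_names(m, aliases).feature_ids == m.feature_ids

    def test_tie_breaks_lexicographically(self):
        m = make_matrix(np.ones((2, 1)))
        m = OmicsMatrix(m.values, m.sample_ids, ("a:1;b:1;c:1;d:1",), m.group)
        aliases = AliasTable((
            ("a", "1", "zeta"), ("b", "1", "zeta"),
            ("c", "1", "alpha"), ("d", "1", "alpha"),
        ))
        assert harmonize_names(m, aliases).feature_ids == ("alpha",)

    def test_empty_alias_table_warns(self):
        m = make_matrix(np.ones((2, 2)))
        with pytest.warns(UserWarning):
            out = harmonize_names(m, AliasTable(()))
        assert out.feature_ids == m.feature_ids


class TestConsolidate:
    def test_mean_over_duplicates(self):
        m = make_matrix([[1, 3], [2, 4], [3, 5]])
        m = OmicsMatrix(m.values, m.sample_ids, ("g", "g"), m.group)
        out = consolidate_duplicates(m)
        assert out.feature_ids == ("g",)
        np.testing.assert_array_equal(out.values[:, 0], [2, 3, 4])

    def test_missing_excluded_from_mean(self):
        m = make_matrix([[1, 3], [np.nan, np.nan]])
        m = OmicsMatrix(m.values, m.sample_ids, ("g", "g"), m.group)
        out = consolidate_duplicates(m)
        assert out.values[0, 0] == 2
        assert np.isnan(out.values[1, 0])

    def test_idempotent_and_identity(self):
        m = make_matrix([[1, 2], [3, 4]])
        once = consolidate_duplicates(m)
        assert once is m  # no duplicates: unchanged
        m2 = make_matrix(np.arange(6.0).reshape(2, 3))
        m2 = OmicsMatrix(m2.values, m2.sample_ids, ("a", "a", "b"), m2.group)
        twice = consolidate_duplicates(consolidate_duplicates(m2))
        np.testing.assert_array_equal(twice.values, consolidate_duplicates(m2).values)


class TestFilterImpute:
    def test_strictly_greater_boundary(self):
        v = np.ones((10, 2))
        v[:2, 0] = np.nan  # 20% missing -> removed
        v[0, 1] = np.nan  # exactly 10% -> retained
        out = filter_missingness(make_matrix(v), 0.10)
        assert out.feature_ids == ("f1",)

    def test_all_removed_raises(self):
        v = np.full((4, 2), np.nan)
        with pytest.raises(ValueError, match="threshold"):
            filter_missingness(make_matrix(v), 0.10)

    def test_knn_forced_neighbor(self):
        # f1 identical to f0 except in the missing sample
        v = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, np.nan]])
        out = impute_knn(make_matrix(v), k=1)
        assert out.values[3, 1] == 4.0

    def test_knn_beats_mean_imputation(self, rng):
        # smooth structure: correlated features
        base = rng.normal(size=(60, 1))
        x = base + 0.1 * rng.normal(size=(60, 10))
        mask = rng.random(x.shape) < 0.05
        xm = x.copy()
        xm[mask] = np.nan
        out = impute_knn(make_matrix(xm), k=3)
        rmse_knn = np.sqrt(np.mean((out.values[mask] - x[mask]) ** 2))
        col_means = np.nanmean(xm, axis=0)
        mean_filled = np.where(mask, np.broadcast_to(col_means, x.shape), xm)
        rmse_mean = np.sqrt(np.mean((mean_filled[mask] - x[mask]) ** 2))
        assert rmse_knn < rmse_mean

    def test_filter_then_impute_leaves_no_missing(self, rng):
        x = np.exp(rng.normal(size=(30, 15)))
        mask = rng.random(x.shape) < 0.08
        x[mask] = np.nan
        m = impute_knn(filter_missingness(make_matrix(x), 0.2))
        assert m.n_missing == 0
        assert np.isfinite(m.values).all()


class TestLogTransform:
    def test_definition(self):
        m = log_transform(make_matrix([[np.e, 1.0]] * 2))
        np.testing.assert_allclose(m.values[0], [1.0, 0.0], atol=1e-12)
        assert m.log_transformed

    def test_double_transform_raises(self):
        m = log_transform(make_matrix([[1.0, 2.0]] * 2))
        with pytest.raises(ValueError, match="already"):
            log_transform(m)

    def test_nonpositive_raises_with_feature_names(self):
        with pytest.raises(ValueError, match="f1"):
            log_transform(make_matrix([[1.0, 0.0], [2.0, 3.0]]))

    def test_lognormal_columns_center_near_zero(self, rng):
        n = 4000
        x = np.exp(rng.normal(size=(n, 3)))
        out = log_transform(make_matrix(x))
        se = 1.0 / np.sqrt(n)
        assert np.all(np.abs(out.values.mean(axis=0)) < 3 * se)


class TestVarianceFilter:
    def test_dominant_gene_selected(self, rng):
        x = rng.normal(size=(20, 5))
        x[:, 2] *= 10.0
        m = make_matrix(x, modality="transcriptomics", log_transformed=True)
        assert variance_filter_genes([m]) == ["f2"]

    def test_gene_absent_from_one_matrix_never_selected(self, rng):
        # f0 dominates in matrix 1 but is absent from matrix 2; f1 is the
        # shared highly variable gene
        x1 = rng.normal(size=(20, 10))
        x1[:, 0] *= 20
        x1[:, 1] *= 10
        m1 = make_matrix(x1, modality="transcriptomics")
        x2 = rng.normal(size=(20, 9))
        x2[:, 0] *= 10
        m2 = OmicsMatrix(
            x2,
            tuple(f"t{i}" for i in range(20)),
            tuple(f"f{j}" for j in range(1, 10)),
            ("cancer",) * 20,
            modality="transcriptomics",
        )
        selected = variance_filter_genes([m1, m2])
        assert "f0" not in selected
        assert "f1" in selected

    def test_normal_tail_fraction(self, rng):
        # log-variances ~ N: selected fraction approx P(Z > 1)
        p = 4000
        lv = rng.normal(0.0, 1.0, size=p)
        sd = np.exp(lv / 2.0)
        x = rng.normal(size=(2000, p)) * sd
        m = make_matrix(x, modality="transcriptomics")
        frac = len(variance_filter_genes([m])) / p
        assert abs(frac - 0.159) < 0.03


def test_prepare_pipeline_on_complete_matrix_only_rescales(rng):
    x = np.exp(rng.normal(size=(12, 6)))
    m = make_matrix(x)
    out = prepare(m)
    assert out.feature_ids == m.feature_ids
    np.testing.assert_allclose(out.values, np.log(x))
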