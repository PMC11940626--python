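"""Normalization, filtering and batch-adjustment behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from somportrait import (center_genes, combat_adjust, counts_to_tpm,
                         filter_low_expression, intersect_genes, log_transform,
                         merge_cohorts, quantile_normalize,
                         read_expression_table, write_expression_table)
from somportrait.preprocess import ExpressionMatrix

from conftest import make_matrix


# ---------------------------------------------------------------------- I/O

def test_read_write_round_trip(tmp_path):
    m = make_matrix(np.arange(6).reshape(3, 2) + 0.5)
    path = tmp_path / "expr.tsv"
    write_expression_table(m, path)
    back = read_expression_table(path, scale="tpm")
    assert back.values.shape == (3, 2)
    assert np.allclose(back.to_numpy(), m.to_numpy(), atol=1e-12)
    assert back.gene_ids == m.gene_ids and back.sample_ids == m.sample_ids


def test_read_transposed_orientation(tmp_path):
    m = make_matrix([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    path = tmp_path / "expr.tsv"
    m.values.T.to_csv(path, sep="\t", index_label="sample_id")
    back = read_expression_table(path, samples_in_rows=True)
    assert np.allclose(back.to_numpy(), m.to_numpy())


def test_duplicate_gene_id_is_reported(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("gene_id\ts1\ts2\ngA\t1\t2\ngA\t3\t4\n")
    with pytest.raises(ValueError, match="gA"):
        read_expression_table(path)


def test_non_numeric_cell_is_reported(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("gene_id\ts1\ngA\t1\ngB\tNA?\n")
    with pytest.raises(ValueError, match="s1"):
        read_expression_table(path)


# ------------------------------------------------------------- counts -> TPM

def test_counts_to_tpm_hand_example():
    m = make_matrix([[10.0], [20.0]], scale="counts")
    m.gene_lengths = pd.Series([1.0, 2.0], index=m.values.index)
    tpm = counts_to_tpm(m)
    # rates 10/1 and 20/2 are equal, so each gene gets half the million
    assert np.allclose(tpm.to_numpy().ravel(), [500000.0, 500000.0])
    assert tpm.scale == "tpm"


def test_counts_to_tpm_single_gene_and_scale_invariance():
    m = make_matrix([[7.0, 3.0]], scale="counts")
    m.gene_lengths = pd.Series([2.5], index=m.values.index)
    assert np.allclose(counts_to_tpm(m).to_numpy(), 1e6)

    rng = np.random.default_rng(0)
    counts = rng.integers(1, 100, size=(5, 3)).astype(float)
    m1 = make_matrix(counts, scale="counts")
    m1.gene_lengths = pd.Series(rng.uniform(0.5, 3, 5), index=m1.values.index)
    m2 = make_matrix(counts * np.array([2.0, 1.0, 5.0]), scale="counts")
    m2.gene_lengths = m1.gene_lengths
    assert np.allclose(counts_to_tpm(m1).to_numpy(), counts_to_tpm(m2).to_numpy())


def test_counts_to_tpm_errors():
    m = make_matrix([[1.0], [2.0]], scale="counts")
    with pytest.raises(ValueError, match="gene_lengths"):
        counts_to_tpm(m)
    m.gene_lengths = pd.Series([0.0, 1.0], index=m.values.index)
    with pytest.raises(ValueError, match="positive"):
        counts_to_tpm(m)
    z = make_matrix([[0.0, 1.0], [0.0, 2.0]], scale="counts")
    z.gene_lengths = pd.Series([1.0, 1.0], index=z.values.index)
    with pytest.raises(ValueError, match="s0"):
        counts_to_tpm(z)


@given(st.integers(1, 8), st.integers(1, 4), st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_counts_to_tpm_columns_sum_to_million(n_genes, n_samples, seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 1000, size=(n_genes, n_samples)).astype(float)
    m = make_matrix(counts, scale="counts")
    m.gene_lengths = pd.Series(rng.uniform(0.2, 5, n_genes),
                               index=m.values.index)
    sums = counts_to_tpm(m).to_numpy().sum(axis=0)
    assert np.allclose(sums, 1e6, rtol=1e-6)


# ------------------------------------------------------------ log transform

def test_log_transform_values_and_negative_error():
    m = make_matrix([[0.0], [1.0], [7.0]])
    out = log_transform(m)
    assert np.allclose(out.to_numpy().ravel(), [0.0, 1.0, 3.0])
    assert out.scale == "log2tpm"
    with pytest.raises(ValueError, match="negative"):
        log_transform(make_matrix([[-1.0]]))


# ------------------------------------------------------ quantile normalize

def test_quantile_normalize_hand_example():
    m = make_matrix([[2.0, 3.0], [4.0, 5.0], [6.0, 7.0]], scale="log2tpm")
    out = quantile_normalize(m).to_numpy()
    assert np.allclose(out[:, 0], [2.5, 4.5, 6.5])
    assert np.allclose(out[:, 1], [2.5, 4.5, 6.5])


def test_quantile_normalize_fixed_point_and_ties():
    same = make_matrix([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]], scale="log2tpm")
    assert np.allclose(quantile_normalize(same).to_numpy(), same.to_numpy())
    # a tied pair receives the mean of its two target values
    tied = make_matrix([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]], scale="log2tpm")
    out = quantile_normalize(tied).to_numpy()
    assert out[0, 0] == out[1, 0] == pytest.approx((5.5 + 10.5) / 2)


@given(st.integers(2, 6), st.integers(2, 30), st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_quantile_normalize_columns_share_sorted_vector(n_samples, n_genes, seed):
    rng = np.random.default_rng(seed)
    m = make_matrix(rng.normal(size=(n_genes, n_samples)), scale="log2tpm")
    out = quantile_normalize(m).to_numpy()
    ref = np.sort(out[:, 0])
    for j in range(1, n_samples):
        assert np.allclose(np.sort(out[:, j]), ref, atol=1e-12)


# ------------------------------------------------------------ gene centering

def test_center_genes_rows_and_idempotence():
    m = make_matrix([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]], scale="log2tpm")
    out = center_genes(m)
    assert np.allclose(out.to_numpy()[0], [-1.0, 0.0, 1.0])
    assert np.allclose(out.to_numpy()[1], 0.0)
    assert out.scale == "normalized"
    twice = center_genes(out)
    assert np.allclose(twice.to_numpy(), out.to_numpy(), atol=1e-10)
    assert np.all(np.abs(out.to_numpy().mean(axis=1)) < 1e-10)


# -------------------------------------------------------------------- ComBat

def _shifted_batches(n_genes=60, n_per=50, delta=2.0, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(5, 1, size=(n_genes, 2 * n_per))
    base[:, n_per:] += delta
    batches = pd.Series(["b1"] * n_per + ["b2"] * n_per,
                        index=[f"s{j}" for j in range(2 * n_per)])
    return make_matrix(base, samples=list(batches.index),
                       scale="log2tpm"), batches, delta


def test_combat_shrinks_additive_shift():
    m, batches, delta = _shifted_batches()
    out = combat_adjust(m, batches).to_numpy()
    half = m.n_samples // 2
    before = np.abs(m.to_numpy()[:, half:].mean(axis=1)
                    - m.to_numpy()[:, :half].mean(axis=1))
    residual = np.abs(out[:, half:].mean(axis=1) - out[:, :half].mean(axis=1))
    # the planted shift is removed down to the sampling-noise floor
    assert residual.mean() < 0.1 * delta
    assert np.all(residual < 0.5 * before)


def test_combat_removes_batch_variance_fraction():
    m, batches, _ = _shifted_batches(seed=3)
    b = (batches == "b2").to_numpy()

    def batch_var_fraction(arr):
        grand = arr.mean(axis=1, keepdims=True)
        between = (b.sum() * (arr[:, b].mean(axis=1) - grand[:, 0]) ** 2
                   + (~b).sum() * (arr[:, ~b].mean(axis=1) - grand[:, 0]) ** 2)
        total = ((arr - grand) ** 2).sum(axis=1)
        return between / total

    before = batch_var_fraction(m.to_numpy()).mean()
    after = batch_var_fraction(combat_adjust(m, batches).to_numpy()).mean()
    assert after < 0.2 * before


def test_combat_agrees_with_scanpy_reference():
    """Independent oracle: scanpy's parametric ComBat on the same data."""
    anndata = pytest.importorskip("anndata")
    scanpy = pytest.importorskip("scanpy")
    m, batches, _ = _shifted_batches(n_genes=30, n_per=20, seed=7)
    ours = combat_adjust(m, batches).to_numpy()
    ad = anndata.AnnData(m.to_numpy().T.astype(np.float64))
    ad.obs["batch"] = batches.to_numpy()
    scanpy.pp.combat(ad, key="batch")
    assert np.corrcoef(ours.ravel(), ad.X.T.ravel())[0, 1] > 0.999
    assert np.allclose(ours, ad.X.T, atol=0.05)


def test_combat_errors_and_equivariance():
    m, batches, _ = _shifted_batches(n_genes=10, n_per=10)
    with pytest.raises(ValueError, match=">=2 batches"):
        combat_adjust(m, pd.Series("b1", index=m.sample_ids))
    bad = batches.copy()
    bad.iloc[:] = "b1"
    bad.iloc[0] = "solo"
    with pytest.raises(ValueError, match="<2 samples"):
        combat_adjust(m, bad)

    rng = np.random.default_rng(1)
    perm = rng.permutation(m.n_samples)
    cols = [m.sample_ids[i] for i in perm]
    permuted = ExpressionMatrix(m.values[cols], scale=m.scale, strict_tpm=False)
    out_then_perm = combat_adjust(m, batches).values[cols]
    perm_then_out = combat_adjust(permuted, batches[cols]).values
    assert np.allclose(out_then_perm.to_numpy(), perm_then_out.to_numpy())


def test_combat_passes_zero_variance_genes_through():
    m, batches, _ = _shifted_batches(n_genes=5, n_per=5)
    m.values.iloc[0] = 3.14
    with pytest.warns(UserWarning, match="zero-variance"):
        out = combat_adjust(m, batches)
    assert np.allclose(out.to_numpy()[0], 3.14)


# ----------------------------------------------------- filtering / overlap

def test_filter_low_expression_boundary_rule():
    m = make_matrix([[1.0, 1.0, 5.0, 5.0],    # 50% below floor -> removed
                     [2.0, 2.0, 2.0, 2.0],    # never below -> kept
                     [0.0, 0.0, 0.0, 0.0]])   # all zero -> removed
    out = filter_low_expression(m, tpm_floor=2.0, frac=0.5)
    assert out.gene_ids == ["g1"]
    with pytest.raises(ValueError, match="frac"):
        filter_low_expression(m, frac=0.0)


def test_intersect_genes_and_merge():
    a = make_matrix(np.ones((3, 2)), genes=["a", "b", "c"])
    b = make_matrix(np.ones((3, 2)), genes=["b", "c", "d"],
                    samples=["t0", "t1"])
    ia, ib = intersect_genes(a, b)
    assert ia.gene_ids == ib.gene_ids == ["b", "c"]
    same_a, _ = intersect_genes(a, a)
    assert sorted(same_a.gene_ids) == sorted(a.gene_ids)
    disjoint = make_matrix(np.ones((2, 2)), genes=["x", "y"])
    with pytest.raises(ValueError, match="intersection"):
        intersect_genes(a, disjoint)
    merged, labels = merge_cohorts(ia, ib)
    assert merged.sample_ids == ia.sample_ids + ib.sample_ids
    assert list(labels.unique()) == ["a", "b"]


def test_label_alignment_survives_pipeline(small_cohort):
    expr, ann, _ = small_cohort
    out = center_genes(quantile_normalize(log_transform(
        filter_low_expression(expr))))
    assert out.sample_ids == expr.sample_ids
    assert set(out.gene_ids) <= set(expr.gene_ids)
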