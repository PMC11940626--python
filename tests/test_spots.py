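"""Spot segmentation, PAT stratification and over-representation analysis."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from somportrait import (GeneSetCollection, SamplePortrait,
                         call_spot_activation, derive_pats, ora_collection,
                         ora_hypergeometric, pat_mean_portraits, segment_spots,
                         spot_expression, summary_map)
from somportrait.spots import SpotExpressionTable


def _flat_model(rows, cols, genes_per_cell=1):
    """Minimal SOMModel stub with a uniform gene->cell layout."""
    from somportrait.som import SOMGrid, SOMModel
    n = rows * cols
    gene_ids, bmu = [], []
    for u in range(n):
        for k in range(genes_per_cell):
            gene_ids.append(f"g{u}_{k}")
            bmu.append(u)
    cb = np.zeros((n, 2))
    return SOMModel(SOMGrid(rows, cols), cb, pd.Series(bmu, index=gene_ids),
                    ["s0", "s1"],
                    pd.DataFrame(np.zeros((len(gene_ids), 2)),
                                 index=gene_ids, columns=["s0", "s1"]))


# -------------------------------------------------------------- summary map

def test_summary_map_variants():
    p1 = SamplePortrait("a", np.array([[1.0, 0.0], [0.0, 0.0]]))
    p2 = SamplePortrait("b", np.array([[3.0, 0.0], [0.0, 0.0]]))
    assert summary_map([p1], "overexpression")[0, 0] == 1.0
    assert summary_map([p1, p2], "overexpression")[0, 0] == 3.0
    assert np.allclose(summary_map([p1, p1], "variance"), 0.0)
    with pytest.raises(ValueError):
        summary_map([], "variance")


# ------------------------------------------------------------- segmentation

def test_single_block_becomes_one_spot():
    sm = np.zeros((10, 10))
    sm[2:5, 3:6] = 1.0
    seg = segment_spots(sm, _flat_model(10, 10), threshold_quantile=0.9)
    assert len(seg.spots) == 1
    assert seg.spots[0].n_cells == 9
    assert seg.spots[0].label == "A"
    assert len(seg.spots[0].genes) == 9


def test_two_separated_blocks_become_two_spots():
    sm = np.zeros((10, 10))
    sm[0:2, 0:2] = 1.0
    sm[6:9, 6:9] = 1.0
    seg = segment_spots(sm, _flat_model(10, 10), threshold_quantile=0.8)
    assert len(seg.spots) == 2
    assert [s.n_cells for s in seg.spots] == [9, 4]  # A is the larger spot


def test_zero_threshold_covers_whole_grid():
    sm = np.zeros((6, 6))
    seg = segment_spots(sm, _flat_model(6, 6), threshold_quantile=0.0)
    assert len(seg.spots) == 1
    assert seg.spots[0].n_cells == 36


def test_no_foreground_warns_and_returns_empty():
    sm = np.zeros((5, 5))
    sm[0, 0] = 1.0  # single high cell < min_cells
    with pytest.warns(UserWarning, match="empty segmentation"):
        seg = segment_spots(sm, _flat_model(5, 5), threshold_quantile=0.9,
                            min_cells=4)
    assert seg.spots == []


def test_touching_blocks_with_two_peaks_are_split():
    sm = np.zeros((10, 10))
    sm[2:5, 2:5] = 1.0
    sm[2:5, 5:8] = 2.0  # second, higher block sharing an edge
    sm[2:5, 4] = 0.8    # shallow valley between the peaks
    model = _flat_model(10, 10)
    # give the two halves distinct codebook profiles for the refinement step
    for u in range(100):
        r, c = divmod(u, 10)
        model.codebook[u] = [1.0, -1.0] if c <= 4 else [-1.0, 1.0]
    seg = segment_spots(sm, model, threshold_quantile=0.85, min_cells=4)
    assert len(seg.spots) == 2


def test_segmentation_permutation_invariance(tiny_model):
    from somportrait.som import all_portraits
    ports = all_portraits(tiny_model)
    rng = np.random.default_rng(0)
    shuffled = [ports[i] for i in rng.permutation(len(ports))]
    a = segment_spots(summary_map(ports, "variance"), tiny_model, 0.8, 1)
    b = segment_spots(summary_map(shuffled, "variance"), tiny_model, 0.8, 1)
    assert [s.metagene_cells for s in a.spots] == [s.metagene_cells
                                                   for s in b.spots]


def test_spot_gene_lists_are_disjoint(tiny_model):
    from somportrait.som import all_portraits
    seg = segment_spots(summary_map(all_portraits(tiny_model), "variance"),
                        tiny_model, 0.5, 1)
    seen = set()
    for s in seg.spots:
        assert not (seen & s.genes)
        seen |= s.genes


# ---------------------------------------------------------- spot expression

def test_spot_expression_values():
    sm = np.zeros((4, 4))
    sm[0, 0] = 1.0
    sm[2:4, 2:4] = 1.0
    seg = segment_spots(sm, _flat_model(4, 4), threshold_quantile=0.5,
                        min_cells=1)
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(4, 4))
    table = spot_expression(seg, [SamplePortrait("s", vals)])
    for s in seg.spots:
        brute = np.mean([vals[r, c] for (r, c) in s.metagene_cells])
        assert table.values.loc["s", s.label] == pytest.approx(brute)
    flat = spot_expression(seg, [SamplePortrait("f", np.full((4, 4), 2.7))])
    assert np.allclose(flat.values.to_numpy(), 2.7)


def test_activation_boundary_rule():
    table = SpotExpressionTable(pd.DataFrame(
        {"A": [0.5, 0.0, -0.2]}, index=["s1", "s2", "s3"]))
    act = call_spot_activation(table, tau=0.0)
    assert act["A"].tolist() == [True, False, False]  # tau itself is inactive
    assert not call_spot_activation(table, tau=np.inf).to_numpy().any()


# --------------------------------------------------------------------- PATs

def _portraits_for(index, values):
    return [SamplePortrait(s, np.full((2, 2), float(v)))
            for s, v in zip(index, values)]


def test_pat_labels_canonical_order_and_none():
    act = pd.DataFrame({"G": [True] * 5 + [False] * 5,
                        "H": [True] * 5 + [False] * 5},
                       index=[f"s{i}" for i in range(10)])
    pats = derive_pats(act, _portraits_for(act.index, range(10)),
                       min_group_size=5)
    assert set(pats.labels) == {"GH*", "none*"}
    assert (pats.labels.iloc[:5] == "GH*").all()


def test_rare_combination_merges_to_best_correlated_pat():
    idx = [f"s{i}" for i in range(11)]
    act = pd.DataFrame({"A": [True] * 5 + [False] * 6,
                        "B": [False] * 5 + [True] * 5 + [False]},
                       index=idx)
    # sample s10 is active nowhere but looks exactly like the A* portrait
    ports = []
    for i, s in enumerate(idx):
        base = np.array([[1.0, -1.0], [0.0, 0.0]])
        if 5 <= i < 10:
            base = -base
        ports.append(SamplePortrait(s, base.copy()))
    pats = derive_pats(act, ports, min_group_size=5)
    assert pats.labels["s10"] == "A*"
    assert pats.sizes()["A*"] == 6


def test_all_rare_without_anchor_raises():
    act = pd.DataFrame({"A": [True, False], "B": [False, True]},
                       index=["s0", "s1"])
    with pytest.raises(ValueError, match="anchor"):
        derive_pats(act, _portraits_for(["s0", "s1"], [1, 2]),
                    min_group_size=5)


def test_pat_mean_portraits():
    idx = ["s0", "s1", "s2"]
    act = pd.DataFrame({"A": [True, True, True]}, index=idx)
    ports = [SamplePortrait("s0", np.full((2, 2), 1.0)),
             SamplePortrait("s1", np.full((2, 2), -1.0)),
             SamplePortrait("s2", np.full((2, 2), 3.0))]
    pats = derive_pats(act, ports, min_group_size=1)
    means = pat_mean_portraits(pats, ports)
    assert np.allclose(means["A*"], 1.0)


# ---------------------------------------------------------------------- ORA

def _brute_force_tail(M, n, N, k):
    """P(X >= k) by enumeration over all possible overlaps."""
    total = comb(M, N)
    return sum(comb(n, i) * comb(M - n, N - i)
               for i in range(k, min(n, N) + 1)) / total


def test_ora_exact_example():
    universe = {f"u{i}" for i in range(20)}
    gene_set = {f"u{i}" for i in range(5)}
    res = ora_hypergeometric(gene_set, gene_set, universe)
    assert res["overlap"] == 5
    assert res["p_value"] == pytest.approx(1 / comb(20, 5), rel=1e-10)


def test_ora_zero_overlap_is_one():
    universe = {f"u{i}" for i in range(20)}
    res = ora_hypergeometric({"u0", "u1"}, {"u10", "u11"}, universe)
    assert res["overlap"] == 0
    assert res["p_value"] == pytest.approx(1.0)


@pytest.mark.parametrize("M,n,N", [(10, 3, 4), (20, 6, 5), (30, 10, 12)])
def test_ora_matches_enumeration(M, n, N):
    universe = {f"u{i}" for i in range(M)}
    gene_set = {f"u{i}" for i in range(n)}
    prev = None
    for k in range(0, min(n, N) + 1):
        spot = ({f"u{i}" for i in range(k)}
                | {f"u{i}" for i in range(n, n + N - k)})
        res = ora_hypergeometric(spot, gene_set, universe)
        assert res["overlap"] == k
        assert res["p_value"] == pytest.approx(_brute_force_tail(M, n, N, k),
                                               abs=1e-10)
        if prev is not None:  # monotone decreasing in overlap
            assert res["p_value"] <= prev + 1e-12
        prev = res["p_value"]
    with pytest.raises(ValueError, match="universe"):
        ora_hypergeometric(set(), set(), set())


def test_ora_collection_bh_and_gmt_round_trip(tmp_path):
    universe = {f"u{i}" for i in range(30)}
    coll = GeneSetCollection({
        "hit": ("enriched set", {f"u{i}" for i in range(6)}),
        "miss": ("background set", {f"u{i}" for i in range(20, 26)}),
    })
    df = ora_collection({f"u{i}" for i in range(6)}, coll, universe)
    assert df.iloc[0]["set"] == "hit"
    assert (df["q_value"] >= df["p_value"] - 1e-15).all()
    path = tmp_path / "sets.gmt"
    coll.to_gmt(path)
    back = GeneSetCollection.from_gmt(path)
    assert back.sets["hit"][1] == coll.sets["hit"][1]
    assert back.sets["miss"][0] == "background set"
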