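"""Shared features, CCA, MNN anchors, label transfer, correction, scores."""

import numpy as np
import pandas as pd
import pytest

from conftest import dense_norm
from homoglia import (
    build_shared_space,
    cca_embed,
    cell_cluster_score,
    cluster_correlation,
    cluster_correlation_matrix,
    find_mnn_anchors,
    integrate_correct,
    log_normalize,
    select_hvg,
    transfer_homolog_labels,
)
from homoglia.containers import ScaledMatrix
from homoglia.integrate import AnchorSet, CCAEmbedding, SharedFeatureSpace
from oracles import brute_mnn_pairs, manual_pearson


def _scaled(X, prefix):
    X = np.asarray(X, float)
    return ScaledMatrix(
        X - X.mean(axis=0),
        pd.Index([f"{prefix}{i}" for i in range(X.shape[0])]),
        pd.Index([f"g{j}" for j in range(X.shape[1])]),
    )


def _space(Xa, Xb):
    sa, sb = _scaled(Xa, "a"), _scaled(Xb, "b")
    return SharedFeatureSpace(features=list(sa.gene_ids), scaled_a=sa, scaled_b=sb)


def _emb_from(A, B):
    return CCAEmbedding(
        coords_a=np.asarray(A, float),
        coords_b=np.asarray(B, float),
        cell_ids_a=pd.Index([f"a{i}" for i in range(len(A))]),
        cell_ids_b=pd.Index([f"b{i}" for i in range(len(B))]),
        correlations=np.array([]),
    )


def _anchor_set(pairs):
    return AnchorSet(
        pairs=pd.DataFrame(pairs, columns=["cell_a", "cell_b"]).assign(score=1.0),
        k_anchor=1,
        k_score=1,
    )


# -------------------------------------------------------- shared feature space


def test_shared_space_identical_datasets_is_hvg_union(small_norm):
    hvg = select_hvg(small_norm, n=50)
    space = build_shared_space(small_norm, small_norm, hvg[:30], hvg[20:50])
    assert set(space.features) == set(hvg)
    assert list(space.scaled_a.gene_ids) == space.features
    assert list(space.scaled_b.gene_ids) == space.features


def test_shared_space_disjoint_gene_names_error():
    na = dense_norm(np.ones((5, 3)), gene_prefix="x")
    nb = dense_norm(np.ones((5, 3)), gene_prefix="y")
    with pytest.raises(ValueError, match="disjoint"):
        build_shared_space(na, nb, ["x0"], ["y0"])


def test_shared_space_excludes_private_genes(small_pair):
    counts_a, counts_b, _ = small_pair
    norm_a, norm_b = log_normalize(counts_a), log_normalize(counts_b)
    hvg_a, hvg_b = select_hvg(norm_a, 200), select_hvg(norm_b, 200)
    space = build_shared_space(norm_a, norm_b, hvg_a, hvg_b)
    genes_a, genes_b = set(norm_a.gene_ids), set(norm_b.gene_ids)
    expected = [g for g in dict.fromkeys(hvg_a + hvg_b) if g in genes_a and g in genes_b]
    assert space.features == expected
    assert not any(g.startswith(("PA", "PB")) for g in space.features)


# ------------------------------------------------------------------------ CCA


def test_cca_self_copy_has_unit_correlations_and_matched_cells():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 25))
    emb = cca_embed(_space(X, X), n_cc=5)
    assert np.all(emb.correlations > 1 - 1e-6)
    d2 = (
        np.sum(emb.coords_a**2, axis=1)[:, None]
        + np.sum(emb.coords_b**2, axis=1)[None, :]
        - 2 * emb.coords_a @ emb.coords_b.T
    )
    assert np.array_equal(np.argmin(d2, axis=1), np.arange(40))


def test_cca_rank_one_common_signal_dominates():
    rng = np.random.default_rng(1)
    w = rng.normal(size=30)
    sa, sb = rng.normal(size=50), rng.normal(size=45)
    Na, Nb = rng.normal(size=(50, 30)), rng.normal(size=(45, 30))
    Xa = np.outer(sa, w) + 0.1 * Na
    Xb = np.outer(sb, w) + 0.1 * Nb
    emb = cca_embed(_space(Xa, Xb), n_cc=5)
    # Empirical noise floor: leading correlation of the noise-only pair.
    floor = cca_embed(_space(0.1 * Na, 0.1 * Nb), n_cc=5).correlations[0]
    assert emb.correlations[0] > 0.95
    assert emb.correlations[1] <= floor + 0.05


def test_cca_matches_independent_dense_svd():
    rng = np.random.default_rng(2)
    Xa, Xb = rng.normal(size=(30, 18)), rng.normal(size=(25, 18))
    space = _space(Xa, Xb)
    emb = cca_embed(space, n_cc=6)
    # Independent oracle: numpy dense SVD of the cross-product, same
    # correlation-based ordering and L2 normalization.
    Za, Zb = space.scaled_a.X, space.scaled_b.X
    U, s, Vt = np.linalg.svd(Za @ Zb.T)
    U, V = U[:, :6], Vt[:6].T
    corr = s[:6] / (
        np.linalg.norm(Za.T @ U, axis=0) * np.linalg.norm(Zb.T @ V, axis=0)
    )
    order = np.argsort(-corr, kind="stable")
    U, V = U[:, order], V[:, order]
    Un = U / np.linalg.norm(U, axis=1, keepdims=True)
    Vn = V / np.linalg.norm(V, axis=1, keepdims=True)
    for k in range(6):
        sign = np.sign(np.dot(emb.coords_a[:, k], Un[:, k]))
        assert np.allclose(emb.coords_a[:, k], sign * Un[:, k], atol=1e-8)
        assert np.allclose(emb.coords_b[:, k], sign * Vn[:, k], atol=1e-8)
    assert np.allclose(emb.correlations, corr[order], atol=1e-8)


def test_cca_invariants_and_errors():
    rng = np.random.default_rng(3)
    emb = cca_embed(_space(rng.normal(size=(20, 12)), rng.normal(size=(15, 12))), n_cc=5)
    assert np.all((emb.correlations >= 0) & (emb.correlations <= 1))
    assert np.all(np.diff(emb.correlations) <= 1e-12)
    assert np.allclose(np.linalg.norm(emb.coords_a, axis=1), 1.0)
    assert np.allclose(np.linalg.norm(emb.coords_b, axis=1), 1.0)
    with pytest.raises(ValueError, match="n_cc"):
        cca_embed(_space(np.ones((4, 3)), np.ones((4, 3))), n_cc=5)


# ---------------------------------------------------------------- MNN anchors


def test_mnn_self_copy_anchors_every_cell():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 6))
    X /= np.linalg.norm(X, axis=1, keepdims=True)
    anchors = find_mnn_anchors(_emb_from(X, X), k_anchor=3)
    self_pairs = {(f"a{i}", f"b{i}") for i in range(30)}
    got = set(zip(anchors.pairs["cell_a"], anchors.pairs["cell_b"]))
    assert self_pairs <= got


def test_mnn_saturation_when_k_equals_cell_count():
    rng = np.random.default_rng(5)
    A, B = rng.normal(size=(6, 3)), rng.normal(size=(5, 3))
    anchors = find_mnn_anchors(_emb_from(A, B), k_anchor=6)
    assert len(anchors) == 6 * 5  # every cross pair
    with pytest.raises(ValueError, match="k_anchor"):
        find_mnn_anchors(_emb_from(A, B), k_anchor=7)


def test_mnn_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(6)
    for _ in range(20):
        n_a, n_b = rng.integers(12, 101, size=2)
        k = int(rng.integers(2, 6))
        A = rng.normal(size=(n_a, 5))
        B = rng.normal(size=(n_b, 5))
        anchors = find_mnn_anchors(_emb_from(A, B), k_anchor=k)
        got = {
            (int(a[1:]), int(b[1:]))
            for a, b in zip(anchors.pairs["cell_a"], anchors.pairs["cell_b"])
        }
        assert got == brute_mnn_pairs(A, B, k)
        assert len(anchors) > 0
        assert anchors.pairs["score"].between(0, 1).all()


# -------------------------------------------------------------- label transfer


def test_transfer_empty_anchor_set():
    labels = pd.Series(["oRG"], index=["h1"])
    out = transfer_homolog_labels(_anchor_set([]), labels, "oRG")
    assert out.empty


def test_transfer_single_anchor():
    labels = pd.Series(["oRG", "tRG"], index=["h1", "h2"])
    out = transfer_homolog_labels(_anchor_set([("h1", "f1")]), labels, "oRG")
    assert list(out["cell_b"]) == ["f1"]
    assert out["labels"].iloc[0] == ["oRG"]
    assert not out["multi"].iloc[0]


def test_transfer_multi_label_flag():
    labels = pd.Series(["oRG", "tRG"], index=["h1", "h2"])
    anchors = _anchor_set([("h1", "f1"), ("h2", "f1")])
    out = transfer_homolog_labels(anchors, labels, ["oRG", "tRG"])
    assert out["labels"].iloc[0] == ["oRG", "tRG"]
    assert out["multi"].iloc[0]


def test_transfer_unknown_target_error():
    labels = pd.Series(["oRG"], index=["h1"])
    with pytest.raises(ValueError, match="unknown target"):
        transfer_homolog_labels(_anchor_set([("h1", "f1")]), labels, "nope")


# ------------------------------------------------------------------ correction


def test_integrate_correct_removes_constant_shift():
    rng = np.random.default_rng(7)
    A = rng.normal(size=(25, 4))
    shift = np.array([2.0, -1.0, 0.5, 3.0])
    B = A + shift
    emb = _emb_from(A, B)
    anchors = _anchor_set([(f"a{i}", f"b{i}") for i in range(25)])
    joint = integrate_correct(emb, anchors, k_weight=10, sd=1.0)
    corrected_b = joint.coords[25:]
    assert np.allclose(corrected_b, A, atol=1e-6)
    assert np.allclose(joint.coords[:25], A)  # A-cells unchanged


def test_integrate_correct_zero_shift_is_noop():
    rng = np.random.default_rng(8)
    A = rng.normal(size=(20, 3))
    emb = _emb_from(A, A)
    anchors = _anchor_set([(f"a{i}", f"b{i}") for i in range(20)])
    joint = integrate_correct(emb, anchors)
    assert np.allclose(joint.coords[20:], A, atol=1e-12)


def test_integrate_correct_empty_anchors_error():
    emb = _emb_from(np.ones((3, 2)), np.ones((3, 2)))
    with pytest.raises(ValueError, match="empty"):
        integrate_correct(emb, _anchor_set([]))


# ---------------------------------------------------------- cluster correlation


def _gs(cluster, genes, scores):
    return pd.DataFrame({"cluster": cluster, "gene": genes, "genescore": scores})


def test_correlation_identical_vectors():
    gs_a = _gs("X", ["g1", "g2", "g3"], [1.0, 2.0, 3.0])
    gs_b = _gs("Y", ["g1", "g2", "g3"], [1.0, 2.0, 3.0])
    entry = cluster_correlation(gs_a, gs_b, "X", "Y")
    assert entry["r"] == pytest.approx(1.0)


def test_correlation_reversed_vectors():
    gs_a = _gs("X", ["g1", "g2", "g3"], [1.0, 2.0, 3.0])
    gs_b = _gs("Y", ["g1", "g2", "g3"], [3.0, 2.0, 1.0])
    assert cluster_correlation(gs_a, gs_b, "X", "Y")["r"] == pytest.approx(-1.0)


def test_correlation_hand_computed_r_and_p():
    gs_a = _gs("X", ["g1", "g2", "g3", "g4"], [1.0, 2.0, 3.0, 4.0])
    gs_b = _gs("Y", ["g1", "g2", "g3", "g4"], [1.0, 3.0, 2.0, 4.0])
    entry = cluster_correlation(gs_a, gs_b, "X", "Y")
    r, p = manual_pearson([1, 2, 3, 4], [1, 3, 2, 4])
    assert r == pytest.approx(0.8)
    assert entry["r"] == pytest.approx(r)
    assert entry["p"] == pytest.approx(p, rel=1e-6)
    assert entry["n"] == 4


def test_correlation_undefined_below_min_shared():
    gs_a = _gs("X", ["g1", "g2"], [1.0, 2.0])
    gs_b = _gs("Y", ["g1", "g2"], [1.0, 2.0])
    entry = cluster_correlation(gs_a, gs_b, "X", "Y", min_shared=3)
    assert not entry["defined"]
    assert np.isnan(entry["r"])


def test_correlation_symmetric_under_swap():
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(8)]
    gs_a = _gs("X", genes, rng.normal(size=8))
    gs_b = _gs("Y", genes, rng.normal(size=8))
    e1 = cluster_correlation(gs_a, gs_b, "X", "Y")
    e2 = cluster_correlation(gs_b, gs_a, "Y", "X")
    assert e1["r"] == pytest.approx(e2["r"])
    assert e1["p"] == pytest.approx(e2["p"])


def test_correlation_matrix_covers_all_pairs():
    gs_a = pd.concat(
        [_gs("X1", ["g1", "g2", "g3"], [1, 2, 3]), _gs("X2", ["g1", "g2", "g3"], [3, 1, 2])]
    )
    gs_b = _gs("Y", ["g1", "g2", "g3"], [1.0, 2.0, 3.0])
    table = cluster_correlation_matrix(gs_a, gs_b)
    assert len(table) == 2
    assert set(table["cluster_a"]) == {"X1", "X2"}


# ------------------------------------------------------------- cluster scores


def test_cell_score_zero_for_silent_cell():
    vals = np.array([[0.0, 0.0], [1.0, 2.0]])
    norm = dense_norm(vals)
    gs = _gs("ref", ["g0", "g1"], [2.0, 3.0])
    s = cell_cluster_score(norm, gs, "ref")
    assert s.iloc[0] == 0.0
    assert s.iloc[1] == pytest.approx(1 * 2.0 + 2 * 3.0)


def test_cell_score_single_marker():
    norm = dense_norm(np.array([[1.0]]))
    gs = _gs("ref", ["g0"], [2.0])
    assert cell_cluster_score(norm, gs, "ref").iloc[0] == pytest.approx(2.0)


def test_cell_score_matches_dot_product_oracle():
    rng = np.random.default_rng(10)
    vals = rng.uniform(0, 3, size=(15, 8))
    norm = dense_norm(vals)
    genes = [f"g{j}" for j in range(8)]
    w = rng.normal(size=8)
    gs = _gs("ref", genes, w)
    s = cell_cluster_score(norm, gs, "ref")
    assert np.allclose(s.to_numpy(), vals @ w)


def test_cell_score_linearity():
    rng = np.random.default_rng(11)
    v1, v2 = rng.uniform(0, 2, size=(2, 6))
    gs = _gs("ref", [f"g{j}" for j in range(6)], rng.normal(size=6))
    s = cell_cluster_score(dense_norm(np.vstack([v1, v2, v1 + v2])), gs, "ref")
    assert s.iloc[2] == pytest.approx(s.iloc[0] + s.iloc[1])


def test_cell_score_skips_missing_markers_and_reports_coverage():
    norm = dense_norm(np.ones((3, 2)))
    gs = _gs("ref", ["g0", "g1", "ABSENT"], [1.0, 1.0, 99.0])
    s = cell_cluster_score(norm, gs, "ref")
    assert s.iloc[0] == pytest.approx(2.0)
    assert s.attrs["coverage"] == {
        "n_markers": 3,
        "n_present": 2,
        "missing": ["ABSENT"],
    }


def test_cell_score_zero_overlap_error():
    norm = dense_norm(np.ones((2, 2)))
    gs = _gs("ref", ["ABSENT"], [1.0])
    with pytest.raises(ValueError, match="no marker"):
        cell_cluster_score(norm, gs, "ref")
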