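"""Pairwise Spearman comparison, Welch test, and PCA embeddings."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from blastohet import (
    compare_intra_inter,
    generate_dataset,
    log_transform,
    normalize,
    pairwise_spearman,
    pca_embedding,
    size_factors,
    welch_statistic,
)

from conftest import make_config, tiny_count_matrix


def four_by_four_matrix(seed=0):
    rng = np.random.default_rng(seed)
    values = rng.poisson(50, size=(80, 16))
    embryos = [f"e{j // 4}" for j in range(16)]
    return tiny_count_matrix(values, embryos=embryos)


def test_pair_counts_four_embryos_four_cells():
    cm = four_by_four_matrix()
    nm = normalize(cm, size_factors(cm))
    comp = pairwise_spearman(nm, stage=4)
    assert comp.n_intra == 24  # 4 * C(4,2)
    assert comp.n_inter == 96  # C(16,2) - 24


def test_identical_cells_correlate_perfectly():
    base = np.random.default_rng(1).poisson(40, size=(60, 1))
    values = np.hstack([base, base, base + np.random.default_rng(2).poisson(5, size=(60, 1))])
    values = np.hstack([values, values[:, [2]]])
    cm = tiny_count_matrix(values, embryos=["e0", "e0", "e1", "e1"])
    nm = normalize(cm, size_factors(cm))
    # make ranks comparable: use raw counts as "normalized" values
    nm.values = values.astype(float)
    comp = pairwise_spearman(nm, stage=4)
    intra = comp.pairs[comp.pairs["kind"] == "intra"]
    rho_c0c1 = intra.loc[
        (intra["cell_a"] == "c0") & (intra["cell_b"] == "c1"), "rho"
    ].iloc[0]
    assert rho_c0c1 == pytest.approx(1.0, abs=1e-12)


def test_rho_matches_rank_then_pearson_oracle():
    cm = four_by_four_matrix(seed=5)
    nm = normalize(cm, size_factors(cm))
    comp = pairwise_spearman(nm, stage=4)
    vals = nm.values[nm.values.mean(axis=1) >= 10]
    for _, row in comp.pairs.sample(20, random_state=0).iterrows():
        a = nm.cell_ids.get_loc(row["cell_a"])
        b = nm.cell_ids.get_loc(row["cell_b"])
        ra, rb = stats.rankdata(vals[:, a]), stats.rankdata(vals[:, b])
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert row["rho"] == pytest.approx(oracle, abs=1e-12)


def test_spearman_invariant_to_monotone_per_cell_transform():
    cm = four_by_four_matrix(seed=6)
    nm = normalize(cm, size_factors(cm))
    comp1 = pairwise_spearman(nm, stage=4)
    keep = nm.values.mean(axis=1) >= 10  # freeze the gene filter
    # same genes, monotone-transformed values: ranks, hence rho, unchanged
    cm2 = tiny_count_matrix(
        cm.values[keep], embryos=list(cm.cells["embryo"]), batches=list(cm.cells["batch"])
    )
    nm2 = normalize(cm2, size_factors(cm2))
    nm2.values = nm.values[keep] ** 1.7 + 3.0  # monotone on >= 0
    comp2 = pairwise_spearman(nm2, stage=4, min_mean=-1.0)
    merged = comp1.pairs.merge(
        comp2.pairs, on=["cell_a", "cell_b"], suffixes=("_1", "_2")
    )
    assert len(merged) == len(comp1.pairs)
    np.testing.assert_allclose(merged["rho_1"], merged["rho_2"], atol=1e-12)


def test_welch_matches_textbook_oracle():
    intra = np.array([0.80, 0.90, 0.85])
    inter = np.array([0.70, 0.75, 0.72])
    t, p = welch_statistic(intra, inter)
    v1, v2 = intra.var(ddof=1), inter.var(ddof=1)
    se2 = v1 / 3 + v2 / 3
    t_ref = (intra.mean() - inter.mean()) / np.sqrt(se2)
    df_ref = se2**2 / ((v1 / 3) ** 2 / 2 + (v2 / 3) ** 2 / 2)
    p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
    assert t == pytest.approx(t_ref, rel=1e-12)
    assert p == pytest.approx(p_ref, rel=1e-12)
    # cross-check against scipy's implementation
    res = stats.ttest_ind(intra, inter, equal_var=False)
    assert t == pytest.approx(res.statistic, rel=1e-12)
    assert p == pytest.approx(res.pvalue, rel=1e-12)


def test_welch_identical_groups():
    x = np.array([0.5, 0.5, 0.5])
    t, p = welch_statistic(x, x.copy())
    assert (t, p) == (0.0, 1.0)


def test_planted_embryo_effects_raise_intra_correlation():
    cfg = make_config(
        n_embryos_per_stage={4: 8}, embryo_effect_sd=0.2, hvg_fraction=0.0, seed=0
    )
    m, _ = generate_dataset(cfg)
    nm = normalize(m, size_factors(m))
    comp = compare_intra_inter(nm, 4)
    assert comp.intra_values.mean() > comp.inter_values.mean()
    assert comp.welch_p < 0.05


def test_cross_batch_pairs_excluded():
    values = np.random.default_rng(0).poisson(50, size=(60, 8))
    embryos = ["e0", "e0", "e1", "e1", "e2", "e2", "e3", "e3"]
    batches = ["b1", "b1", "b1", "b1", "b2", "b2", "b2", "b2"]
    cm = tiny_count_matrix(values, embryos=embryos, batches=batches)
    nm = normalize(cm, size_factors(cm))
    comp = pairwise_spearman(nm, stage=4)
    assert comp.n_intra == 4
    assert comp.n_inter == 2 * 4  # C(4,2)-1 intra ... cross-embryo same batch only
    for _, row in comp.pairs.iterrows():
        a = cm.cells.loc[row["cell_a"]]
        b = cm.cells.loc[row["cell_b"]]
        assert a["batch"] == b["batch"]


def test_pca_duplicate_cells_get_identical_coordinates(small_normalized):
    _, _, nm = small_normalized
    lm = log_transform(nm)
    dup = np.hstack([lm.values, lm.values[:, :3]])
    lm2 = log_transform(nm)
    lm2.values = dup
    lm2.cells = pd.concat([lm.cells, lm.cells.iloc[:3].set_axis([f"dup{i}" for i in range(3)])])
    emb = pca_embedding(lm2, list(lm.gene_ids[:100]), n_components=3)
    np.testing.assert_allclose(
        emb.coordinates.iloc[:3].to_numpy(), emb.coordinates.iloc[-3:].to_numpy(), atol=1e-8
    )


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(3)
    values = rng.normal(size=(50, 20))
    lm_vals = values
    from blastohet import LogMatrix

    genes = pd.DataFrame(
        {"is_spikein": [False] * 50, "is_mito": [False] * 50},
        index=pd.Index([f"g{i}" for i in range(50)], name="gene_id"),
    )
    cells = pd.DataFrame(
        {
            "embryo": ["e"] * 20,
            "stage": [4] * 20,
            "batch": ["b"] * 20,
            "division_pattern": ["NA"] * 20,
        },
        index=pd.Index([f"c{j}" for j in range(20)], name="cell_id"),
    )
    lm = LogMatrix(values=lm_vals, genes=genes, cells=cells,
                        norm_means=pd.Series(np.ones(50), index=genes.index))
    emb = pca_embedding(lm, list(genes.index), n_components=4)
    X = lm_vals.T - lm_vals.T.mean(axis=0)
    C = X.T @ X / (X.shape[0] - 1)
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:4]
    oracle_coords = X @ v[:, order]
    got = emb.coordinates.to_numpy()
    for k in range(4):
        s = np.sign(np.dot(got[:, k], oracle_coords[:, k]))
        np.testing.assert_allclose(got[:, k], s * oracle_coords[:, k], atol=1e-8)
    # orthogonality of scores
    G = got.T @ got
    np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
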