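"""CV²-trend fitting, the chi-square variability test, BH adjustment,
and the embryo-effect regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from blastohet import (
    CV2Fit,
    generate_dataset,
    intra_embryo_hvg,
    log_transform,
    normalize,
    regress_embryo_effect,
    size_factors,
)
from blastohet.variability import fit_cv2_trend
from blastohet.variability import test_hvg as hvg_test

from conftest import make_config


def gene_with_moments(mean, cv2, m):
    """Vector of m values with exactly the requested mean and CV² (ddof=1)."""
    assert m % 2 == 0
    d = np.sqrt(cv2 * mean**2 * (m - 1) / m)
    return np.r_[np.full(m // 2, mean - d), np.full(m // 2, mean + d)]


def test_two_point_exact_interpolation():
    """Two eligible genes at (10, 0.2) and (100, 0.11) force a1=1, a0=0.1."""
    values = np.vstack([gene_with_moments(10, 0.2, 8), gene_with_moments(100, 0.11, 8)])
    fit = fit_cv2_trend(values=values, gene_ids=pd.Index(["a", "b"]), min_mean=5.0)
    assert fit.a1 == pytest.approx(1.0, abs=1e-9)
    assert fit.a0 == pytest.approx(0.1, abs=1e-9)


def test_ols_path_matches_lstsq_oracle():
    rng = np.random.default_rng(1)
    mus = rng.uniform(20, 500, 40)
    values = np.vstack([
        gene_with_moments(mu, 1.2 / mu + 0.05 + rng.uniform(0, 0.02), 10) for mu in mus
    ])
    fit = fit_cv2_trend(values=values, gene_ids=pd.Index([f"g{i}" for i in range(40)]))
    mean = values.mean(axis=1)
    cv2 = values.var(axis=1, ddof=1) / mean**2
    X = np.column_stack([np.ones(40), 1 / mean])
    coef, *_ = np.linalg.lstsq(X, cv2, rcond=None)
    if fit.method == "ols":
        assert fit.a0 == pytest.approx(coef[0], abs=1e-6)
        assert fit.a1 == pytest.approx(coef[1], abs=1e-6)
    else:
        # gamma-GLM solution must still sit close to the OLS one on clean data
        assert fit.a0 == pytest.approx(coef[0], abs=0.02)
        assert fit.a1 == pytest.approx(coef[1], rel=0.2)


def test_statistic_at_null_center():
    """A gene whose CV² equals the fitted value has T = m-1 and p ≈ 0.47."""
    m = 64
    g = gene_with_moments(100.0, 0.05, m)
    cv2 = g.var(ddof=1) / g.mean() ** 2
    fit = CV2Fit(a1=0.0, a0=cv2, genes_used=["g0"], min_mean=10.0, method="ols")
    res = hvg_test(values=g[None, :], gene_ids=pd.Index(["g0"]), fit=fit)
    row = res.table.iloc[0]
    assert row["stat"] == pytest.approx(m - 1, rel=1e-12)
    assert row["p"] == pytest.approx(stats.chi2.sf(m - 1, m - 1), rel=1e-12)
    assert row["p"] > 0.1 and not row["is_variable"]


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up, independent implementation."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * n / rank_from_top)
        adj[i] = prev
    return adj


@pytest.mark.parametrize("seed", range(5))
def test_bh_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=rng.integers(3, 80))
    from statsmodels.stats.multitest import multipletests

    np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1], bh_oracle(p), rtol=1e-12)


def test_low_mean_genes_get_nan_and_never_variable(small_normalized):
    _, _, nm = small_normalized
    fit = fit_cv2_trend(nm)
    res = hvg_test(nm, fit)
    low = res.table["mean"] <= fit.min_mean
    assert res.table.loc[low, "p"].isna().all()
    assert not res.table.loc[low, "is_variable"].any()
    # BH monotonicity
    ok = res.table.dropna(subset=["p"])
    assert (ok["p_adj"] >= ok["p"] - 1e-12).all()


def test_single_embryo_regression_is_identity(small_normalized):
    matrix, _, nm = small_normalized
    lm = log_transform(nm)
    lm.cells = lm.cells.copy()
    lm.cells["embryo"] = "only_one"
    adj = regress_embryo_effect(lm)
    np.testing.assert_allclose(adj.embryo_effects.to_numpy(), 0.0, atol=1e-12)
    np.testing.assert_allclose(adj.values, lm.values, atol=1e-12)


def test_embryo_means_equal_grand_mean_exactly(small_normalized):
    _, _, nm = small_normalized
    lm = log_transform(nm)
    adj = regress_embryo_effect(lm)
    lab = lm.cells["embryo"].to_numpy()
    for e in np.unique(lab):
        cols = lab == e
        np.testing.assert_allclose(
            adj.values[:, cols].mean(axis=1), adj.grand_mean.to_numpy(), atol=1e-10
        )
    # identifiability: sum_k n_k B_ik = 0
    n_k = pd.Series(lab).value_counts()
    weighted = adj.embryo_effects.mul(n_k, axis=1).sum(axis=1)
    np.testing.assert_allclose(weighted.to_numpy(), 0.0, atol=1e-9)


def test_adjustment_invariant_to_per_embryo_constants(small_normalized):
    """Per-embryo per-gene constants are absorbed entirely by the embryo
    effect: the centered adjusted values ĝ - A are unchanged (exact)."""
    _, _, nm = small_normalized
    lm = log_transform(nm)
    adj1 = regress_embryo_effect(lm)
    rng = np.random.default_rng(0)
    lab = lm.cells["embryo"].to_numpy()
    shifted = lm.values.copy()
    for e in np.unique(lab):
        shifted[:, lab == e] += rng.normal(0, 1, size=(lm.values.shape[0], 1))
    lm.values = shifted
    adj2 = regress_embryo_effect(lm)
    resid1 = adj1.values - adj1.grand_mean.to_numpy()[:, None]
    resid2 = adj2.values - adj2.grand_mean.to_numpy()[:, None]
    np.testing.assert_allclose(resid1, resid2, atol=1e-9)


def test_no_embryo_effect_keeps_variable_set():
    cfg = make_config(n_embryos_per_stage={4: 16}, embryo_effect_sd=0.0, seed=8)
    m, _ = generate_dataset(cfg)
    nm = normalize(m, size_factors(m))
    lm = log_transform(nm)
    from blastohet import call_hvg

    plain = call_hvg(nm).variable_genes
    within, _ = intra_embryo_hvg(lm)
    got = within.variable_genes
    union = plain | got
    jaccard = len(plain & got) / len(union) if union else 1.0
    assert jaccard >= 0.8


def test_inter_embryo_only_variability_removed_by_adjustment():
    """Between-embryo shifts inflate the unadjusted caller; removing the
    embryo effect collapses the call count by several fold (aggregated
    over seeds; a small residue remains because a finite number of
    embryos leaves per-gene heteroskedastic technical noise)."""
    from blastohet import call_hvg

    before = after = 0
    for seed in range(3):
        cfg = make_config(
            n_embryos_per_stage={4: 16}, embryo_effect_sd=0.2, hvg_fraction=0.0, seed=seed
        )
        m, _ = generate_dataset(cfg)
        nm = normalize(m, size_factors(m))
        before += len(call_hvg(nm).variable_genes)
        after += len(intra_embryo_hvg(log_transform(nm))[0].variable_genes)
    assert before >= 60
    assert after <= 0.33 * before


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=60))
def test_bh_property_random_p_vectors(p):
    """BH adjustment equals the brute-force step-up on arbitrary p-vectors
    and never decreases a p-value."""
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(adj, bh_oracle(p), rtol=1e-12, atol=1e-12)
    assert (adj >= np.asarray(p) - 1e-12).all()
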