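"""Latent-variable models against independent oracles and their invariants."""

import numpy as np
import pytest

import nmrfib as nf
from nmrfib.chemometrics import (
    coefficients,
    crossval_press,
    cv_anova,
    encode_groups,
    permutation_test,
    predict,
    q2_crossval,
    splot,
    vip,
)


def _labels(n_a, n_c):
    return ["A"] * n_a + ["C"] * n_c


# ---------------------------------------------------------------------------
# PCA


def test_pca_matches_covariance_eigendecomposition():
    """Brute-force oracle: eigenpairs of the sample covariance matrix."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 50))
    model = nf.fit_pca(X, n_components=5)
    Xc = X - X.mean(axis=0)
    evals, evecs = np.linalg.eigh(Xc.T @ Xc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    np.testing.assert_allclose(model.r2x_per_component,
                               evals[:5] / evals[evals > 1e-10].sum(), atol=1e-8)
    for a in range(5):
        v = evecs[:, a]
        got = model.loadings[:, a]
        assert abs(abs(v @ got)) == pytest.approx(1.0, abs=1e-8)  # same direction
        np.testing.assert_allclose(np.abs(got), np.abs(v), atol=1e-8)


def test_pca_rank_one_data():
    X = np.outer([1.0, 2.0, 3.0], [0.6, 0.8])
    model = nf.fit_pca(X, n_components=2)
    assert model.r2x_per_component[0] == pytest.approx(1.0, abs=1e-12)
    assert model.r2x_per_component[1] == pytest.approx(0.0, abs=1e-12)


def test_pca_isotropic_variance_split():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10_000, 2))
    model = nf.fit_pca(X, n_components=2)
    assert model.r2x_per_component[0] == pytest.approx(0.5, abs=0.02)
    assert model.r2x_per_component[1] == pytest.approx(0.5, abs=0.02)


def test_pca_constant_matrix_rejected():
    with pytest.raises(ValueError, match="zero total variance"):
        nf.fit_pca(np.ones((5, 3)), n_components=1)


def test_pca_loadings_orthonormal():
    rng = np.random.default_rng(2)
    model = nf.fit_pca(rng.normal(size=(15, 8)), n_components=4)
    gram = model.loadings.T @ model.loadings
    np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)


def test_pca_r2x_sums_to_one_at_full_rank():
    rng = np.random.default_rng(3)
    model = nf.fit_pca(rng.normal(size=(10, 4)), n_components=4)
    assert model.r2x_per_component.sum() == pytest.approx(1.0, abs=1e-8)


def test_pca_sample_reordering_invariance():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(12, 6))
    perm = rng.permutation(12)
    a = nf.fit_pca(X, 3)
    b = nf.fit_pca(X[perm], 3)
    np.testing.assert_allclose(b.scores, a.scores[perm], atol=1e-8)
    np.testing.assert_allclose(b.loadings, a.loadings, atol=1e-8)


# ---------------------------------------------------------------------------
# PLS-DA


def test_plsda_perfect_predictor_column():
    rng = np.random.default_rng(5)
    y, _ = encode_groups(_labels(10, 10))
    X = 0.1 * rng.normal(size=(20, 30))
    X[:, 0] = y
    model = nf.fit_plsda(X, _labels(10, 10), n_components=1, seed=0)
    assert model.r2y >= 0.99


def test_plsda_first_weight_proportional_to_xty():
    """Algebraic identity: component-1 weights align with X'y."""
    rng = np.random.default_rng(6)
    X = rng.normal(size=(15, 10))
    groups = _labels(8, 7)
    y, _ = encode_groups(groups)
    model = nf.fit_plsda(X, groups, n_components=2, seed=0, compute_q2=False)
    w1 = model.weights[:, 0]
    ref = (X - X.mean(0)).T @ (y - y.mean())
    ref /= np.linalg.norm(ref)
    assert abs(abs(w1 @ ref) - 1.0) < 1e-8
    np.testing.assert_allclose(np.abs(w1), np.abs(ref), atol=1e-8)


def test_plsda_component1_matches_sklearn():
    """Independent implementation cross-check on the first latent component."""
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    rng = np.random.default_rng(7)
    X = rng.normal(size=(18, 12))
    groups = _labels(9, 9)
    y, _ = encode_groups(groups)
    ours = nf.fit_plsda(X, groups, n_components=2, seed=0, compute_q2=False)
    ref = sklearn.PLSRegression(n_components=2, scale=False).fit(X, y)
    for a in range(2):
        cos = abs(np.dot(ours.weights[:, a], ref.x_weights_[:, a]))
        assert cos == pytest.approx(1.0, abs=1e-8)


def test_plsda_single_class_rejected():
    with pytest.raises(ValueError, match="2 classes"):
        nf.fit_plsda(np.random.default_rng(0).normal(size=(6, 3)), ["A"] * 6)


def test_plsda_null_q2_nonpositive():
    """Null-model property: pure-noise X gives Q2 <= 0 in most runs."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(40, 100))
        q2 = q2_crossval(X, _labels(20, 20),
                         {"method": "plsda", "n_components": 2,
                          "scaling": "center"}, seed=seed)
        hits += q2 <= 0
    assert hits >= 9


# ---------------------------------------------------------------------------
# OPLS-DA


def test_oplsda_zero_ortho_equals_one_component_plsda():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(16, 20))
    groups = _labels(8, 8)
    opls = nf.fit_oplsda(X, groups, n_ortho=0, compute_q2=False)
    pls = nf.fit_plsda(X, groups, n_components=1, compute_q2=False)
    np.testing.assert_allclose(opls.scores[:, 0], pls.scores[:, 0], atol=1e-8)
    np.testing.assert_allclose(opls.weights[:, 0], pls.weights[:, 0], atol=1e-8)


def test_oplsda_removes_orthogonal_factor():
    """A strong y-orthogonal factor degrades PLS but not OPLS separation."""
    rng = np.random.default_rng(9)
    n = 30
    groups = _labels(15, 15)
    y, _ = encode_groups(groups)
    signal = np.outer(y, rng.normal(size=40))
    ortho_factor = rng.normal(size=n)
    ortho_factor -= ortho_factor @ y * y / (y @ y)  # orthogonal to class
    confound = 8.0 * np.outer(ortho_factor, rng.normal(size=40))
    X = signal + confound + 0.1 * rng.normal(size=(n, 40))

    def separation(scores):
        a, c = scores[:15], scores[15:]
        pooled = np.sqrt((a.var(ddof=1) + c.var(ddof=1)) / 2)
        return abs(a.mean() - c.mean()) / pooled

    opls = nf.fit_oplsda(X, groups, n_ortho=1, compute_q2=False)
    pls = nf.fit_plsda(X, groups, n_components=1, compute_q2=False)
    assert separation(opls.scores[:, 0]) > separation(pls.scores[:, 0])


def test_oplsda_score_orthogonality():
    rng = np.random.default_rng(10)
    model = nf.fit_oplsda(rng.normal(size=(20, 30)), _labels(10, 10),
                          n_ortho=3, compute_q2=False)
    t = model.scores[:, 0]
    for a in range(3):
        assert abs(t @ model.ortho_scores[:, a]) < 1e-8


def test_oplsda_rank_exhaustion():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(6, 4))
    with pytest.raises(ValueError, match="rank"):
        nf.fit_oplsda(X, _labels(3, 3), n_ortho=10, compute_q2=False)


# ---------------------------------------------------------------------------
# S-plot / VIP / coefficients


def test_splot_against_direct_pearson():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(20, 15))
    model = nf.fit_oplsda(X, _labels(10, 10), compute_q2=False)
    sp = splot(model, X)
    t = model.scores[:, 0]
    for j in range(15):
        r = np.corrcoef(X[:, j], t)[0, 1]
        assert sp["pcorr"].iloc[j] == pytest.approx(r, abs=1e-10)


def test_splot_degenerate_variables():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(14, 6))
    X[:, 2] = 3.14  # constant column
    model = nf.fit_oplsda(X, _labels(7, 7), compute_q2=False)
    sp = splot(model, X)
    assert sp["zero_variance"].iloc[2]
    assert sp["pcorr"].iloc[2] == 0.0
    assert sp["p1"].iloc[2] == pytest.approx(0.0, abs=1e-12)
    # variable equal to the score itself correlates perfectly
    X2 = X.copy()
    X2[:, 0] = model.scores[:, 0]
    sp2 = splot(model, X2)
    assert sp2["pcorr"].iloc[0] == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("method,kwargs", [
    ("plsda", {"n_components": 3}),
    ("oplsda", {"n_ortho": 2}),
])
def test_vip_sum_of_squares_identity(method, kwargs):
    rng = np.random.default_rng(14)
    X = rng.normal(size=(24, 37))
    fit = nf.fit_plsda if method == "plsda" else nf.fit_oplsda
    model = fit(X, _labels(12, 12), compute_q2=False, **kwargs)
    v = vip(model)
    assert v.sum() >= 0
    assert (v ** 2).sum() == pytest.approx(37, rel=1e-10)


def test_vip_identical_copies_all_one():
    rng = np.random.default_rng(15)
    col = np.r_[rng.normal(1, 0.2, 8), rng.normal(-1, 0.2, 8)]
    X = np.tile(col[:, None], (1, 9))
    model = nf.fit_plsda(X, _labels(8, 8), n_components=1, compute_q2=False)
    np.testing.assert_allclose(vip(model), 1.0, atol=1e-10)


def test_vip_flags_informative_variable():
    rng = np.random.default_rng(16)
    groups = _labels(12, 12)
    y, _ = encode_groups(groups)
    X = rng.normal(size=(24, 100))
    X[:, 42] = y + 0.1 * rng.normal(size=24)
    model = nf.fit_plsda(X, groups, n_components=1, compute_q2=False)
    assert int(np.argmax(vip(model))) == 42


def test_prediction_consistent_with_training_fit():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(16, 9))
    groups = _labels(8, 8)
    for fit, kw in [(nf.fit_plsda, {"n_components": 2}),
                    (nf.fit_oplsda, {"n_ortho": 1})]:
        model = fit(X, groups, compute_q2=False, **kw)
        yhat = predict(model, X)
        y, _ = encode_groups(groups)
        r2 = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(model.r2y, abs=1e-8)


# ---------------------------------------------------------------------------
# cross-validation, CV-ANOVA, permutation test


def test_loo_q2_matches_brute_force():
    """Leave-one-out PRESS recomputed independently, fold by fold."""
    rng = np.random.default_rng(18)
    X = rng.normal(size=(6, 4))
    groups = _labels(3, 3)
    y, _ = encode_groups(groups)
    settings = {"method": "plsda", "n_components": 1, "scaling": "center"}
    got = q2_crossval(X, groups, settings, k_folds=6, seed=0)

    press = 0.0
    for i in range(6):
        tr = [j for j in range(6) if j != i]
        Xtr, ytr = X[tr], y[tr]
        xc, ym = Xtr.mean(0), ytr.mean()
        Xc, yc = Xtr - xc, ytr - ym
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        q = yc @ t / (t @ t)
        yhat = (X[i] - xc) @ w * q + ym
        press += (y[i] - yhat) ** 2
    expected = 1 - press / np.sum((y - y.mean()) ** 2)
    assert got == pytest.approx(expected, abs=1e-10)


def test_q2_high_for_encoded_signal():
    rng = np.random.default_rng(19)
    groups = _labels(10, 10)
    y, _ = encode_groups(groups)
    X = np.outer(y, rng.normal(size=20)) + 0.05 * rng.normal(size=(20, 20))
    q2 = q2_crossval(X, groups, {"method": "plsda", "n_components": 1,
                                 "scaling": "center"}, seed=0)
    assert q2 >= 0.9


def test_q2_deterministic_under_seed():
    rng = np.random.default_rng(20)
    X = rng.normal(size=(14, 10))
    groups = _labels(7, 7)
    s = {"method": "oplsda", "n_ortho": 1, "scaling": "center"}
    assert q2_crossval(X, groups, s, seed=5) == q2_crossval(X, groups, s, seed=5)


def test_crossval_fold_class_guard():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(5, 4))
    with pytest.raises(ValueError, match="class"):
        crossval_press(X, ["A", "A", "A", "A", "C"],
                       {"method": "plsda", "n_components": 1,
                        "scaling": "center"}, k_folds=5, seed=0)


def test_cv_anova_limits():
    assert cv_anova(1e-12, 10.0, 20, 2)[1] < 1e-10  # near-perfect prediction
    assert cv_anova(10.0, 10.0, 20, 2) == (0.0, 1.0)  # PRESS == SSY boundary
    assert cv_anova(12.0, 10.0, 20, 2)[1] == 1.0  # PRESS above SSY


def test_cv_anova_significant_on_separated_data(ac_model):
    press, ssy, _ = crossval_press(
        ac_model["X"], ac_model["groups"],
        {"method": "oplsda", "n_ortho": 1, "scaling": "uv"}, seed=17)
    F, p = cv_anova(press, ssy, len(ac_model["groups"]), 2)
    assert p < 0.05


def test_permutation_test_passes_on_separated_data(ac_model):
    report = permutation_test(ac_model["X"], ac_model["groups"],
                              {"method": "oplsda", "n_ortho": 1, "scaling": "uv"},
                              n_permutations=50, seed=17)
    assert report.passed
    assert report.original_q2 > 0.5
    assert np.all(report.permuted_corr < 1.0)
    assert report.permuted_q2.size == 50


def test_permutation_count_guard():
    rng = np.random.default_rng(22)
    with pytest.raises(ValueError, match="permutations"):
        permutation_test(rng.normal(size=(10, 5)), _labels(5, 5),
                         n_permutations=5, seed=0)


def test_supervised_models_invariant_to_sample_order():
    rng = np.random.default_rng(23)
    X = rng.normal(size=(14, 9))
    groups = np.array(_labels(7, 7))
    perm = rng.permutation(14)
    a = nf.fit_oplsda(X, groups, compute_q2=False)
    b = nf.fit_oplsda(X[perm], groups[perm], compute_q2=False)
    np.testing.assert_allclose(b.scores[:, 0], a.scores[perm, 0], atol=1e-8)
    np.testing.assert_allclose(b.weights, a.weights, atol=1e-8)
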