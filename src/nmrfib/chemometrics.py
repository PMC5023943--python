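"""Latent-variable modelling and validation, implemented from scratch.

PCA by singular value decomposition on mean-centered data; PLS-DA by the
NIPALS sequence with deflation (exact, non-iterative for a single response);
OPLS-DA by orthogonal-signal removal before a final one-predictive-component
PLS fit; S-plot and VIP diagnostics; class-stratified k-fold Q2; permutation
testing of R2Y/Q2 with the Q2-intercept pass rule; and CV-ANOVA on the
cross-validated predictive residuals.

Class membership is coded +1/-1 on a single response column. The default
variable treatment is mean-centering only; unit-variance ("uv") and Pareto
scaling are available behind the ``scaling`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_EPS = 1e-12


@dataclass
class LatentModel:
    """Fitted projection model (PCA, PLS-DA or OPLS-DA).

    Scores/loadings/weights are stored column-per-component in the
    preprocessed (centered, optionally scaled) variable space. For OPLS-DA
    the single predictive component lives in ``scores``/``loadings``/
    ``weights`` and the removed components in the ``ortho_*`` fields.
    """

    kind: str  # "PCA" | "PLSDA" | "OPLSDA"
    centering: np.ndarray
    scaling: str  # "center" | "uv" | "pareto"
    scale: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    r2x_per_component: np.ndarray
    weights: np.ndarray | None = None
    y_loadings: np.ndarray | None = None
    ortho_scores: np.ndarray | None = None
    ortho_loadings: np.ndarray | None = None
    ortho_weights: np.ndarray | None = None
    y_coding: dict[str, int] | None = None
    y_mean: float = 0.0
    r2y: float | None = None
    q2: float | None = None
    settings: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class ValidationReport:
    """Permutation-test and CV-ANOVA summary for one supervised model."""

    n_permutations: int
    permuted_r2: np.ndarray
    permuted_q2: np.ndarray
    permuted_corr: np.ndarray
    original_r2: float
    original_q2: float
    q2_intercept: float
    passed: bool
    cv_anova_F: float
    cv_anova_p: float


# ---------------------------------------------------------------------------
# preprocessing helpers


def _preprocess(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    if scaling == "center":
        scale = np.ones(X.shape[1])
    elif scaling in ("uv", "pareto"):
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd < _EPS, 1.0, sd)
        scale = sd if scaling == "uv" else np.sqrt(sd)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (X - center) / scale, center, scale


def encode_groups(groups) -> tuple[np.ndarray, dict[str, int]]:
    """Code a two-class label vector as +1/-1 (alphabetically first is +1)."""
    labels = [str(g) for g in groups]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {classes}")
    coding = {classes[0]: 1, classes[1]: -1}
    y = np.array([coding[g] for g in labels], dtype=float)
    counts = {c: labels.count(c) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"each class needs at least 2 members, got {counts}")
    return y, coding


def _fix_signs(*, loadings: np.ndarray, others: list[np.ndarray]) -> None:
    """Flip component signs so the largest-|loading| entry is positive."""
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            for arr in others:
                arr[:, a] *= -1


# ---------------------------------------------------------------------------
# PCA


def fit_pca(X: np.ndarray, n_components: int = 2) -> LatentModel:
    """PCA on mean-centered data via SVD.

    ``r2x_per_component`` holds the eigenvalue fractions of total centered
    variance; component signs follow the largest-|loading|-positive rule.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds rank bound "
                         f"{min(n - 1, p)}")
    Xc, center, scale = _preprocess(X, "center")
    total = float(np.sum(Xc ** 2))
    if total < _EPS:
        raise ValueError("zero total variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T.copy()
    _fix_signs(loadings=loadings, others=[scores])
    r2x = (s[:k] ** 2) / total
    return LatentModel(kind="PCA", centering=center, scaling="center", scale=scale,
                       scores=scores, loadings=loadings, r2x_per_component=r2x,
                       settings={"n_components": k})


# ---------------------------------------------------------------------------
# PLS / OPLS cores (operate on preprocessed X and centered y)


def _pls1_core(Xs: np.ndarray, yc: np.ndarray, n_components: int) -> dict:
    X = Xs.copy()
    y = yc.copy()
    W, T, P, q = [], [], [], []
    for _ in range(n_components):
        w = X.T @ y
        nw = float(np.linalg.norm(w))
        if nw < _EPS:
            raise ValueError("residual rank exhausted; fewer components available")
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < _EPS:
            raise ValueError("degenerate score vector; fewer components available")
        p = X.T @ t / tt
        qa = float(y @ t / tt)
        X = X - np.outer(t, p)
        y = y - qa * t
        W.append(w); T.append(t); P.append(p); q.append(qa)
    return {"W": np.column_stack(W), "T": np.column_stack(T),
            "P": np.column_stack(P), "q": np.array(q)}


def _pls1_predict(fit: dict, Xs_new: np.ndarray) -> np.ndarray:
    W, P, q = fit["W"], fit["P"], fit["q"]
    B = W @ np.linalg.solve(P.T @ W, q)
    return Xs_new @ B


def _opls_core(Xs: np.ndarray, yc: np.ndarray, n_ortho: int) -> dict:
    X = Xs.copy()
    w = X.T @ yc
    nw = float(np.linalg.norm(w))
    if nw < _EPS:
        raise ValueError("y carries no covariance with X")
    w /= nw
    Wo, To, Po = [], [], []
    for _ in range(n_ortho):
        t = X @ w
        tt = float(t @ t)
        p = X.T @ t / tt
        w_o = p - float(w @ p) * w
        n_o = float(np.linalg.norm(w_o))
        if n_o < _EPS * max(1.0, float(np.linalg.norm(p))):
            raise ValueError("residual rank exhausted: no orthogonal variation left")
        w_o /= n_o
        t_o = X @ w_o
        tto = float(t_o @ t_o)
        if tto < _EPS:
            raise ValueError("residual rank exhausted: degenerate orthogonal score")
        p_o = X.T @ t_o / tto
        X = X - np.outer(t_o, p_o)
        Wo.append(w_o); To.append(t_o); Po.append(p_o)
    t = X @ w
    tt = float(t @ t)
    p = X.T @ t / tt
    q = float(yc @ t / tt)
    stack = lambda v: np.column_stack(v) if v else np.zeros((Xs.shape[1], 0))
    return {"w": w, "t": t, "p": p, "q": q,
            "Wo": stack(Wo), "Po": stack(Po),
            "To": np.column_stack(To) if To else np.zeros((Xs.shape[0], 0))}


def _opls_predict(fit: dict, Xs_new: np.ndarray) -> np.ndarray:
    X = Xs_new.copy()
    for a in range(fit["Wo"].shape[1]):
        t_o = X @ fit["Wo"][:, a]
        X = X - np.outer(t_o, fit["Po"][:, a])
    return (X @ fit["w"]) * fit["q"]


def _fit_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                 settings: dict) -> np.ndarray:
    """Fit on the training block and predict the held-out response."""
    Xs, center, scale = _preprocess(Xtr, settings.get("scaling", "center"))
    ym = float(ytr.mean())
    yc = ytr - ym
    Xte_s = (Xte - center) / scale
    if settings["method"] == "plsda":
        fit = _pls1_core(Xs, yc, settings.get("n_components", 2))
        return _pls1_predict(fit, Xte_s) + ym
    elif settings["method"] == "oplsda":
        fit = _opls_core(Xs, yc, settings.get("n_ortho", 1))
        return _opls_predict(fit, Xte_s) + ym
    raise ValueError(f"unknown method {settings['method']!r}")


# ---------------------------------------------------------------------------
# supervised fits


def fit_plsda(X: np.ndarray, groups, n_components: int = 2,
              scaling: str = "center", k_folds: int = 7, seed: int = 0,
              compute_q2: bool = True) -> LatentModel:
    """Two-class PLS-DA by NIPALS with deflation.

    R2Y is the in-model fraction of coded-class variance explained; Q2 comes
    from class-stratified k-fold cross-validation of the full procedure.
    """
    X = np.asarray(X, dtype=float)
    y, coding = encode_groups(groups)
    Xs, center, scale = _preprocess(X, scaling)
    ym = float(y.mean())
    yc = y - ym
    fit = _pls1_core(Xs, yc, n_components)
    W, T, P = fit["W"], fit["T"], fit["P"]
    q2d = fit["q"][None, :].copy()
    _fix_signs(loadings=P, others=[W, T, q2d])  # flips w,t,p,q together
    q = q2d[0]
    yhat = T @ q
    ssy = float(yc @ yc)
    r2y = 1.0 - float((yc - yhat) @ (yc - yhat)) / ssy
    total = float(np.sum(Xs ** 2))
    r2x = np.array([float(T[:, a] @ T[:, a]) * float(P[:, a] @ P[:, a]) / total
                    for a in range(n_components)])
    settings = {"method": "plsda", "n_components": n_components, "scaling": scaling}
    q2 = q2_crossval(X, groups, settings, k_folds=k_folds, seed=seed) \
        if compute_q2 else None
    return LatentModel(kind="PLSDA", centering=center, scaling=scaling, scale=scale,
                       scores=T, loadings=P, weights=W, y_loadings=q,
                       y_coding=coding, y_mean=ym, r2x_per_component=r2x,
                       r2y=r2y, q2=q2, settings=settings)


def fit_oplsda(X: np.ndarray, groups, n_ortho: int = 1, scaling: str = "center",
               k_folds: int = 7, seed: int = 0,
               compute_q2: bool = True) -> LatentModel:
    """OPLS-DA: remove ``n_ortho`` y-orthogonal components, then fit one
    predictive PLS component. With ``n_ortho=0`` this equals 1-component
    PLS-DA. Predictive scores are orthogonal to every orthogonal score."""
    X = np.asarray(X, dtype=float)
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    y, coding = encode_groups(groups)
    Xs, center, scale = _preprocess(X, scaling)
    ym = float(y.mean())
    yc = y - ym
    fit = _opls_core(Xs, yc, n_ortho)
    t, p, w, q = fit["t"], fit["p"], fit["w"], fit["q"]
    j = int(np.argmax(np.abs(p)))
    if p[j] < 0:
        t, p, w, q = -t, -p, -w, -q
    yhat = q * t
    ssy = float(yc @ yc)
    r2y = 1.0 - float((yc - yhat) @ (yc - yhat)) / ssy
    total = float(np.sum(Xs ** 2))
    r2x_pred = float(t @ t) * float(p @ p) / total
    r2x_ortho = [float(fit["To"][:, a] @ fit["To"][:, a])
                 * float(fit["Po"][:, a] @ fit["Po"][:, a]) / total
                 for a in range(n_ortho)]
    settings = {"method": "oplsda", "n_ortho": n_ortho, "scaling": scaling}
    q2 = q2_crossval(X, groups, settings, k_folds=k_folds, seed=seed) \
        if compute_q2 else None
    return LatentModel(kind="OPLSDA", centering=center, scaling=scaling, scale=scale,
                       scores=t[:, None], loadings=p[:, None], weights=w[:, None],
                       y_loadings=np.array([q]),
                       ortho_scores=fit["To"], ortho_loadings=fit["Po"],
                       ortho_weights=fit["Wo"],
                       y_coding=coding, y_mean=ym,
                       r2x_per_component=np.array([r2x_pred] + r2x_ortho),
                       r2y=r2y, q2=q2, settings=settings)


def fit_pls2(X: np.ndarray, Y: np.ndarray, n_components: int = 2,
             scaling: str = "uv", max_iter: int = 500,
             tol: float = 1e-12) -> dict:
    """Multi-response PLS (NIPALS PLS2), used for biplot coordinates.

    Returns a dict with sample scores ``T``, X-weights ``W``, X-loadings
    ``P`` and Y-loadings ``Q`` (columns per component), plus the centers and
    scales of both blocks.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Xs, xc, xs = _preprocess(X, scaling)
    Ys, yc_, ys = _preprocess(Y, scaling)
    T, W, P, Q = [], [], [], []
    Xd, Yd = Xs.copy(), Ys.copy()
    for _ in range(n_components):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        t_old = None
        for _it in range(max_iter):
            w = Xd.T @ u
            w /= max(float(np.linalg.norm(w)), _EPS)
            t = Xd @ w
            qv = Yd.T @ t / max(float(t @ t), _EPS)
            u = Yd @ qv / max(float(qv @ qv), _EPS)
            if t_old is not None and float(np.linalg.norm(t - t_old)) < tol:
                break
            t_old = t
        tt = max(float(t @ t), _EPS)
        p = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, qv)
        T.append(t); W.append(w); P.append(p); Q.append(qv)
    out = {"T": np.column_stack(T), "W": np.column_stack(W),
           "P": np.column_stack(P), "Q": np.column_stack(Q),
           "x_center": xc, "x_scale": xs, "y_center": yc_, "y_scale": ys}
    _fix_signs(loadings=out["P"], others=[out["W"], out["T"], out["Q"]])
    return out


# ---------------------------------------------------------------------------
# diagnostics


def splot(model: LatentModel, X: np.ndarray):
    """S-plot coordinates for every variable against the predictive score.

    ``p1`` is the covariance of the centered variable with the predictive
    score (original variable units); ``pcorr`` the Pearson correlation.
    Zero-variance variables get ``pcorr = 0`` and ``zero_variance = True``.
    """
    import pandas as pd

    if model.kind not in ("PLSDA", "OPLSDA"):
        raise ValueError("S-plot requires a supervised model")
    X = np.asarray(X, dtype=float)
    t = model.scores[:, 0]
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    p1 = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    zero = sx < _EPS
    denom = np.where(zero, 1.0, sx) * max(st, _EPS)
    pcorr = np.where(zero, 0.0, p1 / denom)
    pcorr = np.clip(pcorr, -1.0, 1.0)
    return pd.DataFrame({"p1": p1, "pcorr": pcorr, "zero_variance": zero})


def vip(model: LatentModel) -> np.ndarray:
    """Variable importance in the projection over predictive components.

    ``VIP_j = sqrt(p * sum_a SSY_a (w_ja/|w_a|)^2 / sum_a SSY_a)`` with
    ``SSY_a = q_a^2 t_a't_a``; satisfies ``sum_j VIP_j^2 = p`` exactly.
    """
    if model.weights is None or model.y_loadings is None:
        raise ValueError("VIP requires a fitted supervised model")
    W, T, q = model.weights, model.scores, model.y_loadings
    p = W.shape[0]
    ssy = q ** 2 * np.einsum("ia,ia->a", T, T)
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn ** 2) @ ssy / ssy.sum())


def coefficients(model: LatentModel) -> np.ndarray:
    """Per-variable regression coefficients for the coded class response
    (in the model's preprocessed variable space)."""
    if model.kind == "PLSDA":
        return model.weights @ np.linalg.solve(
            model.loadings.T @ model.weights, model.y_loadings)
    if model.kind == "OPLSDA":
        return model.weights[:, 0] * model.y_loadings[0]
    raise ValueError("coefficients require a supervised model")


def predict(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted coded-class response for new samples."""
    Xs = (np.asarray(X_new, dtype=float) - model.centering) / model.scale
    if model.kind == "PLSDA":
        return Xs @ coefficients(model) + model.y_mean
    if model.kind == "OPLSDA":
        for a in range(0 if model.ortho_weights is None
                       else model.ortho_weights.shape[1]):
            t_o = Xs @ model.ortho_weights[:, a]
            Xs = Xs - np.outer(t_o, model.ortho_loadings[:, a])
        return (Xs @ model.weights[:, 0]) * model.y_loadings[0] + model.y_mean
    raise ValueError("prediction requires a supervised model")


# ---------------------------------------------------------------------------
# cross-validation and significance


def _stratified_folds(y: np.ndarray, k_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Class-stratified fold assignment (round-robin after a seeded shuffle)."""
    n = y.size
    if k_folds < 2 or k_folds > n:
        raise ValueError(f"k_folds must be in [2, {n}]")
    assign = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assign[idx] = (np.arange(idx.size) + offset) % k_folds
        offset += idx.size  # stagger classes across folds
    folds = [np.flatnonzero(assign == f) for f in range(k_folds)]
    for f, te in enumerate(folds):
        tr = np.setdiff1d(np.arange(n), te)
        if np.unique(y[tr]).size < 2:
            raise ValueError("cross-validation fold would lose an entire class")
    return [f for f in folds if f.size]


def crossval_press(X: np.ndarray, groups, settings: dict, k_folds: int = 7,
                   seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Held-out PRESS and total SSY for the given model settings.

    Returns ``(PRESS, SSY_total, residuals)`` with one cross-validated
    residual per sample. Deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y, _ = encode_groups(groups)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k_folds, rng)
    resid = np.empty_like(y)
    for te in folds:
        tr = np.setdiff1d(np.arange(y.size), te)
        yhat = _fit_predict(X[tr], y[tr], X[te], settings)
        resid[te] = y[te] - yhat
    press = float(resid @ resid)
    ssy = float(np.sum((y - y.mean()) ** 2))
    return press, ssy, resid


def q2_crossval(X: np.ndarray, groups, settings: dict, k_folds: int = 7,
                seed: int = 0) -> float:
    """Cross-validated Q2 = 1 - PRESS/SSY over class-stratified folds."""
    press, ssy, _ = crossval_press(X, groups, settings, k_folds=k_folds, seed=seed)
    return 1.0 - press / ssy


def cv_anova(press: float, ssy_total: float, n_samples: int,
             n_model_components: int) -> tuple[float, float]:
    """CV-ANOVA F-test on cross-validated predictive residuals.

    F = ((SSY - PRESS)/df1) / (PRESS/df2) with df1 = number of fitted model
    components (predictive + orthogonal) and df2 = N - df1 - 1. PRESS >=
    SSY (no cross-validated signal) returns (0, 1) rather than erroring.
    """
    df1 = max(1, int(n_model_components))
    df2 = n_samples - df1 - 1
    if df2 <= 0:
        raise ValueError("too few samples for CV-ANOVA degrees of freedom")
    if press >= ssy_total or press <= 0:
        return 0.0, 1.0
    F = ((ssy_total - press) / df1) / (press / df2)
    return float(F), float(stats.f.sf(F, df1, df2))


def _model_df(settings: dict) -> int:
    if settings["method"] == "plsda":
        return settings.get("n_components", 2)
    return 1 + settings.get("n_ortho", 1)


def permutation_test(X: np.ndarray, groups, settings: dict | None = None,
                     n_permutations: int = 200, k_folds: int = 7,
                     seed: int = 0) -> ValidationReport:
    """Permutation validation of a supervised model plus CV-ANOVA.

    The class vector is permuted ``n_permutations`` times (draws equal to
    the original labelling are redrawn); each permuted model's R2Y and Q2
    are recorded against |corr(y_perm, y)|. The Q2 intercept comes from the
    least-squares line through the permuted points and the original point at
    |corr| = 1. The model passes if the intercept is negative or every
    permuted Q2 lies below the original Q2.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    settings = settings or {"method": "oplsda", "n_ortho": 1, "scaling": "center"}
    X = np.asarray(X, dtype=float)
    y, _ = encode_groups(groups)
    rng = np.random.default_rng(seed)

    def _r2(yvec: np.ndarray) -> float:
        Xs, _, _ = _preprocess(X, settings.get("scaling", "center"))
        yc = yvec - yvec.mean()
        if settings["method"] == "plsda":
            fit = _pls1_core(Xs, yc, settings.get("n_components", 2))
            yhat = fit["T"] @ fit["q"]
        else:
            fit = _opls_core(Xs, yc, settings.get("n_ortho", 1))
            yhat = fit["q"] * fit["t"]
        return 1.0 - float((yc - yhat) @ (yc - yhat)) / float(yc @ yc)

    groups_arr = np.asarray([str(g) for g in groups])
    press, ssy, _ = crossval_press(X, groups_arr, settings, k_folds=k_folds,
                                   seed=seed)
    q2_orig = 1.0 - press / ssy
    r2_orig = _r2(y)
    F, p_cv = cv_anova(press, ssy, y.size, _model_df(settings))

    r2s, q2s, corrs = [], [], []
    for i in range(n_permutations):
        perm = rng.permutation(y.size)
        while np.array_equal(y[perm], y):
            perm = rng.permutation(y.size)
        yp = y[perm]
        corrs.append(abs(float(np.corrcoef(yp, y)[0, 1])))
        r2s.append(_r2(yp))
        q2s.append(q2_crossval(X, groups_arr[perm], settings, k_folds=k_folds,
                               seed=seed + 1 + i))
    corrs = np.array(corrs)
    q2s = np.array(q2s)
    xs = np.concatenate([corrs, [1.0]])
    ys_ = np.concatenate([q2s, [q2_orig]])
    slope, intercept = np.polyfit(xs, ys_, 1)
    # the intercept/ordering rules certify the permutation line; the q2 > 0
    # guard refuses to certify a model with no cross-validated predictivity
    # at all (without it, a null model whose permuted Q2 cloud sits below
    # zero would "validate" through the negative intercept alone)
    passed = bool((intercept < 0 or np.all(q2s < q2_orig)) and q2_orig > 0)
    return ValidationReport(
        n_permutations=n_permutations,
        permuted_r2=np.array(r2s), permuted_q2=q2s, permuted_corr=corrs,
        original_r2=r2_orig, original_q2=q2_orig,
        q2_intercept=float(intercept), passed=passed,
        cv_anova_F=F, cv_anova_p=p_cv)
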