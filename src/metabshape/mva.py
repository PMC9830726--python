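"""PLS-DA and OPLS-DA by NIPALS, with VIP scores and cross-validated R2/Q2.

Two-class group separation is modelled with orthogonal projections to latent
structures (O-PLS): variation in X orthogonal to the class vector is removed
component by component, then a single predictive PLS component is fitted to
the filtered matrix.  Multi-group overviews use PLS2 on the dummy-coded group
matrix.  Variable importance in projection (VIP) summarises each metabolite's
contribution to the predictive component(s); the mean of squared VIP over all
variables equals 1 by construction, so VIP > 1 marks above-average
contributors.

Model quality is reported as R2X / R2Y (training variance explained) and Q2
(cross-validated predictive fraction, ``1 - PRESS/SSY``), with stratified
venetian-blind fold assignment.  Q2 <= 0 means no predictive power; VIP
selection is still defined for such models.

All fits are deterministic: NIPALS starts from the dummy column of maximal
variance and every component's sign is fixed so that its largest-magnitude
x-loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500
_EPS = np.finfo(float).eps


# ---------------------------------------------------------------------------
# scaling and coding helpers
# ---------------------------------------------------------------------------

def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _fit_scaler(X: np.ndarray, scale: str) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scale == "uv":
        s = np.where(sd > 0, sd, 1.0)
    elif scale == "pareto":
        s = np.where(sd > 0, np.sqrt(sd), 1.0)
    elif scale == "none":
        s = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling {scale!r}; use 'uv', 'pareto' or 'none'")
    return mean, s


def _dummy_code(y) -> tuple[np.ndarray, list]:
    y = np.asarray(y)
    levels = sorted(pd.unique(y).tolist())
    if len(levels) < 2:
        raise ValueError("y must have at least 2 levels")
    Y = np.column_stack([(y == lv).astype(float) for lv in levels])
    return Y, levels


def _flip_sign(p: np.ndarray) -> float:
    """Sign making the largest-magnitude element of a loading vector positive."""
    j = int(np.argmax(np.abs(p)))
    return 1.0 if p[j] >= 0 else -1.0


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """NIPALS PLS2 discriminant model on dummy-coded groups."""

    weights: np.ndarray          # p x A, unit norm per component
    scores: np.ndarray           # n x A
    x_loadings: np.ndarray       # p x A
    y_loadings: np.ndarray       # g x A
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    levels: list
    feature_names: list[str]
    r2x: list[float]             # cumulative per component
    r2y: list[float]
    ssy_explained: list[float]   # Y sum of squares explained per component
    scale: str

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def transform(self, X) -> np.ndarray:
        X, _ = _as_array(X)
        Xs = (X - self.x_mean) / self.x_scale
        T = np.zeros((X.shape[0], self.n_components))
        for a in range(self.n_components):
            t = Xs @ self.weights[:, a]
            T[:, a] = t
            Xs = Xs - np.outer(t, self.x_loadings[:, a])
        return T

    def predict(self, X) -> np.ndarray:
        """Predict the centered dummy matrix (add back the column means)."""
        T = self.transform(X)
        return T @ self.y_loadings.T + self.y_mean

    def to_dict(self) -> dict:
        return {
            "kind": "plsda",
            "levels": [str(lv) for lv in self.levels],
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "r2x": self.r2x,
            "r2y": self.r2y,
        }


@dataclass
class OplsModel:
    """O-PLS-DA: orthogonal filtering plus one predictive component."""

    w_pred: np.ndarray           # p
    t_pred: np.ndarray           # n
    p_pred: np.ndarray           # p
    q_pred: float
    w_orth: np.ndarray           # p x k
    t_orth: np.ndarray           # n x k
    p_orth: np.ndarray           # p x k
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    levels: list
    feature_names: list[str]
    r2x: float
    r2y: float
    ssy_explained: float
    ssx_orth: np.ndarray         # X sum of squares captured per orth component
    scale: str
    q2: float | None = None

    @property
    def n_orth(self) -> int:
        return self.w_orth.shape[1]

    def _filter(self, X) -> np.ndarray:
        X, _ = _as_array(X)
        Xs = (X - self.x_mean) / self.x_scale
        for k in range(self.n_orth):
            t_o = Xs @ self.w_orth[:, k]
            Xs = Xs - np.outer(t_o, self.p_orth[:, k])
        return Xs

    def transform(self, X) -> np.ndarray:
        """Predictive scores for new observations."""
        return self._filter(X) @ self.w_pred

    def predict(self, X) -> np.ndarray:
        """Predicted class code on the 0/1 scale of ``levels[1]`` membership."""
        return self.transform(X) * self.q_pred + self.y_mean

    def to_dict(self) -> dict:
        return {
            "kind": "oplsda",
            "levels": [str(lv) for lv in self.levels],
            "feature_names": self.feature_names,
            "w_pred": self.w_pred.tolist(),
            "p_pred": self.p_pred.tolist(),
            "q_pred": self.q_pred,
            "w_orth": self.w_orth.tolist(),
            "p_orth": self.p_orth.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "r2x": self.r2x,
            "r2y": self.r2y,
            "q2": self.q2,
        }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_plsda(X, y, n_components: int, scale: str = "uv") -> PlsModel:
    """Fit a PLS2 discriminant model by NIPALS.

    ``y`` holds group labels (any hashable values, >= 2 levels); they are
    dummy-coded and centered internally.  ``n_components`` must not exceed the
    rank of the scaled X.
    """
    Xa, names = _as_array(X)
    Y, levels = _dummy_code(y)
    if Xa.shape[0] != Y.shape[0]:
        raise ValueError("X and y length mismatch")
    x_mean, x_scale = _fit_scaler(Xa, scale)
    Xs = (Xa - x_mean) / x_scale
    rank = np.linalg.matrix_rank(Xs)
    if n_components < 1 or n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    ssx0 = float(np.sum(Xs**2))
    ssy0 = float(np.sum(Yc**2))
    n, p = Xs.shape
    g = Yc.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((g, n_components))
    r2x, r2y, ssy_explained = [], [], []
    Xr, Yr = Xs.copy(), Yc.copy()
    for a in range(n_components):
        u = Yr[:, int(np.argmax(Yr.var(axis=0, ddof=0)))].copy()
        t = np.zeros(n)
        for _ in range(NIPALS_MAX_ITER):
            w = Xr.T @ u / max(u @ u, _EPS)
            w /= max(np.linalg.norm(w), _EPS)
            t_new = Xr @ w
            q = Yr.T @ t_new / max(t_new @ t_new, _EPS)
            u = Yr @ q / max(q @ q, _EPS)
            if np.linalg.norm(t_new - t) <= NIPALS_TOL * max(np.linalg.norm(t_new), _EPS):
                t = t_new
                break
            t = t_new
        tt = max(t @ t, _EPS)
        pvec = Xr.T @ t / tt
        sgn = _flip_sign(pvec)
        w, t, pvec, q = sgn * w, sgn * t, sgn * pvec, sgn * q
        ssy_before = float(np.sum(Yr**2))
        Xr = Xr - np.outer(t, pvec)
        Yr = Yr - np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pvec, q
        r2x.append(1.0 - float(np.sum(Xr**2)) / ssx0 if ssx0 > 0 else 0.0)
        r2y.append(1.0 - float(np.sum(Yr**2)) / ssy0 if ssy0 > 0 else 0.0)
        ssy_explained.append(ssy_before - float(np.sum(Yr**2)))
    return PlsModel(W, T, P, Q, x_mean, x_scale, y_mean, levels, names,
                    r2x, r2y, ssy_explained, scale)


def fit_oplsda(X, y, n_orth: int = 1, scale: str = "uv") -> OplsModel:
    """Fit a two-class O-PLS-DA model.

    ``n_orth`` class-orthogonal components are stripped from X, then a single
    predictive PLS component is fitted to the filtered matrix.  Predictive and
    orthogonal score vectors are exactly orthogonal by construction.
    """
    Xa, names = _as_array(X)
    y = np.asarray(y)
    levels = sorted(pd.unique(y).tolist())
    if len(levels) != 2:
        raise ValueError(f"OPLS-DA needs a binary y; got levels {levels}")
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    yc = (y == levels[1]).astype(float)
    y_mean = float(yc.mean())
    yv = yc - y_mean

    x_mean, x_scale = _fit_scaler(Xa, scale)
    Xs = (Xa - x_mean) / x_scale
    ssx0 = float(np.sum(Xs**2))
    ssy0 = float(yv @ yv)
    n, p = Xs.shape

    W_o = np.zeros((p, 0))
    T_o = np.zeros((n, 0))
    P_o = np.zeros((p, 0))
    ssx_orth = []
    Xr = Xs.copy()
    for _ in range(n_orth):
        w = Xr.T @ yv / max(yv @ yv, _EPS)
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xr @ w
        pvec = Xr.T @ t / max(t @ t, _EPS)
        w_o = pvec - (w @ pvec) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:      # no y-orthogonal variation left
            break
        w_o /= n_wo
        t_o = Xr @ w_o
        p_o = Xr.T @ t_o / max(t_o @ t_o, _EPS)
        sgn = _flip_sign(p_o)
        w_o, t_o, p_o = sgn * w_o, sgn * t_o, sgn * p_o
        Xr = Xr - np.outer(t_o, p_o)
        W_o = np.column_stack([W_o, w_o])
        T_o = np.column_stack([T_o, t_o])
        P_o = np.column_stack([P_o, p_o])
        ssx_orth.append(float(t_o @ t_o * (p_o @ p_o)))

    w = Xr.T @ yv / max(yv @ yv, _EPS)
    w /= max(np.linalg.norm(w), _EPS)
    t = Xr @ w
    tt = max(t @ t, _EPS)
    pvec = Xr.T @ t / tt
    q = float(yv @ t / tt)
    sgn = _flip_sign(pvec)
    w, t, pvec, q = sgn * w, sgn * t, sgn * pvec, sgn * q

    resid_y = yv - t * q
    r2y = 1.0 - float(resid_y @ resid_y) / ssy0 if ssy0 > 0 else 0.0
    ssx_pred = float(tt * (pvec @ pvec))
    r2x = (sum(ssx_orth) + ssx_pred) / ssx0 if ssx0 > 0 else 0.0
    return OplsModel(
        w, t, pvec, q, W_o, T_o, P_o, x_mean, x_scale, y_mean, levels, names,
        r2x, r2y, float(ssy0 - resid_y @ resid_y), np.asarray(ssx_orth), scale,
    )


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def vip(model: PlsModel | OplsModel, variant: str = "pred") -> pd.Series:
    """Variable importance in projection, as a Series over metabolite ids.

    ``VIP_j = sqrt(p * sum_a ssy_a (w_ja / ||w_a||)^2 / sum_a ssy_a)`` over the
    predictive components.  For O-PLS the default ``"pred"`` variant uses the
    predictive component only; ``"total"`` also folds in the orthogonal
    weights, weighted by the X sum of squares each captures.  Either way
    ``mean(VIP^2) = 1`` exactly.
    """
    if isinstance(model, PlsModel):
        if model.n_components < 1:
            raise ValueError("model has no fitted components")
        W = model.weights
        ssy = np.asarray(model.ssy_explained, dtype=float)
        if not np.any(ssy > 0):
            ssy = np.ones_like(ssy)
        p = W.shape[0]
        contrib = (W**2) @ ssy
        v = np.sqrt(p * contrib / ssy.sum())
        return pd.Series(v, index=model.feature_names, name="vip")
    if isinstance(model, OplsModel):
        p = model.w_pred.shape[0]
        if variant == "pred":
            v = np.sqrt(p) * np.abs(model.w_pred)
        elif variant == "total":
            ssy = model.ssy_explained if model.ssy_explained > 0 else 1.0
            weights_sq = model.w_pred**2 * ssy
            total = ssy
            for k in range(model.n_orth):
                weights_sq = weights_sq + model.w_orth[:, k] ** 2 * model.ssx_orth[k]
                total += model.ssx_orth[k]
            v = np.sqrt(p * weights_sq / total)
        else:
            raise ValueError(f"unknown VIP variant {variant!r}")
        return pd.Series(v, index=model.feature_names, name="vip")
    raise TypeError("vip() expects a fitted PlsModel or OplsModel")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, k_folds: int, seed: int) -> np.ndarray:
    """Venetian-blind fold assignment, stratified by class, shuffled by seed."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    counter = 0
    # a single counter across classes balances fold sizes and makes
    # k_folds == n exact leave-one-out
    for lv in pd.unique(y):
        for i in rng.permutation(np.flatnonzero(y == lv)):
            folds[i] = counter % k_folds
            counter += 1
    return folds


def cross_validate(X, y, model_spec: dict | None = None, k_folds: int = 7,
                   seed: int = 0) -> tuple[float, float]:
    """Return (R2Y, Q2) for a PLS-DA or O-PLS-DA model specification.

    ``model_spec`` defaults to ``{"kind": "oplsda", "n_orth": 1}``.  Q2 is
    ``1 - PRESS / SSY`` with out-of-fold predictions from models refit (scaling
    included) on each training fold; fold assignment is stratified and
    deterministic given ``seed``.
    """
    spec = {"kind": "oplsda", "n_orth": 1, "scale": "uv"}
    spec.update(model_spec or {})
    Xa, _ = _as_array(X)
    y = np.asarray(y)
    n = len(y)
    if not 2 <= k_folds <= n:
        raise ValueError("k_folds must be between 2 and n")

    def fit(Xtr, ytr):
        if spec["kind"] == "oplsda":
            return fit_oplsda(Xtr, ytr, n_orth=spec.get("n_orth", 1),
                              scale=spec.get("scale", "uv"))
        if spec["kind"] == "plsda":
            return fit_plsda(Xtr, ytr, n_components=spec.get("n_components", 2),
                             scale=spec.get("scale", "uv"))
        raise ValueError(f"unknown model kind {spec['kind']!r}")

    full = fit(Xa, y)
    r2y = full.r2y[-1] if isinstance(full, PlsModel) else full.r2y

    folds = _stratified_folds(y, k_folds, seed)
    if spec["kind"] == "oplsda":
        levels = sorted(pd.unique(y).tolist())
        ycode = (y == levels[1]).astype(float)
        press, ss = 0.0, float(np.sum((ycode - ycode.mean()) ** 2))
        for f in range(k_folds):
            test = folds == f
            if not test.any():
                continue
            if len(pd.unique(y[~test])) < 2:
                raise ValueError("a training fold lost a class; reduce k_folds")
            m = fit(Xa[~test], y[~test])
            yhat = m.predict(Xa[test])
            press += float(np.sum((ycode[test] - yhat) ** 2))
        return r2y, 1.0 - press / ss
    # PLS-DA: PRESS over the dummy-coded matrix
    Y, _ = _dummy_code(y)
    press, ss = 0.0, float(np.sum((Y - Y.mean(axis=0)) ** 2))
    for f in range(k_folds):
        test = folds == f
        if not test.any():
            continue
        if len(pd.unique(y[~test])) < 2:
            raise ValueError("a training fold lost a class; reduce k_folds")
        m = fit(Xa[~test], y[~test])
        press += float(np.sum((Y[test] - m.predict(Xa[test])) ** 2))
    return r2y, 1.0 - press / ss


def permutation_q2(X, y, model_spec: dict | None = None, n_perm: int = 100,
                   k_folds: int = 7, seed: int = 0) -> np.ndarray:
    """Q2 values under ``n_perm`` random permutations of the class labels.

    A sound model's observed Q2 should exceed this null distribution; on pure
    noise the permuted Q2 values average at or below zero.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    out = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        # keep fold assignment tied to the permuted labels but vary the stream
        _, q2 = cross_validate(X, yp, model_spec, k_folds=k_folds,
                               seed=int(rng.integers(2**31 - 1)))
        out[i] = q2
    return out
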