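"""Feature-selection statistics: transform gating, one-way ANOVA, PCA with
cross-validated Q2, OPLS-DA with VIP, and the joint VIP/p selection rule.

The selection rule keeps an FFA when its OPLS-DA variable importance in
projection exceeds 1.0 AND its one-way ANOVA p-value is below 0.05.  No
multiple-testing correction is applied by default (Benjamini-Hochberg is
available behind a flag), matching the original univariate treatment.

PCA is plain SVD on (optionally autoscaled) data.  OPLS-DA follows the
orthogonal-projections-to-latent-structures construction: orthogonal variation
is stripped from X component by component, then a single predictive PLS
component is fit against the one-hot class matrix.  With one predictive
component, VIP_j = sqrt(p) * |w_j| / ||w||, so the normalization identity
sum(VIP^2) = p holds exactly.  Q2 for both models comes from 7-fold
cross-validation over samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransformResult",
    "AnovaResult",
    "LatentModel",
    "transform_gate",
    "one_way_anova",
    "pca",
    "oplsda",
    "select_significant",
]

_TINY_P = 1e-300


@dataclass
class TransformResult:
    transform: str                 # 'none' | 'sqrt' | 'log10'
    groups: list[np.ndarray]       # transformed values
    forced: bool                   # True when no candidate passed and log10 was forced


@dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    transform: str
    group_means: np.ndarray
    group_sds: np.ndarray
    degenerate: bool = False
    forced_transform: bool = False


@dataclass
class LatentModel:
    """Fitted latent-variable model (PCA or OPLS-DA).

    ``r2x`` holds the per-component explained fraction of (scaled) X variance,
    predictive component first for OPLS-DA.  ``q2`` is the cross-validated
    predictive fraction; ``r2y``/``vip`` are OPLS-DA only.
    """

    scores: np.ndarray
    loadings: np.ndarray
    r2x: np.ndarray
    q2: float
    r2y: float | None = None
    vip: np.ndarray | None = None
    n_orthogonal: int = 0
    orthogonal_scores: np.ndarray | None = None
    weights: np.ndarray | None = None
    truncated: bool = False

    @property
    def r2x_cum(self) -> float:
        return float(np.sum(self.r2x))


# ---------------------------------------------------------------------------
# Transform gating and ANOVA
# ---------------------------------------------------------------------------

def _passes_gate(groups: list[np.ndarray], alpha: float) -> bool:
    # normality is tested on the pooled group-centered residuals (the ANOVA
    # assumption) rather than per group: one Shapiro test keeps the combined
    # false-rejection rate near alpha instead of compounding it per group
    resid = np.concatenate([g - g.mean() for g in groups])
    if stats.shapiro(resid).pvalue < alpha:
        return False
    return stats.levene(*groups).pvalue >= alpha


def transform_gate(groups: list[np.ndarray], alpha: float = 0.05,
                   shift: bool = False) -> TransformResult:
    """Pick the first of [none, sqrt, log10] under which the pooled
    group-centered residuals pass Shapiro-Wilk normality and the groups pass
    Levene homoscedasticity.

    If no candidate passes, log10 is used with ``forced=True``.  sqrt/log10 on
    non-positive values raises unless ``shift=True``, in which case values are
    shifted by ``1 - min`` first.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("need >= 3 values per group to test distributional fit")

    def apply(name: str) -> list[np.ndarray] | None:
        if name == "none":
            return groups
        lo = min(g.min() for g in groups)
        gs = groups
        if lo <= 0:
            if not shift:
                raise ValueError(
                    f"non-positive values: cannot apply {name} (pass shift=True to offset)"
                )
            gs = [g + (1.0 - lo) for g in groups]
        fn = np.sqrt if name == "sqrt" else np.log10
        return [fn(g) for g in gs]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns on tiny/tied samples
        for name in ("none", "sqrt", "log10"):
            cand = apply(name)
            if _passes_gate(cand, alpha):
                return TransformResult(name, cand, forced=False)
    return TransformResult("log10", apply("log10"), forced=True)


def one_way_anova(groups: list[np.ndarray], transform: str = "none",
                  forced_transform: bool = False) -> AnovaResult:
    """Classical one-way ANOVA (between/within decomposition, F test).

    ``transform`` is recorded, never applied here — callers gate first.  The
    degenerate zero-within-variance case with unequal means reports the
    smallest positive p and a ``degenerate`` flag.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    means = np.array([g.mean() for g in groups])
    sds = np.array([g.std(ddof=1) for g in groups])
    if ssw <= 0:
        if ssb <= 0:
            return AnovaResult(0.0, 1.0, dfb, dfw, transform, means, sds,
                               degenerate=True, forced_transform=forced_transform)
        return AnovaResult(np.inf, _TINY_P, dfb, dfw, transform, means, sds,
                           degenerate=True, forced_transform=forced_transform)
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), max(p, _TINY_P), dfb, dfw, transform, means, sds,
                       forced_transform=forced_transform)


def anova_with_gating(groups: list[np.ndarray], alpha: float = 0.05,
                      shift: bool = False) -> AnovaResult:
    """Convenience: transform_gate then one_way_anova on the transformed values."""
    tr = transform_gate(groups, alpha=alpha, shift=shift)
    return one_way_anova(tr.groups, transform=tr.transform, forced_transform=tr.forced)


# ---------------------------------------------------------------------------
# Latent-variable models
# ---------------------------------------------------------------------------

def _autoscale(X: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
    else:
        sd = np.ones(X.shape[1])
    return (X - mean) / sd, mean, sd


def _folds(n: int, n_folds: int) -> list[np.ndarray]:
    n_folds = min(n_folds, n)
    idx = np.arange(n)
    return [idx[f::n_folds] for f in range(n_folds)]


def pca(X: np.ndarray, n_components: int = 2, scale: bool = True,
        n_folds: int = 7) -> LatentModel:
    """PCA by SVD with per-component R2X and row-wise cross-validated Q2.

    Q2 = 1 - PRESS/SS where held-out rows (scaled with training statistics) are
    reconstructed from the training loadings.  Requesting more components than
    the rank truncates with ``truncated=True``.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA input must not contain missing values")
    rank = min(X.shape[0] - 1, X.shape[1])
    truncated = n_components > rank
    a = min(n_components, rank)

    Xs, _, _ = _autoscale(X, scale)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    total = (Xs ** 2).sum()
    r2x = (s[:a] ** 2) / total if total > 0 else np.zeros(a)
    scores = U[:, :a] * s[:a]
    loadings = Vt[:a].T

    press = ss = 0.0
    for test in _folds(X.shape[0], n_folds):
        train = np.setdiff1d(np.arange(X.shape[0]), test)
        if len(train) < 2:
            continue
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
        sd[sd == 0] = 1.0
        Ztr = (X[train] - mu) / sd
        Zte = (X[test] - mu) / sd
        _, _, Vt_tr = np.linalg.svd(Ztr, full_matrices=False)
        k = min(a, Vt_tr.shape[0])
        V = Vt_tr[:k].T
        press += ((Zte - Zte @ V @ V.T) ** 2).sum()
        ss += (Zte ** 2).sum()
    q2 = 1.0 - press / ss if ss > 0 else 0.0
    return LatentModel(scores=scores, loadings=loadings, r2x=r2x, q2=float(q2),
                       truncated=truncated)


def _one_hot(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes for a discriminant model")
    Y = (y[:, None] == classes[None, :]).astype(float)
    return Y, classes


def _first_weight(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    # dominant left singular vector of X'Y: the multi-Y PLS weight
    U, _, _ = np.linalg.svd(X.T @ Y, full_matrices=False)
    w = U[:, 0]
    # deterministic sign: largest-magnitude element positive
    j = np.argmax(np.abs(w))
    return w * np.sign(w[j]) if w[j] != 0 else w


def _opls_core(Xs: np.ndarray, Ys: np.ndarray, n_orth: int):
    """Strip n_orth orthogonal components, fit 1 predictive PLS component."""
    Xc = Xs.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_orth):
        w = _first_weight(Xc, Ys)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xc @ w_o
        denom = t_o @ t_o
        if denom < 1e-12:
            break
        p_o = Xc.T @ t_o / denom
        Xc = Xc - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    w = _first_weight(Xc, Ys)
    t = Xc @ w
    tt = t @ t
    p = Xc.T @ t / tt
    c = Ys.T @ t / tt
    return w, t, p, c, W_o, P_o, T_o


def _opls_filter(Xnew: np.ndarray, W_o, P_o) -> np.ndarray:
    Xc = Xnew.copy()
    for w_o, p_o in zip(W_o, P_o):
        t_o = Xc @ w_o
        Xc = Xc - np.outer(t_o, p_o)
    return Xc


def oplsda(X: np.ndarray, y: np.ndarray, n_orthogonal: int | None = None,
           max_orthogonal: int = 5, scale: bool = True,
           n_folds: int = 7) -> LatentModel:
    """OPLS-DA: one predictive component after orthogonal-variation removal.

    ``y`` holds class labels (one-hot encoded internally).  When
    ``n_orthogonal`` is None the count is chosen to maximize 7-fold
    cross-validated Q2 over 0..max_orthogonal.  ``vip`` satisfies
    sum(VIP^2) = n_variables exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("OPLS-DA input must not contain missing values")
    Y, classes = _one_hot(y)

    if n_orthogonal is None:
        best_k, best_q2 = 0, -np.inf
        for k in range(0, max_orthogonal + 1):
            q2 = _oplsda_q2(X, Y, k, scale, n_folds)
            if q2 > best_q2 + 1e-12:
                best_k, best_q2 = k, q2
        n_orthogonal = best_k
        q2 = best_q2
    else:
        q2 = _oplsda_q2(X, Y, n_orthogonal, scale, n_folds)

    Xs, _, _ = _autoscale(X, scale)
    Ys = Y - Y.mean(axis=0)
    w, t, p, c, W_o, P_o, T_o = _opls_core(Xs, Ys, n_orthogonal)

    total_x = (Xs ** 2).sum()
    r2x = [float((t @ t) * (p @ p) / total_x)]
    for t_o, p_o in zip(T_o, P_o):
        r2x.append(float((t_o @ t_o) * (p_o @ p_o) / total_x))
    Yhat = np.outer(t, c)
    r2y = 1.0 - ((Ys - Yhat) ** 2).sum() / (Ys ** 2).sum()

    vip = np.sqrt(X.shape[1]) * np.abs(w) / np.linalg.norm(w)
    return LatentModel(
        scores=t[:, None], loadings=p[:, None], r2x=np.array(r2x), q2=float(q2),
        r2y=float(r2y), vip=vip, n_orthogonal=len(W_o),
        orthogonal_scores=np.column_stack(T_o) if T_o else None, weights=w,
    )


def _oplsda_q2(X: np.ndarray, Y: np.ndarray, n_orth: int, scale: bool,
               n_folds: int) -> float:
    press = ss = 0.0
    for test in _folds(X.shape[0], n_folds):
        train = np.setdiff1d(np.arange(X.shape[0]), test)
        if len(np.unique(Y[train].argmax(axis=1))) < 2:
            continue
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
        sd[sd == 0] = 1.0
        ym = Y[train].mean(axis=0)
        Ztr, Zte = (X[train] - mu) / sd, (X[test] - mu) / sd
        Ytr, Yte = Y[train] - ym, Y[test] - ym
        w, _, _, cvec, W_o, P_o, _ = _opls_core(Ztr, Ytr, n_orth)
        Zte_f = _opls_filter(Zte, W_o, P_o)
        t_te = Zte_f @ w
        press += ((Yte - np.outer(t_te, cvec)) ** 2).sum()
        ss += (Yte ** 2).sum()
    return 1.0 - press / ss if ss > 0 else -np.inf


# ---------------------------------------------------------------------------
# Joint selection rule
# ---------------------------------------------------------------------------

def select_significant(p_values: pd.Series, vip: pd.Series,
                       p_threshold: float = 0.05, vip_threshold: float = 1.0,
                       fdr: bool = False) -> list[str]:
    """FFAs with VIP > 1.0 and ANOVA p < 0.05 (indices must coincide).

    ``fdr=True`` applies Benjamini-Hochberg to the p-values first; off by
    default to match the original univariate treatment (a known caveat).
    """
    if set(p_values.index) != set(vip.index):
        raise ValueError("p-value and VIP tables cover different FFA sets")
    p = p_values.sort_index()
    v = vip.sort_index()
    if fdr:
        order = np.argsort(p.to_numpy())
        m = len(p)
        adj = np.empty(m)
        ranked = p.to_numpy()[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        p = pd.Series(np.minimum(adj, 1.0), index=p.index)
    keep = (v > vip_threshold) & (p < p_threshold)
    return list(p.index[keep])
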