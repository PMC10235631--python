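"""Regularized neighborhood-component feature weighting and the ballot.

The weighting model maximizes F(w) = sum_i p_i - lambda * sum_j w_j^2 with
weighted L1 distance d_w(x_i, x_l) = sum_j w_j^2 |x_ij - x_lj| and soft
nearest-neighbor reference probabilities p_il = softmax(-d_w) over l != i;
p_i sums p_il over same-class neighbors.  Lambda is chosen by stratified
5-fold CV over a 20-point grid on [0, 2]/n; 60 seeded rounds are sorted by
final-fit loss, the best 30 vote 6,5,4,3,2,1 for their top-six features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from osteotex.errors import DataError, LabelError, ParameterError, SchemaError

FEATURE_NAMES = (
    "fd_mode",
    "fd_sigma",
    "fd_skewness",
    "fd_kurtosis",
    "fd_entropy",
    "lac_A",
    "lac_B",
    "ent_mode",
    "ent_sigma",
    "ent_skewness",
    "ent_kurtosis",
)

BALLOT_POINTS = (6, 5, 4, 3, 2, 1)


@dataclass
class NCAFit:
    """Learned feature weights at one regularization strength."""

    weights: np.ndarray
    lam: float
    loss: float  # expected leave-one-out error, 1 - mean(p_i)


@dataclass
class BallotResult:
    """Aggregated ballot over the retained fitting rounds."""

    scores: np.ndarray  # total ballot score per feature (canonical order)
    ranking: list[str]  # feature names by descending score
    selected: list[str]  # top-k of the ranking
    kept_losses: np.ndarray
    kept_weights: np.ndarray  # (n_kept, n_features)
    feature_names: tuple[str, ...]


def _softmax_probs(w: np.ndarray, absdiff: np.ndarray, same: np.ndarray):
    """Reference probabilities P (n, n) and same-class totals p_i."""
    dist = absdiff @ (w * w)  # (n, n)
    np.fill_diagonal(dist, np.inf)
    kern = np.exp(-dist)
    denom = kern.sum(axis=1, keepdims=True)
    denom = np.where(denom > 0, denom, 1.0)
    prob = kern / denom
    p_i = (prob * same).sum(axis=1)
    return prob, p_i


def _objective(w: np.ndarray, absdiff: np.ndarray, same: np.ndarray, lam: float):
    """F(w) and mean same-class probability (no gradient)."""
    _, p_i = _softmax_probs(w, absdiff, same)
    return float(p_i.sum() - lam * np.dot(w, w)), float(p_i.mean())


def _objective_and_grad(
    w: np.ndarray,
    absdiff: np.ndarray,
    same: np.ndarray,
    lam: float,
):
    """F(w), its gradient, and mean same-class probability.

    absdiff: (n, n, d) pairwise |x_ij - x_lj|; same: (n, n) same-class
    indicator with zero diagonal.
    """
    prob, p_i = _softmax_probs(w, absdiff, same)
    f_val = float(p_i.sum() - lam * np.dot(w, w))
    # dF/dw_j = 2 w_j * [ sum_i p_i sum_m P_im A_imj - sum_{l same} P_il A_ilj ] - 2 lam w_j
    weighted = (p_i[:, None] - same) * prob  # (n, n)
    inner = np.einsum("im,imj->j", weighted, absdiff, optimize=True)
    grad = 2.0 * w * inner - 2.0 * lam * w
    return f_val, grad, float(p_i.mean())


try:  # optional numba acceleration of the hot inner loops
    from numba import njit as _njit

    @_njit(cache=False, fastmath=True)
    def _nb_kernel(w, absdiff):
        # symmetric kernel matrix exp(-d_w); zero diagonal
        n, _, d = absdiff.shape
        w2 = w * w
        kern = np.zeros((n, n))
        for i in range(n):
            for l in range(i + 1, n):
                dist = 0.0
                for j in range(d):
                    dist += w2[j] * absdiff[i, l, j]
                k = np.exp(-dist)
                kern[i, l] = k
                kern[l, i] = k
        return kern

    @_njit(cache=False, fastmath=True)
    def _nb_objective(w, absdiff, same, lam):
        n, _, d = absdiff.shape
        kern = _nb_kernel(w, absdiff)
        p_sum = 0.0
        for i in range(n):
            denom = 0.0
            same_sum = 0.0
            for l in range(n):
                denom += kern[i, l]
                if same[i, l] > 0.0:
                    same_sum += kern[i, l]
            if denom > 0.0:
                p_sum += same_sum / denom
        reg = 0.0
        for j in range(d):
            reg += w[j] * w[j]
        return p_sum - lam * reg, p_sum / n

    @_njit(cache=False, fastmath=True)
    def _nb_objective_and_grad(w, absdiff, same, lam):
        n, _, d = absdiff.shape
        kern = _nb_kernel(w, absdiff)
        p = np.zeros(n)
        inv_denom = np.zeros(n)
        p_sum = 0.0
        for i in range(n):
            denom = 0.0
            same_sum = 0.0
            for l in range(n):
                denom += kern[i, l]
                if same[i, l] > 0.0:
                    same_sum += kern[i, l]
            if denom > 0.0:
                inv_denom[i] = 1.0 / denom
                p[i] = same_sum / denom
                p_sum += p[i]
        grad = np.zeros(d)
        for i in range(n):
            for l in range(i + 1, n):
                if kern[i, l] == 0.0:
                    continue
                # fold the symmetric (i,l) and (l,i) terms together
                c = (p[i] - same[i, l]) * kern[i, l] * inv_denom[i]
                c += (p[l] - same[l, i]) * kern[l, i] * inv_denom[l]
                for j in range(d):
                    grad[j] += c * absdiff[i, l, j]
        reg = 0.0
        for j in range(d):
            reg += w[j] * w[j]
        f_val = p_sum - lam * reg
        for j in range(d):
            grad[j] = 2.0 * w[j] * grad[j] - 2.0 * lam * w[j]
        return f_val, grad, p_sum / n

    _OBJ = _nb_objective
    _OBJ_GRAD = _nb_objective_and_grad
except ImportError:  # pragma: no cover - numba is optional
    _OBJ = _objective
    _OBJ_GRAD = _objective_and_grad


def ncfs_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    w0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    return_trace: bool = False,
):
    """Gradient-ascent fit of the regularized feature weights.

    Starts from the all-ones weight vector (or ``w0``), uses backtracking
    line search, and stops when the objective improves by less than
    ``tol`` or after ``max_iter`` accepted steps.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise DataError("feature matrix must be finite")
    if lam < 0:
        raise ParameterError("lambda must be nonnegative")
    n, d = X.shape
    absdiff = np.ascontiguousarray(np.abs(X[:, None, :] - X[None, :, :]))
    same = (y[:, None] == y[None, :]).astype(np.float64)
    np.fill_diagonal(same, 0.0)

    w = np.ones(d) if w0 is None else np.asarray(w0, dtype=np.float64).copy()
    f_val, grad, p_mean = _OBJ_GRAD(w, absdiff, same, lam)
    trace = [f_val]
    step = 1.0
    for _ in range(max_iter):
        gnorm2 = float(np.dot(grad, grad))
        if gnorm2 < 1e-18:
            break
        # first trial evaluates the gradient too: full steps are usually
        # accepted and then no second pass over the kernel matrix is needed
        alpha = step
        w_new = w + alpha * grad
        f_new, grad_new, p_new = _OBJ_GRAD(w_new, absdiff, same, lam)
        accepted = f_new > f_val + 1e-4 * alpha * gnorm2
        if not accepted:
            for _ in range(29):
                alpha *= 0.5
                w_new = w + alpha * grad
                f_new, p_new = _OBJ(w_new, absdiff, same, lam)
                if f_new > f_val + 1e-4 * alpha * gnorm2:
                    accepted = True
                    grad_new = None
                    break
        if not accepted:
            break
        delta = f_new - f_val
        w, f_val, p_mean = w_new, f_new, p_new
        if grad_new is None:
            _, grad, _ = _OBJ_GRAD(w, absdiff, same, lam)
        else:
            grad = grad_new
        trace.append(f_val)
        step = min(alpha * 2.0, 1e6)
        if abs(delta) < tol:
            break
    fit = NCAFit(weights=np.abs(w), lam=float(lam), loss=float(1.0 - p_mean))
    return (fit, trace) if return_trace else fit


def weighted_1nn_error(
    fit: NCAFit, X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, y_test: np.ndarray
) -> float:
    """Error rate of 1-NN under the fit's weighted L1 distance."""
    w2 = fit.weights**2
    dist = np.abs(X_test[:, None, :] - X_train[None, :, :]) @ w2
    pred = y_train[np.argmin(dist, axis=1)]
    return float(np.mean(pred != y_test))


def lambda_grid(n: int, n_points: int = 20) -> np.ndarray:
    """20 equally spaced regularization values on [0, 2] divided by n."""
    return np.linspace(0.0, 2.0, n_points) / n


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _coerce_table(table) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Accept a pandas FeatureTable (11 features + label) or (X, y)."""
    import pandas as pd

    if isinstance(table, pd.DataFrame):
        missing = [c for c in FEATURE_NAMES if c not in table.columns]
        if missing:
            raise SchemaError(f"feature table missing columns: {missing}")
        if "label" not in table.columns:
            raise SchemaError("feature table needs a 'label' column")
        X = table.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
        y = table["label"].to_numpy()
        return X, y, FEATURE_NAMES
    X, y = table
    X = np.asarray(X, dtype=np.float64)
    names = tuple(f"f{j}" for j in range(X.shape[1]))
    return X, np.asarray(y), names


def cv_select_lambda(
    table, seed: int, n_folds: int = 5, max_repartition: int = 10, return_curve: bool = False
):
    """Pick lambda by stratified K-fold CV of weighted 1-NN error.

    Ties resolve to the smaller lambda; the returned fit is trained on all
    (z-scored) data at the winning lambda.
    """
    X, y, _ = _coerce_table(table)
    n = X.shape[0]
    if n < 10:
        raise DataError("need at least 10 samples")
    if np.unique(y).size < 2:
        raise LabelError("need 2 classes")
    Xz = _zscore(X)
    grid = lambda_grid(n)

    for attempt in range(max_repartition):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) + attempt)
        folds = list(skf.split(Xz, y))
        if all(np.unique(y[tr]).size >= 2 and len(te) > 0 for tr, te in folds):
            break
    else:  # pragma: no cover - stratification nearly always succeeds
        raise LabelError("could not stratify folds without losing a class")

    losses = np.zeros(grid.size)
    for tr, te in folds:
        Xtr, ytr, Xte, yte = Xz[tr], y[tr], Xz[te], y[te]
        w0 = None
        for gi, lam in enumerate(grid):
            fit = ncfs_fit(Xtr, ytr, lam, w0=w0)
            w0 = fit.weights  # warm start along the lambda path
            losses[gi] += weighted_1nn_error(fit, Xtr, ytr, Xte, yte)
    losses /= len(folds)
    best = int(np.argmin(losses))  # first minimum -> smallest lambda on ties
    lam_star = float(grid[best])
    final = ncfs_fit(Xz, y, lam_star)
    if return_curve:
        return lam_star, final, losses
    return lam_star, final


def ballot_rank(
    table, n_rounds: int = 60, seed: int = 0, keep_best: int | None = None, top_k: int = 6
) -> BallotResult:
    """Repeated CV-selected fits vote for the most influential features.

    ``n_rounds`` independent rounds (seeded sub-streams) each produce a
    final fit; rounds are sorted by fitting loss and the best ``keep_best``
    retained.  In each retained round the six largest weights receive 6..1
    ballot points; totals rank the features (ties broken by larger mean
    weight, then canonical order).
    """
    X, y, names = _coerce_table(table)
    if keep_best is None:
        keep_best = max(1, n_rounds // 2)  # retain the better-fitting half
    if keep_best > n_rounds:
        raise ParameterError("keep_best cannot exceed n_rounds")
    round_seeds = np.random.SeedSequence(seed).generate_state(n_rounds) % (2**31 - 1)
    fits = []
    for rs in round_seeds:
        _, fit = cv_select_lambda((X, y), int(rs))
        fits.append(fit)
    order = np.argsort([f.loss for f in fits], kind="stable")[:keep_best]
    kept = [fits[i] for i in order]
    kept_weights = np.stack([f.weights for f in kept])
    d = X.shape[1]
    scores = np.zeros(d, dtype=np.int64)
    points = tuple(range(min(top_k, d), 0, -1))
    for wts in kept_weights:
        # descending weight, canonical order on ties (stable sort on -w)
        rank = np.argsort(-wts, kind="stable")
        for pos, pts in enumerate(points):
            scores[rank[pos]] += pts
    mean_w = kept_weights.mean(axis=0)
    final_order = sorted(
        range(d), key=lambda j: (-scores[j], -mean_w[j], j)
    )
    ranking = [names[j] for j in final_order]
    return BallotResult(
        scores=scores,
        ranking=ranking,
        selected=ranking[:top_k],
        kept_losses=np.array([f.loss for f in kept]),
        kept_weights=kept_weights,
        feature_names=names,
    )
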