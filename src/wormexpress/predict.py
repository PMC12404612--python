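"""Multi-gene trait prediction: cumulative-PC regression with permutation
nulls, greedy forward gene selection, train/test resampling of top-k
sets, and elastic-net leave-one-out prediction.

These analyses are deliberately plain multiple regressions (no replicate
random effect): the question is predictive power of aggregate expression
profiles, not inference on a single gene.  Test-set performance is the
squared Pearson correlation of predicted versus observed by default
(``r2_method="corr"``); 1 - SSE/SST is available as a config switch.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "pca_scores", "cumulative_pc_r2", "GreedyForwardRegressor",
    "greedy_forward_selection", "train_test_resampling", "elastic_net_loocv",
]

log = logging.getLogger("wormexpress")


# ----------------------------------------------------------------------
# PCA + cumulative R^2 curves
# ----------------------------------------------------------------------

def pca_scores(log_expr: pd.DataFrame) -> pd.DataFrame:
    """PC scores of worms from a genes x worms log-expression matrix.

    Genes are centered, components ordered by decreasing variance
    explained, and each component's sign fixed so its largest-magnitude
    gene loading is positive.  Returns worms x components.
    """
    M = log_expr.values.astype(float)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite values in expression matrix")
    n_worms = M.shape[1]
    if n_worms < 2:
        raise ValueError("need at least 2 worms for PCA")
    X = (M - M.mean(axis=1, keepdims=True)).T  # worms x genes, centered per gene
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    cols = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return pd.DataFrame(scores, index=log_expr.columns, columns=cols)


def _r2_sequence(Xcols: np.ndarray, y: np.ndarray) -> np.ndarray:
    """R^2 of intercept + first k columns, for k = 1..K, via Gram-Schmidt."""
    n, K = Xcols.shape
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst <= 0:
        raise ValueError("response has zero variance")
    Q = []  # orthonormal basis of centered predictors
    r2 = np.zeros(K)
    acc = 0.0
    for k in range(K):
        v = Xcols[:, k] - Xcols[:, k].mean()
        for q in Q:
            v = v - (q @ v) * q
        nv = np.linalg.norm(v)
        if nv > 1e-10 * max(1.0, np.linalg.norm(Xcols[:, k])):
            q = v / nv
            Q.append(q)
            acc += float((q @ yc) ** 2)
        r2[k] = min(acc / sst, 1.0)
    return r2


def cumulative_pc_r2(scores: pd.DataFrame, trait: pd.Series, k_max: int,
                     n_perm: int = 100, seed: int = 0) -> pd.DataFrame:
    """Observed and permutation-null R^2 of the first k PCs, k = 1..k_max.

    PCs enter the multiple regression in variance order; the null band
    comes from ``n_perm`` shuffles of the trait vector.  With k
    approaching n - 1 the curve rises to 1 even for shuffled traits.
    """
    S = scores.values.astype(float)
    y = trait.loc[scores.index].values.astype(float)
    if k_max > S.shape[1]:
        raise ValueError("k_max exceeds the number of components")
    obs = _r2_sequence(S[:, :k_max], y)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, k_max))
    for b in range(n_perm):
        null[b] = _r2_sequence(S[:, :k_max], rng.permutation(y))
    return pd.DataFrame({
        "k": np.arange(1, k_max + 1),
        "observed_r2": obs,
        "null_mean_r2": null.mean(axis=0),
        "null_sd_r2": null.std(axis=0, ddof=1),
    })


# ----------------------------------------------------------------------
# Greedy forward selection
# ----------------------------------------------------------------------

class GreedyForwardRegressor:
    """Forward stepwise gene selection maximizing multiple-regression R^2.

    At each step the gene giving the largest R^2 increment given the
    already-selected genes is added (ties within 1e-12 broken by
    lexicographic gene id).  Selection stops early if no remaining gene
    adds numerically independent variance.

    Attributes (after ``fit``)
    --------------------------
    selected_ : list of gene ids in selection order
    r2_path_ : cumulative R^2 after each addition
    coef_, intercept_ : OLS refit on the selected genes
    """

    def __init__(self, k: int = 10, tie_tol: float = 1e-12):
        self.k = k
        self.tie_tol = tie_tol

    def get_params(self, deep: bool = True):
        return {"k": self.k, "tie_tol": self.tie_tol}

    def set_params(self, **params):
        for key, v in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, v)
        return self

    def fit(self, X, y, feature_names=None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns) if feature_names is None else feature_names
            X = X.values
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, G = X.shape
        if feature_names is None:
            feature_names = [f"g{j}" for j in range(G)]
        names = np.asarray(feature_names, dtype=object)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        yc = y - y.mean()
        sst = float(yc @ yc)
        if sst <= 0:
            raise ValueError("trait variance is zero")

        Xc = X - X.mean(axis=0)
        resid_y = yc.copy()
        resid_X = Xc.copy()
        norm0 = np.linalg.norm(Xc, axis=0)
        active = np.ones(G, dtype=bool)
        selected_idx: list[int] = []
        r2_path: list[float] = []
        acc = 0.0
        for _ in range(min(self.k, G)):
            norms2 = np.einsum("ij,ij->j", resid_X, resid_X)
            # genes numerically dependent on the current design cannot add variance
            usable = active & (np.sqrt(norms2) > 1e-10 * np.maximum(norm0, 1.0))
            if not usable.any():
                break
            proj = resid_X.T @ resid_y
            gain = np.where(usable, proj ** 2 / np.where(norms2 > 0, norms2, 1.0), -np.inf)
            best = np.max(gain)
            if not np.isfinite(best) or best <= self.tie_tol * sst:
                break
            tied = np.where(gain >= best - self.tie_tol * sst)[0]
            j = min(tied, key=lambda t: str(names[t])) if len(tied) > 1 else int(tied[0])
            q = resid_X[:, j] / np.sqrt(norms2[j])
            acc += float((q @ resid_y) ** 2) / sst
            resid_y = resid_y - (q @ resid_y) * q
            resid_X = resid_X - np.outer(q, q @ resid_X)
            active[j] = False
            selected_idx.append(int(j))
            r2_path.append(min(acc, 1.0))

        self.selected_idx_ = selected_idx
        self.selected_ = [str(names[j]) for j in selected_idx]
        self.r2_path_ = np.asarray(r2_path)
        # OLS refit on the selected columns for prediction
        A = np.column_stack([np.ones(n), X[:, selected_idx]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        return self

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            X = X.values
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X[:, self.selected_idx_] @ self.coef_


def greedy_forward_selection(expr: pd.DataFrame, trait: pd.Series,
                             k_max: int) -> pd.DataFrame:
    """Ordered gene list and cumulative R^2 from forward selection.

    ``expr`` is genes x worms (any expression layer); the regression
    design is worms x genes.
    """
    y = trait.loc[expr.columns].values.astype(float)
    model = GreedyForwardRegressor(k=k_max).fit(expr.values.T, y,
                                                feature_names=list(expr.index))
    return pd.DataFrame({"step": np.arange(1, len(model.selected_) + 1),
                         "gene": model.selected_,
                         "cumulative_r2": model.r2_path_})


# ----------------------------------------------------------------------
# Train/test resampling
# ----------------------------------------------------------------------

def _r2(pred: np.ndarray, obs: np.ndarray, method: str = "corr") -> float:
    if method == "corr":
        if pred.std() == 0 or obs.std() == 0:
            return 0.0
        return float(np.corrcoef(pred, obs)[0, 1] ** 2)
    if method == "sse":
        sst = float(np.sum((obs - obs.mean()) ** 2))
        return 1.0 - float(np.sum((obs - pred) ** 2)) / sst if sst > 0 else 0.0
    raise ValueError(f"unknown r2 method {method!r}")


def train_test_resampling(expr: pd.DataFrame, trait: pd.Series,
                          n_iter: int = 500, k: int = 10, seed: int = 0,
                          r2_method: str = "corr") -> pd.DataFrame:
    """Repeated half-split validation of greedy top-k gene sets.

    Each iteration: randomly split worms into equal train/test halves,
    select k genes by forward selection on the train half, refit OLS
    coefficients on the train half, and score the test half.  Iterations
    are seeded independently from ``seed`` via numpy's SeedSequence
    spawning, so any single iteration is reproducible in isolation.
    """
    worms = list(expr.columns)
    n = len(worms)
    y_all = trait.loc[worms].values.astype(float)
    X_all = expr.values.T.astype(float)
    genes = list(expr.index)
    children = np.random.SeedSequence(seed).spawn(n_iter)
    rows = []
    for it in range(n_iter):
        rng = np.random.default_rng(children[it])
        perm = rng.permutation(n)
        half = n // 2
        tr, te = perm[:half], perm[half:]
        y_tr, y_te = y_all[tr], y_all[te]
        if y_tr.std() == 0 or y_te.std() == 0:
            log.info("resampling iteration %d skipped: degenerate trait split", it)
            continue
        model = GreedyForwardRegressor(k=k).fit(X_all[tr], y_tr,
                                                feature_names=genes)
        pred_te = model.predict(X_all[te])
        rows.append({
            "iteration": it,
            "train_worms": ";".join(worms[i] for i in sorted(tr)),
            "genes": ";".join(model.selected_),
            "train_r2": float(model.r2_path_[-1]) if len(model.r2_path_) else 0.0,
            "test_r2": _r2(pred_te, y_te, r2_method),
        })
    res = pd.DataFrame(rows)
    if len(res):
        res.attrs["median_test_r2"] = float(res["test_r2"].median())
        res.attrs["test_r2_range"] = (float(res["test_r2"].min()),
                                      float(res["test_r2"].max()))
    return res


# ----------------------------------------------------------------------
# Elastic-net LOOCV
# ----------------------------------------------------------------------

def elastic_net_loocv(expr: pd.DataFrame, trait: pd.Series,
                      alpha: float = 0.5, inner_cv: int = 5,
                      n_lambdas: int = 50, seed: int = 0) -> pd.DataFrame:
    """Leave-one-out elastic-net prediction of a trait from expression.

    For each worm, an elastic net (L1 ratio ``alpha`` = 0.5) is trained
    on the other n-1 worms — penalty weight chosen by ``inner_cv``-fold
    cross-validation within that training set, predictors standardized
    within the fold — and used to predict the held-out worm.  The
    held-out worm's trait never enters its own prediction.  The overall
    R^2 is the squared correlation of predicted versus observed.
    """
    from sklearn.linear_model import ElasticNetCV
    from sklearn.preprocessing import StandardScaler

    worms = list(expr.columns)
    n = len(worms)
    if n < 10:
        raise ValueError("need at least 10 worms for LOOCV")
    X = expr.values.T.astype(float)
    y = trait.loc[worms].values.astype(float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        log.warning("elastic net dropped %d zero-variance genes",
                    int((~keep).sum()))
        X = X[:, keep]
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        scaler = StandardScaler().fit(X[mask])
        model = ElasticNetCV(l1_ratio=alpha, cv=inner_cv,
                             alphas=n_lambdas, random_state=seed,
                             max_iter=5000)
        model.fit(scaler.transform(X[mask]), y[mask])
        preds[i] = model.predict(scaler.transform(X[i:i + 1]))[0]
    out = pd.DataFrame({"worm_id": worms, "observed": y, "predicted": preds})
    out.attrs["r2"] = _r2(preds, y, "corr")
    return out
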