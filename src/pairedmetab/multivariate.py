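"""Multivariate modelling: autoscaling, PCA, PLS-DA, validation, VIP.

PLS-DA is fitted by NIPALS on a single centred dummy response (the two
conditions coded 0/1).  With one response column the NIPALS inner loop is
exact in one pass per component:

    w_a = X_a' y / ||X_a' y||          (weights)
    t_a = X_a w_a                      (scores)
    p_a = X_a' t_a / (t_a' t_a)        (x-loadings)
    q_a = y' t_a / (t_a' t_a)          (y-loading)
    X_{a+1} = X_a - t_a p_a'           (deflation)

Model quality is summarised by cumulative R2X/R2Y, predictive ability by
k-fold cross-validated Q2Y = 1 - PRESS / SS_tot, and over-fitting risk by a
label-permutation test.  Variable influence is scored with VIP, normalised
so the mean squared VIP over modelled variables is 1; VIP > 1 conventionally
flags discriminating variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import ConcentrationTable

__all__ = [
    "ScaledMatrix",
    "PcaModel",
    "PlsdaModel",
    "ValidationReport",
    "autoscale",
    "scale_matrix",
    "fit_pca",
    "fit_plsda",
    "cross_validate_q2",
    "permutation_test",
    "vip_scores",
    "plot_scores",
]


@dataclass
class ScaledMatrix:
    """Column-standardised data plus the statistics to undo it."""

    X: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    columns: list[str]
    sample_labels: list[str] = field(default_factory=list)


def _scale_params(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = sds < 1e-12
    if scaling == "none":
        return np.zeros_like(means), np.ones_like(sds)
    if scaling == "center":
        return means, np.ones_like(sds)
    if scaling == "pareto":
        s = np.sqrt(np.where(constant, 1.0, sds))
        return means, s
    if scaling == "auto":
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant column(s) left centred "
                "with unit divisor",
                stacklevel=3,
            )
        return means, np.where(constant, 1.0, sds)
    raise ValueError(f"unknown scaling {scaling!r}")


def scale_matrix(
    X: np.ndarray, columns: list[str], scaling: str = "auto",
    sample_labels: list[str] | None = None,
) -> ScaledMatrix:
    """Standardise columns of a raw matrix (sample sd, ddof=1)."""
    X = np.asarray(X, dtype=float)
    means, sds = _scale_params(X, scaling)
    return ScaledMatrix(
        X=(X - means) / sds,
        column_means=means,
        column_sds=sds,
        columns=list(columns),
        sample_labels=list(sample_labels or []),
    )


def autoscale(table: ConcentrationTable, scaling: str = "auto") -> ScaledMatrix:
    """Autoscale a concentration table (centre + unit sample variance)."""
    if len(table.data) < 3:
        raise ValueError("autoscaling needs at least 3 samples")
    return scale_matrix(
        table.data.to_numpy(),
        table.metabolites,
        scaling=scaling,
        sample_labels=[f"{k.animal_id}_{k.condition.value}" for k in table.samples],
    )


# -- PCA -------------------------------------------------------------------


@dataclass
class PcaModel:
    scores: np.ndarray          # samples x k
    loadings: np.ndarray        # variables x k, columns orthonormal
    explained_fraction: np.ndarray
    cumulative_r2x: np.ndarray
    columns: list[str]


def _fix_component_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    # deterministic orientation: largest-|loading| entry of each component positive
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1.0
            scores[:, a] *= -1.0


def fit_pca(scaled: ScaledMatrix, k: int) -> PcaModel:
    """PCA of the scaled matrix via SVD; components ordered by variance."""
    X = scaled.X
    max_k = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in [1, {max_k}], got {k}")
    U, s, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    eig = s**2
    total = eig.sum()
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T.copy()
    _fix_component_signs(loadings, scores)
    frac = eig[:k] / total
    return PcaModel(
        scores=scores,
        loadings=loadings,
        explained_fraction=frac,
        cumulative_r2x=np.cumsum(frac),
        columns=list(scaled.columns),
    )


# -- PLS-DA ----------------------------------------------------------------

CLASS_CODING = {"before": 0.0, "after": 1.0}


def encode_response(y: np.ndarray) -> np.ndarray:
    """Dummy-code condition labels to a centred numeric response."""
    labels = np.asarray([str(v).lower() for v in np.asarray(y).ravel()])
    classes = set(labels)
    if not classes <= set(CLASS_CODING):
        raise ValueError(f"labels must be 'before'/'after', got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    coded = np.array([CLASS_CODING[v] for v in labels])
    return coded - coded.mean()


@dataclass
class PlsdaModel:
    n_components: int
    weights: np.ndarray     # J x A
    x_loadings: np.ndarray  # J x A
    y_loadings: np.ndarray  # A
    scores: np.ndarray      # n x A
    r2x: np.ndarray         # cumulative, per component
    r2y: np.ndarray         # cumulative, per component
    columns: list[str]
    y_mean: float

    @property
    def coefficients(self) -> np.ndarray:
        """Regression vector b with y_hat = X b (X scaled, y centred)."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(X_scaled) @ self.coefficients + self.y_mean


def fit_plsda(
    scaled: ScaledMatrix, y, n_components: int = 5
) -> PlsdaModel:
    """Fit PLS-DA by single-response NIPALS with X deflation."""
    X = scaled.X.copy()
    y_raw = np.asarray(
        [CLASS_CODING[str(v).lower()] for v in np.asarray(y).ravel()]
    )
    if len(set(y_raw)) < 2:
        raise ValueError("both classes must be present")
    if len(y_raw) != X.shape[0]:
        raise ValueError("y length must match number of rows")
    y_mean = y_raw.mean()
    yc = y_raw - y_mean
    n, J = X.shape
    rank = np.linalg.matrix_rank(scaled.X)
    A = int(n_components)
    if A < 1:
        raise ValueError("n_components must be >= 1")
    if A > rank:
        warnings.warn(
            f"n_components={A} exceeds rank {rank}; truncated", stacklevel=2
        )
        A = rank
    ss_x = float((scaled.X**2).sum())
    ss_y = float((yc**2).sum())
    W = np.zeros((J, A))
    P = np.zeros((J, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    r2x = np.zeros(A)
    r2y = np.zeros(A)
    x_explained = 0.0
    for a in range(A):
        w = X.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            A = a
            break
        w /= norm
        t = X @ w
        tt = float(t @ t)
        p = X.T @ t / tt
        q_a = float(yc @ t) / tt
        X = X - np.outer(t, p)
        W[:, a], P[:, a], T[:, a], q[a] = w, p, t, q_a
        x_explained += tt * float(p @ p)
        r2x[a] = x_explained / ss_x
        fitted = T[:, : a + 1] @ q[: a + 1]
        r2y[a] = 1.0 - float(((yc - fitted) ** 2).sum()) / ss_y
    if A == 0:
        raise ValueError("no y-variance to model")
    return PlsdaModel(
        n_components=A,
        weights=W[:, :A],
        x_loadings=P[:, :A],
        y_loadings=q[:A],
        scores=T[:, :A],
        r2x=r2x[:A],
        r2y=r2y[:A],
        columns=list(scaled.columns),
        y_mean=y_mean,
    )


# -- validation ------------------------------------------------------------


@dataclass
class ValidationReport:
    q2y: float
    folds: int
    permutation_p: float
    permutation_stats: np.ndarray
    observed_stat: float
    seed: int


def cross_validate_q2(
    X: np.ndarray,
    y,
    n_components: int = 5,
    folds: int = 10,
    seed: int = 0,
    scaling: str = "auto",
    columns: list[str] | None = None,
) -> float:
    """Stratified k-fold cross-validated Q2Y.

    Each fold is held out once; the model (including the column scaling) is
    re-estimated on the training rows only, the held-out dummy responses are
    predicted, and squared errors accumulate into PRESS.
    Q2Y = 1 - PRESS / SS_tot with SS_tot about the overall response mean.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray([str(v).lower() for v in np.asarray(y).ravel()])
    y_num = np.array([CLASS_CODING[v] for v in labels])
    n = len(y_num)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds {n} samples")
    if folds > int(pd.Series(labels).value_counts().min()):
        raise ValueError("cannot stratify: a class has fewer members than folds")
    cols = columns or [f"v{j}" for j in range(X.shape[1])]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    for train, test in skf.split(X, labels):
        if len(set(labels[train])) < 2:  # pragma: no cover - stratification prevents it
            raise ValueError("training fold with a single class")
        scaled_tr = scale_matrix(X[train], cols, scaling=scaling)
        model = fit_plsda(scaled_tr, labels[train], n_components=n_components)
        X_te = (X[test] - scaled_tr.column_means) / scaled_tr.column_sds
        pred = model.predict(X_te)
        press += float(((y_num[test] - pred) ** 2).sum())
    ss_tot = float(((y_num - y_num.mean()) ** 2).sum())
    return 1.0 - press / ss_tot


def permutation_test(
    X: np.ndarray,
    y,
    n_components: int = 5,
    B: int = 1000,
    seed: int = 0,
    scaling: str = "auto",
    statistic: str = "r2y",
    folds: int = 10,
    pairs: np.ndarray | None = None,
    columns: list[str] | None = None,
) -> tuple[float, np.ndarray]:
    """Label-permutation test of the fitted PLS-DA model.

    The class labels are permuted B times and the model refitted each time
    at the same component count; the p-value is (#{null >= observed} + 1) /
    (B + 1), so it can never be exactly zero.  ``statistic`` is the refit
    R2Y by default ('q2y' uses cross-validated Q2Y instead — slower).  With
    ``pairs`` given (one pair id per row), permutation flips labels within
    each pair, the strict paired-design null.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    labels = np.asarray([str(v).lower() for v in np.asarray(y).ravel()])
    cols = columns or [f"v{j}" for j in range(X.shape[1])]
    rng = np.random.default_rng(seed)

    def stat(lab: np.ndarray, fold_seed: int) -> float:
        if statistic == "r2y":
            scaled = scale_matrix(X, cols, scaling=scaling)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_plsda(scaled, lab, n_components=n_components)
            return float(model.r2y[-1])
        if statistic == "q2y":
            return cross_validate_q2(
                X, lab, n_components=n_components, folds=folds,
                seed=fold_seed, scaling=scaling, columns=cols,
            )
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = stat(labels, int(rng.integers(2**31 - 1)))
    null = np.empty(B)
    for b in range(B):
        if pairs is None:
            perm = rng.permutation(labels)
        else:
            perm = labels.copy()
            for pid in np.unique(pairs):
                idx = np.flatnonzero(pairs == pid)
                if rng.random() < 0.5:
                    perm[idx] = perm[idx][::-1]
        null[b] = stat(perm, int(rng.integers(2**31 - 1)))
    p = (int((null >= observed).sum()) + 1) / (B + 1)
    return p, null


def validate_plsda(
    X: np.ndarray,
    y,
    n_components: int = 5,
    folds: int = 10,
    B: int = 1000,
    seed: int = 0,
    scaling: str = "auto",
    columns: list[str] | None = None,
) -> ValidationReport:
    """Convenience wrapper: Q2Y plus permutation test in one report."""
    q2 = cross_validate_q2(
        X, y, n_components=n_components, folds=folds, seed=seed,
        scaling=scaling, columns=columns,
    )
    scaled = scale_matrix(np.asarray(X, float), columns or [], scaling=scaling)
    observed = float(
        fit_plsda(scaled, y, n_components=n_components).r2y[-1]
    )
    p, null = permutation_test(
        X, y, n_components=n_components, B=B, seed=seed, scaling=scaling,
        columns=columns,
    )
    return ValidationReport(
        q2y=q2, folds=folds, permutation_p=p, permutation_stats=null,
        observed_stat=observed, seed=seed,
    )


# -- VIP -------------------------------------------------------------------


def vip_scores(model: PlsdaModel) -> pd.Series:
    """Variable Importance in the Projection per modelled variable.

    VIP_j = sqrt( J * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a ) where
    SSY_a = q_a^2 t_a' t_a is the response variance captured by component a.
    The normalisation forces sum_j VIP_j^2 = J.
    """
    W = model.weights
    J = W.shape[0]
    ssy = model.y_loadings**2 * (model.scores**2).sum(axis=0)
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    w_norm2 = (W**2).sum(axis=0)
    w_norm2[w_norm2 == 0] = 1.0
    contrib = (W**2 / w_norm2) @ ssy
    vip = np.sqrt(J * contrib / total)
    return pd.Series(vip, index=model.columns, name="vip")


def plot_scores(scores: np.ndarray, labels, ax=None, title: str = ""):
    """Scatter of the first two score vectors, coloured by condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray([str(v) for v in labels])
    for lab, color in zip(sorted(set(labels)), ("tab:blue", "tab:red")):
        m = labels == lab
        ax.scatter(scores[m, 0], scores[m, 1], label=lab, color=color, s=30)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    return ax
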