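"""Morphospace ordination and discriminant classification.

Three related tools live here:

* covariance-matrix PCA of the pooled (extant + fossil) shape data, giving
  an unsupervised morphospace;
* canonical linear discriminant analysis (LDA) trained on extant taxa
  grouped by locomotor mode, with fossils superimposed afterwards through
  the extant-trained axes;
* regularized discriminant analysis (RDA) in the two-parameter
  (γ, λ) family that interpolates between quadratic (per-group covariance),
  linear (pooled covariance) and spherical rules, used to predict fossil
  locomotor mode, with (γ, λ) chosen by cross-validated or bootstrap
  misclassification.

The regularization follows the standard two-stage shrinkage: group scatter
is first blended with the pooled scatter (λ), then the result is shrunk
toward a scaled identity (γ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.model_selection import StratifiedKFold

from .io import ValidationError
from .preprocess import ShapeMatrix


def _as_frame(shape) -> pd.DataFrame:
    return shape.values if isinstance(shape, ShapeMatrix) else shape


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude coefficient positive (in place)."""
    for j in range(vectors.shape[1]):
        k = int(np.argmax(np.abs(vectors[:, j])))
        if vectors[k, j] < 0:
            vectors[:, j] = -vectors[:, j]
    return vectors


@dataclass
class Ordination:
    """Scores, axis coefficients and per-axis variance fractions.

    ``kind`` is ``"PCA"`` or ``"DA"``.  For PCA the axes are orthonormal
    eigenvectors of the sample covariance matrix; for DA they are canonical
    coefficient vectors scaled to unit pooled within-group variance, and
    ``variance_fraction`` is the proportion-of-trace eigenvalue share.
    ``center`` is the grand mean subtracted before projection (for DA, the
    extant training grand mean).
    """

    scores: pd.DataFrame
    axes: pd.DataFrame  # variables × axes
    variance_fraction: np.ndarray
    kind: str
    center: pd.Series

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if np.any(vf < -1e-12) or abs(vf.sum() - 1.0) > 1e-10:
            raise ValidationError("variance fractions must be >= 0 and sum to 1")
        self.variance_fraction = vf


@dataclass
class DiscriminantModel:
    """Gaussian discriminant rule with two-parameter covariance shrinkage."""

    group_labels: list[str]
    group_means: pd.DataFrame  # groups × variables
    pooled_cov: np.ndarray
    group_covs: dict[str, np.ndarray]
    gamma: float
    lam: float
    priors: pd.Series
    error_estimates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0 and 0.0 <= self.lam <= 1.0):
            raise ValidationError("gamma and lambda must lie in [0, 1]")
        if abs(float(self.priors.sum()) - 1.0) > 1e-10:
            raise ValidationError("priors must sum to 1")


def pca_covariance(shape) -> Ordination:
    """PCA by eigendecomposition of the sample covariance matrix (ddof=1).

    Axes are sorted by descending eigenvalue with the sign convention that
    each eigenvector's largest-magnitude coefficient is positive; scores are
    the centered data projected on the eigenvectors; variance fractions are
    eigenvalue shares.
    """
    X = _as_frame(shape)
    if X.isna().to_numpy().any():
        raise ValidationError("missing cells in ordination input")
    if len(X) < 2:
        raise ValidationError("PCA requires at least 2 taxa")
    vals = X.to_numpy(dtype=float)
    center = vals.mean(axis=0)
    S = np.cov(vals, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    eigval, eigvec = linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = _fix_signs(eigvec[:, order])
    scores = (vals - center) @ eigvec
    names = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    return Ordination(
        scores=pd.DataFrame(scores, index=X.index, columns=names),
        axes=pd.DataFrame(eigvec, index=X.columns, columns=names),
        variance_fraction=eigval / eigval.sum(),
        kind="PCA",
        center=pd.Series(center, index=X.columns),
    )


def _scatter_matrices(vals: np.ndarray, codes: np.ndarray, g: int):
    """Within-group scatter W (sum over groups), between scatter B, counts."""
    d = vals.shape[1]
    W = np.zeros((d, d))
    B = np.zeros((d, d))
    grand = vals.mean(axis=0)
    counts = np.zeros(g, dtype=int)
    means = np.zeros((g, d))
    for k in range(g):
        Xk = vals[codes == k]
        counts[k] = len(Xk)
        means[k] = Xk.mean(axis=0)
        C = Xk - means[k]
        W += C.T @ C
        dk = means[k] - grand
        B += counts[k] * np.outer(dk, dk)
    return W, B, counts, means


def lda_fit(shape, labels: pd.Series):
    """Canonical LDA on extant taxa grouped by locomotor mode.

    Returns ``(Ordination, DiscriminantModel)``.  Canonical axes are
    eigenvectors of (pooled within-group covariance)⁻¹ × between-group
    scatter, scaled so pooled within-group variance along each axis is 1;
    g groups yield g−1 axes and the variance fractions are the eigenvalue
    shares (proportion of trace).  If the within-group scatter is singular
    (variables ≥ residual degrees of freedom) a pseudo-inverse fallback is
    engaged with a warning.
    """
    X = _as_frame(shape)
    labels = pd.Series(labels).reindex(X.index)
    if labels.isna().any():
        raise ValidationError("every training row needs a group label")
    groups = sorted(labels.unique())
    g = len(groups)
    if g < 2:
        raise ValidationError("need at least 2 groups")
    codes = labels.map({lb: k for k, lb in enumerate(groups)}).to_numpy()
    vals = X.to_numpy(dtype=float)
    N, d = vals.shape
    counts = np.bincount(codes, minlength=g)
    if counts.min() < 2:
        raise ValidationError("every group needs at least 2 members")
    W, B, counts, means = _scatter_matrices(vals, codes, g)
    Sw = W / (N - g)
    n_axes = g - 1
    try:
        if d >= N - g:
            raise linalg.LinAlgError("within-scatter rank-deficient")
        eigval, eigvec = linalg.eigh(B, Sw)
        order = np.argsort(eigval)[::-1][:n_axes]
        eigval = np.clip(eigval[order], 0.0, None)
        A = eigvec[:, order]  # already a' Sw a = 1 for scipy's generalized eigh
    except linalg.LinAlgError:
        warnings.warn(
            "singular within-group scatter: using pseudo-inverse fallback",
            RuntimeWarning,
            stacklevel=2,
        )
        M = linalg.pinvh(Sw) @ B
        ev, V = linalg.eig(M)
        order = np.argsort(ev.real)[::-1][:n_axes]
        eigval = np.clip(ev.real[order], 0.0, None)
        A = V[:, order].real
        for j in range(A.shape[1]):
            s = A[:, j] @ Sw @ A[:, j]
            if s > 0:
                A[:, j] /= np.sqrt(s)
    A = _fix_signs(A)
    grand = vals.mean(axis=0)
    scores = (vals - grand) @ A
    names = [f"DF{i + 1}" for i in range(n_axes)]
    ord_ = Ordination(
        scores=pd.DataFrame(scores, index=X.index, columns=names),
        axes=pd.DataFrame(A, index=X.columns, columns=names),
        variance_fraction=eigval / eigval.sum() if eigval.sum() > 0 else eigval,
        kind="DA",
        center=pd.Series(grand, index=X.columns),
    )
    model = rda_fit(X, labels, gamma=0.0, lam=1.0)
    try:
        pred, _ = classify(model, X)
        model.error_estimates["apparent"] = float((pred != labels).mean())
    except ValidationError:
        # pooled covariance singular (variables >= residual dof): the
        # canonical axes above still exist via the pseudo-inverse, but the
        # Gaussian classification rule does not
        model.error_estimates["apparent"] = float("nan")
    return ord_, model


def da_project(ordination: Ordination, newdata) -> pd.DataFrame:
    """Superimpose new taxa (e.g. fossils) onto an extant-trained space.

    Rows are centered with the training grand mean and projected on the
    trained axes; pushing the training data through reproduces its fitted
    scores exactly.
    """
    X = _as_frame(newdata)
    if list(X.columns) != list(ordination.axes.index):
        raise ValidationError("variable mismatch with ordination axes")
    scores = (X.to_numpy(dtype=float) - ordination.center.to_numpy()) @ (
        ordination.axes.to_numpy()
    )
    return pd.DataFrame(scores, index=X.index, columns=ordination.axes.columns)


def rda_fit(
    shape,
    labels: pd.Series,
    gamma: float,
    lam: float,
    priors: str | pd.Series = "proportional",
) -> DiscriminantModel:
    """Fit the (γ, λ) regularized Gaussian discriminant model.

    Group covariance: Σ_k(λ) = [(1−λ)·W_k + λ·W] / [(1−λ)·(n_k−1) + λ·(N−g)]
    with W_k the group scatter and W the pooled scatter; then
    Σ_k(λ, γ) = (1−γ)·Σ_k(λ) + γ·(tr Σ_k(λ)/d)·I.  γ=0, λ=1 is the linear
    (pooled) rule; γ=0, λ=0 the quadratic rule; γ=1 a spherical rule.
    """
    X = _as_frame(shape)
    labels = pd.Series(labels).reindex(X.index)
    groups = sorted(labels.unique())
    g = len(groups)
    codes = labels.map({lb: k for k, lb in enumerate(groups)}).to_numpy()
    vals = X.to_numpy(dtype=float)
    N, d = vals.shape
    W, _, counts, means = _scatter_matrices(vals, codes, g)
    group_covs = {}
    for k, lb in enumerate(groups):
        Xk = vals[codes == k]
        C = Xk - means[k]
        Wk = C.T @ C
        denom = (1 - lam) * (counts[k] - 1) + lam * (N - g)
        if denom <= 0:
            raise ValidationError("degenerate regularization denominator")
        Sk = ((1 - lam) * Wk + lam * W) / denom
        Sk = (1 - gamma) * Sk + gamma * (np.trace(Sk) / d) * np.eye(d)
        group_covs[lb] = Sk
    if isinstance(priors, str):
        if priors == "proportional":
            pr = pd.Series(counts / N, index=groups)
        elif priors == "uniform":
            pr = pd.Series(np.full(g, 1.0 / g), index=groups)
        else:
            raise ValueError(f"unknown priors mode {priors!r}")
    else:
        pr = priors.reindex(groups)
        pr = pr / pr.sum()
    return DiscriminantModel(
        group_labels=groups,
        group_means=pd.DataFrame(means, index=groups, columns=X.columns),
        pooled_cov=W / (N - g),
        group_covs=group_covs,
        gamma=float(gamma),
        lam=float(lam),
        priors=pr,
    )


def classify(model: DiscriminantModel, newdata):
    """Gaussian log-discriminant classification with posteriors.

    Returns ``(labels, posteriors)``: posteriors ∝ prior × Gaussian density
    under each group's regularized covariance, normalized to sum to 1 per
    row; the label is the argmax with a first-index tie-break.
    """
    X = _as_frame(newdata)
    if list(X.columns) != list(model.group_means.columns):
        raise ValidationError("variable mismatch with discriminant model")
    vals = X.to_numpy(dtype=float)
    n = len(vals)
    logd = np.empty((n, len(model.group_labels)))
    for k, lb in enumerate(model.group_labels):
        S = model.group_covs[lb]
        try:
            cho = linalg.cho_factor(S)
            logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
            diff = vals - model.group_means.loc[lb].to_numpy()
            maha = np.sum(diff * linalg.cho_solve(cho, diff.T).T, axis=1)
        except linalg.LinAlgError as exc:
            raise ValidationError(
                f"singular regularized covariance for group {lb!r}"
            ) from exc
        logd[:, k] = np.log(model.priors[lb]) - 0.5 * logdet - 0.5 * maha
    logd -= logd.max(axis=1, keepdims=True)
    post = np.exp(logd)
    post /= post.sum(axis=1, keepdims=True)
    idx = np.argmax(post, axis=1)
    labels = pd.Series([model.group_labels[i] for i in idx], index=X.index)
    posteriors = pd.DataFrame(post, index=X.index, columns=model.group_labels)
    return labels, posteriors


def _misclassification(model: DiscriminantModel, X: pd.DataFrame, y: pd.Series) -> float:
    pred, _ = classify(model, X)
    return float((pred.to_numpy() != y.to_numpy()).mean())


def _cv_error(X, y, gamma, lam, priors, folds, seed) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    yv = y.to_numpy()
    for tr, te in skf.split(X.to_numpy(), yv):
        model = rda_fit(X.iloc[tr], y.iloc[tr], gamma, lam, priors)
        errs.append(_misclassification(model, X.iloc[te], y.iloc[te]))
    return float(np.mean(errs))


def _bootstrap_error(X, y, gamma, lam, priors, n_boot, seed) -> float:
    """Stratified bootstrap resampling with out-of-bag misclassification."""
    rng = np.random.default_rng(seed)
    yv = y.to_numpy()
    n = len(yv)
    errs = []
    for _ in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(np.flatnonzero(yv == lb), size=(yv == lb).sum(), replace=True)
                for lb in np.unique(yv)
            ]
        )
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) == 0:
            continue
        model = rda_fit(X.iloc[idx], y.iloc[idx], gamma, lam, priors)
        errs.append(_misclassification(model, X.iloc[oob], y.iloc[oob]))
    return float(np.mean(errs)) if errs else float("nan")


def rda_optimize(
    shape,
    labels: pd.Series,
    grid=None,
    scheme: str = "crossval",
    folds: int = 10,
    n_boot: int = 25,
    seed: int = 0,
    priors: str | pd.Series = "proportional",
) -> DiscriminantModel:
    """Select (γ, λ) on a lattice by estimated misclassification.

    ``grid`` is an iterable of (γ, λ) pairs; the default is a 21 × 21
    uniform lattice on [0, 1]².  ``scheme`` is ``"crossval"`` (stratified
    k-fold) or ``"bootstrap"`` (stratified resamples, out-of-bag error).
    Ties break toward the first grid point.  The returned model is refit on
    all data at the optimum with apparent, cross-validated and bootstrap
    error estimates recorded.
    """
    X = _as_frame(shape)
    labels = pd.Series(labels).reindex(X.index)
    if grid is None:
        ticks = np.linspace(0.0, 1.0, 21)
        grid = [(gm, lm) for gm in ticks for lm in ticks]
    grid = list(grid)
    if not grid:
        raise ValueError("empty optimization grid")
    min_group = labels.value_counts().min()
    if scheme == "crossval" and min_group < folds:
        raise ValidationError(
            f"smallest group ({min_group}) is smaller than the fold count ({folds})"
        )
    best = None
    for gamma, lam in grid:
        try:
            if scheme == "crossval":
                err = _cv_error(X, labels, gamma, lam, priors, folds, seed)
            elif scheme == "bootstrap":
                err = _bootstrap_error(X, labels, gamma, lam, priors, n_boot, seed)
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
        except ValidationError:
            # singular regularized covariance (possible at gamma=0 with
            # groups smaller than the variable count): infeasible grid point
            err = float("inf")
        if best is None or err < best[0]:
            best = (err, gamma, lam)
    _, gamma, lam = best
    if not np.isfinite(best[0]):
        raise ValidationError("no feasible (gamma, lambda) grid point")
    model = rda_fit(X, labels, gamma, lam, priors)
    model.error_estimates = {
        "apparent": _misclassification(model, X, labels),
        "crossval": _cv_error(X, labels, gamma, lam, priors, folds, seed)
        if min_group >= folds
        else float("nan"),
        "bootstrap": _bootstrap_error(X, labels, gamma, lam, priors, n_boot, seed),
    }
    return model
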