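"""Severity/region taxonomy and cell-fate prediction statistics.

Field-level injury severity is graded A-D from the fraction of cells
whose calcium exceeded twice baseline; cells are binned into injured
(<= 200 um from the epicenter), penumbra (200-500 um) and distal
(> 500 um) regions.  Outcome models relate the eight per-cell
predictors (pre/post participation, connectivity, event rate, severity
grade, distance) to the 6-hour live/dead label: maximum-likelihood
logistic regression with per-feature likelihood-ratio chi-squared
tests, and Fisher linear discriminant analysis summarized by Wilks'
lambda and the correct-prediction rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SeverityClass",
    "DiscriminantFit",
    "LogisticFit",
    "severity_class",
    "region_assign",
    "fit_logistic",
    "fit_lda",
    "FEATURES_ALL",
    "FEATURES_NETWORK",
]

#: the full eight-predictor set used for the injured-area fate model
FEATURES_ALL = ["pi_pre", "ci_pre", "r_pre", "pi_post", "ci_post", "r_post", "s", "d"]
#: the six network-only predictors used for the penumbra fate model
FEATURES_NETWORK = ["pi_pre", "ci_pre", "r_pre", "pi_post", "ci_post", "r_post"]

#: ordinal encoding of the severity grade for regression / LDA
SEVERITY_ORDINAL = {"D": 0, "C": 1, "B": 2, "A": 3}


@dataclass
class SeverityClass:
    label: str                      # A (worst) .. D
    responder_fraction: float

    @property
    def ordinal(self) -> int:
        return SEVERITY_ORDINAL[self.label]


@dataclass
class LogisticFit:
    params: pd.Series               # intercept + slopes
    conf_int: pd.DataFrame          # 95% CI per parameter
    lr_pvalues: pd.Series           # per-feature likelihood-ratio chi2 p
    llf: float
    converged: bool
    separation_warning: bool


@dataclass
class DiscriminantFit:
    class_means: dict
    direction: np.ndarray           # Fisher discriminant axis
    wilks_lambda: float             # det(W)/det(T) in (0, 1]
    accuracy: float                 # correct-prediction rate
    features: list[str]
    cross_validated: bool = False


def severity_class(responder_fraction: float) -> SeverityClass:
    """Grade a field by its fraction of responders (Ca > 2x baseline).

    Half-open bins, highest severity first: A = [0.75, 1], B =
    [0.50, 0.75), C = [0.25, 0.50), D = [0, 0.25).
    """
    f = float(responder_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError("responder fraction must lie in [0, 1]")
    if f >= 0.75:
        label = "A"
    elif f >= 0.50:
        label = "B"
    elif f >= 0.25:
        label = "C"
    else:
        label = "D"
    return SeverityClass(label=label, responder_fraction=f)


def region_assign(distance_um: float) -> str:
    """Region by distance from the injury epicenter.

    ``injured`` within 200 um, ``penumbra`` to 500 um, ``distal``
    beyond.
    """
    d = float(distance_um)
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d <= 200.0:
        return "injured"
    if d <= 500.0:
        return "penumbra"
    return "distal"


def fit_logistic(
    records: pd.DataFrame,
    features: list[str] | None = None,
    label: str = "fate",
) -> LogisticFit:
    """Maximum-likelihood logistic regression of the fate label.

    Fit by iteratively reweighted least squares; each feature receives a
    likelihood-ratio chi-squared p-value from refitting without it.
    Perfect separation is flagged rather than fatal.  Deterministic for
    a given input table.
    """
    features = list(FEATURES_ALL if features is None else features)
    y = records[label].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("fate labels contain a single class; nothing to fit")
    for f in features:
        if records[f].nunique() < 2:
            raise ValueError(f"feature {f!r} is constant")
    x = sm.add_constant(records[features], has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, x).fit(disp=False, maxiter=200)
        except Exception:
            res = sm.Logit(y, x).fit_regularized(disp=False, alpha=1e-8, maxiter=500)
            separation = True
        separation = separation or any(
            "separation" in str(w.message).lower() for w in caught
        )
    lr_p = {}
    for f in features:
        reduced_feats = [g for g in features if g != f]
        xr = sm.add_constant(records[reduced_feats], has_constant="add")
        red = sm.Logit(y, xr).fit(disp=False, maxiter=200)
        lr = 2.0 * (res.llf - red.llf)
        lr_p[f] = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return LogisticFit(
        params=res.params,
        conf_int=res.conf_int(alpha=0.05),
        lr_pvalues=pd.Series(lr_p),
        llf=float(res.llf),
        converged=bool(getattr(res, "mle_retvals", {}).get("converged", True)),
        separation_warning=separation,
    )


def _scatter_matrices(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    """Within-class (W) and total (T) scatter matrices and class means."""
    grand = x.mean(axis=0)
    t = (x - grand).T @ (x - grand)
    w = np.zeros_like(t)
    means = {}
    for cls in np.unique(y):
        xi = x[y == cls]
        mu = xi.mean(axis=0)
        means[cls] = mu
        w += (xi - mu).T @ (xi - mu)
    return w, t, means


def fit_lda(
    records: pd.DataFrame,
    features: list[str] | None = None,
    label: str = "fate",
    cross_validate: bool = False,
    rng: np.random.Generator | int | None = None,
) -> DiscriminantFit:
    """Fisher linear discriminant analysis of the fate label.

    The discriminant direction maximizes the between- to within-class
    scatter ratio; Wilks' lambda is ``det(W) / det(T)`` of the
    within-class and total scatter matrices.  The reported accuracy is
    the resubstitution correct-prediction rate by default (the
    convention the severity analysis mirrors); ``cross_validate=True``
    switches to 5-fold CV accuracy instead.
    """
    features = list(FEATURES_ALL if features is None else features)
    x = records[features].to_numpy(dtype=float)
    y = records[label].to_numpy()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    for cls in classes:
        if (y == cls).sum() < len(features) + 1:
            raise ValueError(f"class {cls!r} has fewer records than features + 1")
    w, t, means = _scatter_matrices(x, y)
    det_w, det_t = np.linalg.det(w), np.linalg.det(t)
    if det_t <= 0:
        warnings.warn("singular total scatter; using pseudo-determinant ratio")
        wilks = float(np.real(np.prod(np.linalg.eigvals(np.linalg.pinv(t) @ w))))
    else:
        wilks = float(det_w / det_t)
    b = t - w
    try:
        direction = np.linalg.solve(w, means[classes[1]] - means[classes[0]]) \
            if classes.size == 2 else None
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class scatter; using pseudo-inverse")
        direction = np.linalg.pinv(w) @ (means[classes[1]] - means[classes[0]])
    if direction is None:
        eigvals, eigvecs = np.linalg.eig(np.linalg.pinv(w) @ b)
        direction = np.real(eigvecs[:, np.argmax(np.real(eigvals))])

    def classify(xtr, ytr, xte):
        # Gaussian discriminant rule with pooled covariance W/(n-K) and
        # empirical priors; z is automatically oriented toward class 1
        # because (mu1-mu0)' Sigma^-1 (mu1-mu0) > 0
        wtr, _, mtr = _scatter_matrices(xtr, ytr)
        cls = np.unique(ytr)
        n_tr, k = len(ytr), cls.size
        sigma = wtr / max(n_tr - k, 1)
        delta = mtr[cls[1]] - mtr[cls[0]]
        try:
            axis = np.linalg.solve(sigma, delta)
        except np.linalg.LinAlgError:
            axis = np.linalg.pinv(sigma) @ delta
        pi0 = (ytr == cls[0]).mean()
        pi1 = (ytr == cls[1]).mean()
        cut = 0.5 * (mtr[cls[0]] + mtr[cls[1]]) @ axis - np.log(
            max(pi1, 1e-12) / max(pi0, 1e-12)
        )
        return np.where(xte @ axis >= cut, cls[1], cls[0])

    if classes.size == 2:
        if cross_validate:
            rng = np.random.default_rng(rng)
            idx = rng.permutation(len(y))
            folds = np.array_split(idx, 5)
            correct = 0
            for k in range(5):
                test = folds[k]
                train = np.concatenate([folds[j] for j in range(5) if j != k])
                pred = classify(x[train], y[train], x[test])
                correct += int((pred == y[test]).sum())
            accuracy = correct / len(y)
        else:
            pred = classify(x, y, x)
            accuracy = float((pred == y).mean())
    else:
        # nearest class mean in the discriminant subspace
        eigvals, eigvecs = np.linalg.eig(np.linalg.pinv(w) @ b)
        order = np.argsort(np.real(eigvals))[::-1][: classes.size - 1]
        proj = np.real(eigvecs[:, order])
        z = x @ proj
        centroids = {c: z[y == c].mean(axis=0) for c in classes}
        dists = np.stack([np.linalg.norm(z - centroids[c], axis=1) for c in classes])
        pred = classes[np.argmin(dists, axis=0)]
        accuracy = float((pred == y).mean())

    return DiscriminantFit(
        class_means=means,
        direction=np.asarray(direction, dtype=float),
        wilks_lambda=wilks,
        accuracy=accuracy,
        features=features,
        cross_validated=cross_validate,
    )
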