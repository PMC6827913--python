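"""Fisher linear discriminant machine observers for edge classification.

Both classes are modeled as Gaussians with a shared (pooled) covariance
``Sigma``; under that assumption the Bayes-optimal decision statistic is
linear in the feature vector ``s``:

    score(s) = w . s + c,
    w = Sigma^-1 (mu1 - mu0),
    c = (mu0' Sigma^-1 mu0 - mu1' Sigma^-1 mu1) / 2,

which is exactly the log-likelihood ratio log P(s|class1) / P(s|class0).
Class 0 is "shadow", class 1 is "other" (material); a positive score
predicts "other".  Performance is summarized as a confusion matrix and
the SDT sensitivity d' = z(pH) - z(pFA), sharing the extreme-rate
correction rule of :mod:`shadowedge.sdt` so that machine and human
observers are scored identically.

Confidence intervals come from a parametric bootstrap: per-class
Gaussians are fitted to the data, replicate datasets of the original
class sizes are drawn from them, and the classifier is refitted and
re-evaluated on each replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .sdt import bias as _sdt_bias
from .sdt import corrected_rates, dprime

__all__ = [
    "CLASS_LABELS",
    "LDAModel",
    "ConfusionMatrix",
    "BootstrapCI",
    "fit_lda",
    "decision_score",
    "predict",
    "evaluate",
    "rank_features",
    "incremental_curves",
    "parametric_bootstrap",
]

#: class 0 / class 1 label order used everywhere in this module
CLASS_LABELS = ("shadow", "other")


@dataclass(frozen=True)
class LDAModel:
    """Fitted linear discriminant: class means, pooled covariance, w and c."""

    mu0: np.ndarray  # shadow mean
    mu1: np.ndarray  # other (material) mean
    sigma: np.ndarray  # pooled covariance, after ridge
    w: np.ndarray
    c: float
    feature_names: tuple[str, ...]
    ridge: float

    def to_dict(self) -> dict:
        return {
            "mu0": self.mu0.tolist(),
            "mu1": self.mu1.tolist(),
            "sigma": self.sigma.tolist(),
            "w": self.w.tolist(),
            "c": self.c,
            "feature_names": list(self.feature_names),
            "ridge": self.ridge,
            "class_labels": list(CLASS_LABELS),
        }


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts (true class x predicted class, order shadow/other) plus rates.

    ``pH = P(predict other | other)``, ``pFA = P(predict other | shadow)``;
    d' and criterion are computed from the (possibly corrected) rates.
    """

    counts: np.ndarray
    pH: float
    pFA: float
    dprime: float
    criterion: float
    correction_applied: bool


@dataclass(frozen=True)
class BootstrapCI:
    point_dprime: float
    lo: float
    hi: float
    n_boot: int
    seed: int | None
    replicates: np.ndarray = field(repr=False, default=None)


def _split_classes(X: np.ndarray, y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    x0 = X[y == CLASS_LABELS[0]]
    x1 = X[y == CLASS_LABELS[1]]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("need at least two samples of each class")
    return x0, x1


def fit_lda(X, y, feature_names=None, ridge_scale: float = 1e-8) -> LDAModel:
    """Fit the two-class linear discriminant.

    Parameters
    ----------
    X : (n, k) array of feature values
    y : length-n labels in {"shadow", "other"}
    ridge_scale
        Regularization added to the pooled covariance diagonal as
        ``ridge_scale * trace(Sigma) / k`` for conditioning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    x0, x1 = _split_classes(X, y)
    k = X.shape[1]
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    # pooled covariance: scatter matrices over n0 + n1 - 2
    s0 = (x0 - mu0).T @ (x0 - mu0)
    s1 = (x1 - mu1).T @ (x1 - mu1)
    sigma = (s0 + s1) / (len(x0) + len(x1) - 2)
    trace = np.trace(sigma)
    # absolute floor keeps zero-variance features (e.g. chromatic channels of
    # luminance-only stimuli) well-posed: they get w = 0 and contribute nothing
    ridge = ridge_scale * (trace / k if trace > 0 else 1.0)
    sigma = sigma + ridge * np.eye(k)
    try:
        sigma_inv_d = np.linalg.solve(sigma, np.stack([mu1 - mu0, mu0, mu1], axis=1))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"pooled covariance singular beyond ridge: {exc}")
    w = sigma_inv_d[:, 0]
    c = 0.5 * (mu0 @ sigma_inv_d[:, 1] - mu1 @ sigma_inv_d[:, 2])
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{i}" for i in range(k)
    )
    return LDAModel(mu0=mu0, mu1=mu1, sigma=sigma, w=w, c=float(c),
                    feature_names=names, ridge=float(ridge))


def decision_score(model: LDAModel, s) -> np.ndarray:
    """Log-likelihood-ratio score ``w . s + c``; positive predicts "other"."""
    s = np.asarray(s, dtype=float)
    if s.shape[-1] != model.w.shape[0]:
        raise ValueError(
            f"feature dimension {s.shape[-1]} does not match model ({model.w.shape[0]})"
        )
    return s @ model.w + model.c


def predict(model: LDAModel, X) -> np.ndarray:
    scores = decision_score(model, X)
    return np.where(scores > 0, CLASS_LABELS[1], CLASS_LABELS[0])


def _confusion(y_true, y_pred) -> ConfusionMatrix:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    counts = np.zeros((2, 2), dtype=int)
    for i, t in enumerate(CLASS_LABELS):
        for j, p in enumerate(CLASS_LABELS):
            counts[i, j] = int(np.sum((y_true == t) & (y_pred == p)))
    n_shadow, n_other = counts[0].sum(), counts[1].sum()
    if n_shadow == 0 or n_other == 0:
        raise ValueError("evaluation data must contain both classes")
    hits = counts[1, 1]  # "other" predicted for true "other"
    fas = counts[0, 1]  # "other" predicted for true shadow
    ph, pfa, corrected = corrected_rates(hits, n_other, fas, n_shadow)
    return ConfusionMatrix(
        counts=counts, pH=ph, pFA=pfa,
        dprime=float(dprime(ph, pfa)), criterion=float(_sdt_bias(ph, pfa)),
        correction_applied=corrected,
    )


def evaluate(
    model: LDAModel | None,
    X,
    y,
    protocol: str = "resub",
    k_folds: int = 10,
    seed: int | None = 0,
    ridge_scale: float = 1e-8,
) -> ConfusionMatrix:
    """Confusion matrix and d' under resubstitution or k-fold cross-validation.

    ``protocol="resub"`` scores ``model`` on (X, y) in-sample.  With
    ``protocol="kfold"`` the model argument is ignored; the classifier is
    refitted on each training split and scored on the held-out fold, and the
    pooled out-of-fold predictions form the confusion matrix.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    if protocol == "resub":
        if model is None:
            model = fit_lda(X, y, ridge_scale=ridge_scale)
        return _confusion(y, predict(model, X))
    if protocol == "kfold":
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(y))
        folds = np.array_split(order, k_folds)
        y_pred = np.empty(len(y), dtype=object)
        for fold in folds:
            train = np.setdiff1d(order, fold)
            m = fit_lda(X[train], y[train], ridge_scale=ridge_scale)
            y_pred[fold] = predict(m, X[fold])
        return _confusion(y, y_pred.astype(str))
    raise ValueError(f"unknown protocol {protocol!r}")


def rank_features(X, y, feature_names, protocol: str = "resub") -> pd.DataFrame:
    """Rank features by their individual (single-feature classifier) d'.

    Ties are broken by feature-name order.  Returns a DataFrame with
    columns feature, dprime, rank (1 = most informative).
    """
    X = np.asarray(X, dtype=float)
    rows = []
    for j, name in enumerate(feature_names):
        cm = evaluate(
            fit_lda(X[:, [j]], y, feature_names=[name]) if protocol == "resub" else None,
            X[:, [j]], y, protocol=protocol,
        )
        rows.append({"feature": name, "dprime": cm.dprime})
    df = pd.DataFrame(rows).sort_values(
        ["dprime", "feature"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


COLOR_VARIANTS = {
    "none": (),
    "+d_LM": ("d_LM",),
    "+d_Sop": ("d_Sop",),
    "+d_LM+d_Sop": ("d_LM", "d_Sop"),
}


def incremental_curves(
    X,
    y,
    feature_names,
    luminance_features=("C_Lum", "m_Lum", "sigma_Lum", "rho_Lum"),
    color_variants: dict | None = None,
    n_boot: int = 1000,
    seed: int | None = 0,
    protocol: str = "resub",
) -> pd.DataFrame:
    """d' as luminance properties are added one by one, per color variant.

    Luminance features are first ranked by individual d' and then added in
    order from highest to lowest; each of the four color variants (no
    color, +d_LM, +d_Sop, +both) is evaluated at every count, with a
    parametric-bootstrap confidence interval per cell.
    """
    X = np.asarray(X, dtype=float)
    feature_names = list(feature_names)
    variants = COLOR_VARIANTS if color_variants is None else color_variants
    lum_idx = [feature_names.index(f) for f in luminance_features]
    ranking = rank_features(X[:, lum_idx], y, list(luminance_features), protocol=protocol)
    ordered = list(ranking["feature"])
    rows = []
    ss = np.random.SeedSequence(seed)
    for m in range(1, len(ordered) + 1):
        base = ordered[:m]
        for variant, extra in variants.items():
            subset = base + [f for f in extra if f in feature_names]
            idx = [feature_names.index(f) for f in subset]
            ci = parametric_bootstrap(
                X[:, idx], y, n_boot=n_boot,
                seed=int(ss.generate_state(1)[0] % (2**31)) if seed is not None else None,
                protocol=protocol,
            )
            rows.append(
                {
                    "n_properties": m, "variant": variant,
                    "feature_set": "+".join(subset),
                    "dprime": ci.point_dprime, "ci_lo": ci.lo, "ci_hi": ci.hi,
                }
            )
    return pd.DataFrame(rows)


def parametric_bootstrap(
    X,
    y,
    n_boot: int = 1000,
    seed: int | None = 0,
    protocol: str = "resub",
) -> BootstrapCI:
    """95% parametric-bootstrap interval for the classifier's d'.

    Per-class Gaussians (class means, shared pooled covariance) are fitted
    to the data; each replicate draws the original class sizes from those
    Gaussians, refits the discriminant and re-evaluates d'.  The interval
    is the 2.5th-97.5th percentile range of replicate d' values.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    model = fit_lda(X, y)
    point = evaluate(model, X, y, protocol=protocol).dprime
    x0, x1 = _split_classes(X, y)
    n0, n1 = len(x0), len(x1)
    chol = np.linalg.cholesky(model.sigma)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    y_rep = np.array([CLASS_LABELS[0]] * n0 + [CLASS_LABELS[1]] * n1)
    for b in range(n_boot):
        z = rng.standard_normal((n0 + n1, X.shape[1]))
        sample = z @ chol.T
        sample[:n0] += model.mu0
        sample[n0:] += model.mu1
        reps[b] = evaluate(None, sample, y_rep, protocol=protocol).dprime
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapCI(point_dprime=float(point), lo=float(lo), hi=float(hi),
                       n_boot=n_boot, seed=seed, replicates=reps)


def all_feature_subsets(
    luminance_features=("C_Lum", "m_Lum", "sigma_Lum", "rho_Lum"),
    chromatic_features=("d_LM", "d_Sop"),
):
    """Every nonempty luminance subset crossed with the four color variants."""
    subsets = []
    for m in range(1, len(luminance_features) + 1):
        for base in combinations(luminance_features, m):
            for extra in COLOR_VARIANTS.values():
                subsets.append(tuple(base) + tuple(f for f in extra if f in chromatic_features))
    # drop duplicates while keeping order
    seen, out = set(), []
    for s in subsets:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out
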