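"""Fisher discriminant analysis, holdout colony assignment and Mahalanobis
acoustic distance matrices.

The discriminant axes solve the generalized eigenproblem B v = lambda W v,
where B is the (count-weighted) between-class scatter of group means and W
the pooled within-class covariance; axes are scaled so v' W v = 1, i.e.
they are orthonormal in the within-class metric, and at most min(k-1, p)
axes carry signal. Classification assumes Gaussian classes with the shared
pooled covariance and (by default) sample-proportional priors, matching the
conventions of the R ecosystem's `lda`.

Colony-level acoustic distance is the squared Mahalanobis distance between
colony centroids in (LD1, LD2) under the pooled within-colony covariance;
an exemplar-to-centroid variant is available behind the ``pair_stat``
switch and as a diagnostic table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .distmat import DistanceMatrix
from .screening import FeatureScreenReport, screen_features

__all__ = ["DiscriminantModel", "fit_discriminant", "classify_holdout",
           "AssignmentReport", "acoustic_distance_matrix",
           "exemplar_centroid_distances"]


def _pooled_within_cov(x: np.ndarray, labels: np.ndarray,
                       classes: np.ndarray) -> np.ndarray:
    n, p = x.shape
    s = np.zeros((p, p))
    for c in classes:
        xc = x[labels == c]
        if len(xc) > 1:
            s += (len(xc) - 1) * np.cov(xc, rowvar=False)
    dof = max(n - len(classes), 1)
    return s / dof


def _ridge_if_singular(cov: np.ndarray, where: str) -> tuple[np.ndarray, float]:
    p = cov.shape[0]
    eps = 0.0
    try:
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e10:
        eps = 1e-8 * max(np.trace(cov) / p, 1.0)
        cov = cov + eps * np.eye(p)
        warnings.warn(f"singular pooled covariance in {where}; "
                      f"ridge-regularised with epsilon={eps:.3g}", stacklevel=3)
    return cov, eps


@dataclass
class DiscriminantModel:
    class_labels: list[str]
    class_means: np.ndarray          # k x p
    pooled_within_cov: np.ndarray    # p x p
    discriminant_axes: np.ndarray    # p x n_axes, v' W v = 1
    axis_eigenvalues: np.ndarray     # non-increasing
    priors: np.ndarray               # sums to 1
    grand_mean: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    ridge_epsilon: float = 0.0
    ld1_screen: FeatureScreenReport | None = None

    @property
    def n_axes(self) -> int:
        return self.discriminant_axes.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.grand_mean) @ self.discriminant_axes

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Assign each row to the class with the highest linear
        discriminant score (Gaussian classes, pooled covariance)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        cov, _ = _ridge_if_singular(self.pooled_within_cov, "predict")
        prec = np.linalg.inv(cov)
        a = self.class_means @ prec                       # k x p
        b = -0.5 * np.einsum("ij,ij->i", a, self.class_means) \
            + np.log(self.priors)
        scores = x @ a.T + b
        return np.asarray(self.class_labels)[np.argmax(scores, axis=1)]


def fit_discriminant(features: pd.DataFrame, labels, which_features: list[str],
                     priors: str = "proportional",
                     emit_ld1_screen: bool = True
                     ) -> tuple[DiscriminantModel, pd.DataFrame]:
    """Fit Fisher DFA on the chosen features; return model + LD scores.

    The returned score frame has one row per exemplar with columns LD1,
    LD2, ... plus the group label; a one-way ANOVA + Tukey report on LD1
    is attached to the model.
    """
    x = features[which_features].to_numpy(dtype=float)
    y = np.asarray([str(l) for l in labels])
    if np.isnan(x).any():
        keep = ~np.isnan(x).any(axis=1)
        x, y = x[keep], y[keep]
    classes, counts = np.unique(y, return_counts=True)
    k, (n, p) = len(classes), x.shape
    if k < 2:
        raise ValueError("discriminant analysis needs >= 2 classes")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than features ({p})")

    grand = x.mean(axis=0)
    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    w = _pooled_within_cov(x, y, classes)
    w_reg, eps = _ridge_if_singular(w, "fit_discriminant")
    b = np.zeros((p, p))
    for c, m, nc in zip(classes, means, counts):
        diff = (m - grand)[:, None]
        b += nc * (diff @ diff.T)
    b /= max(n - k, 1)

    eigvals, eigvecs = linalg.eigh(b, w_reg)
    order = np.argsort(eigvals)[::-1]
    n_axes = min(k - 1, p)
    eigvals = eigvals[order][:n_axes]
    axes = eigvecs[:, order][:, :n_axes]
    # fix sign for reproducibility: largest-magnitude loading positive
    for j in range(axes.shape[1]):
        lead = np.argmax(np.abs(axes[:, j]))
        if axes[lead, j] < 0:
            axes[:, j] = -axes[:, j]

    if priors == "proportional":
        pri = counts / n
    elif priors == "uniform":
        pri = np.full(k, 1.0 / k)
    else:
        raise ValueError("priors must be 'proportional' or 'uniform'")

    model = DiscriminantModel(
        class_labels=[str(c) for c in classes], class_means=means,
        pooled_within_cov=w, discriminant_axes=axes,
        axis_eigenvalues=eigvals, priors=pri, grand_mean=grand,
        feature_names=list(which_features), ridge_epsilon=eps,
    )
    scores = model.transform(x)
    score_df = pd.DataFrame(
        scores, columns=[f"LD{i + 1}" for i in range(scores.shape[1])])
    score_df["colony"] = y
    if emit_ld1_screen:
        model.ld1_screen = screen_features(score_df, feature_cols=["LD1"])
    return model, score_df


@dataclass
class AssignmentReport:
    per_colony_pct_correct: dict[str, float]
    overall_pct_correct: float
    confusion: pd.DataFrame       # true colony x assigned colony counts
    holdout_fraction: float
    seed: int | None

    def as_dict(self) -> dict:
        return {
            "per_colony_pct_correct": self.per_colony_pct_correct,
            "overall_pct_correct": self.overall_pct_correct,
            "confusion": self.confusion.to_dict(),
            "holdout_fraction": self.holdout_fraction, "seed": self.seed,
        }


def classify_holdout(features: pd.DataFrame, labels, which_features: list[str],
                     holdout_fraction: float = 0.5, seed: int | None = None,
                     priors: str = "proportional") -> AssignmentReport:
    """Stratified holdout validation of colony assignment.

    Half the exemplars of each colony (by default) are withheld, the DFA
    is fit on the rest, and each test exemplar is assigned to the colony
    with the highest discriminant score.
    """
    y = np.asarray([str(l) for l in labels])
    classes, counts = np.unique(y, return_counts=True)
    for c, nc in zip(classes, counts):
        if nc < 2:
            raise ValueError(
                f"colony {c!r} has a single exemplar and cannot be stratified")
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(y), dtype=bool)
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_test = max(1, int(round(holdout_fraction * len(idx))))
        n_test = min(n_test, len(idx) - 1)  # keep >= 1 training exemplar
        test_mask[idx[:n_test]] = True

    x_all = features[which_features]
    if len(classes) == 1:
        assigned = np.full(int(test_mask.sum()), classes[0])
    else:
        model, _ = fit_discriminant(x_all[~test_mask], y[~test_mask],
                                    which_features, priors=priors,
                                    emit_ld1_screen=False)
        assigned = model.predict(x_all[test_mask].to_numpy(dtype=float))

    truth = y[test_mask]
    conf = pd.crosstab(pd.Series(truth, name="true"),
                       pd.Series(assigned, name="assigned"))
    conf = conf.reindex(index=classes, columns=classes, fill_value=0)
    per = {c: 100.0 * conf.loc[c, c] / conf.loc[c].sum() for c in classes}
    overall = 100.0 * np.trace(conf.to_numpy()) / conf.to_numpy().sum()
    return AssignmentReport(per, float(overall), conf,
                            holdout_fraction, seed)


def _centroids_and_pooled(scores: np.ndarray, y: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    classes = np.unique(y)
    cents = np.stack([scores[y == c].mean(axis=0) for c in classes])
    cov = _pooled_within_cov(scores, y, classes)
    cov, _ = _ridge_if_singular(cov, "acoustic_distance_matrix")
    return classes, cents, cov


def exemplar_centroid_distances(scores: pd.DataFrame,
                                ld_cols: tuple[str, ...] = ("LD1", "LD2"),
                                group_col: str = "colony") -> pd.DataFrame:
    """Squared Mahalanobis distance of every exemplar to every colony
    centroid (diagnostic table)."""
    ld_cols = [c for c in ld_cols if c in scores.columns]
    x = scores[list(ld_cols)].to_numpy(dtype=float)
    y = scores[group_col].to_numpy()
    classes, cents, cov = _centroids_and_pooled(x, y)
    prec = np.linalg.inv(cov)
    out = {"colony": y}
    for c, m in zip(classes, cents):
        d = x - m
        out[f"d2_to_{c}"] = np.einsum("ij,jk,ik->i", d, prec, d)
    return pd.DataFrame(out)


def acoustic_distance_matrix(scores: pd.DataFrame,
                             ld_cols: tuple[str, ...] = ("LD1", "LD2"),
                             group_col: str = "colony",
                             pair_stat: str = "centroid") -> DistanceMatrix:
    """Colony-pair squared Mahalanobis distance in discriminant space.

    ``pair_stat='centroid'`` (default): distance between colony centroids
    under the pooled within-colony covariance. ``pair_stat='mean_exemplar'``:
    mean exemplar-to-other-centroid distance, symmetrised by averaging the
    two directions.
    """
    ld_cols = [c for c in ld_cols if c in scores.columns]
    x = scores[list(ld_cols)].to_numpy(dtype=float)
    y = scores[group_col].to_numpy()
    classes, cents, cov = _centroids_and_pooled(x, y)
    if len(classes) < 2:
        raise ValueError("need >= 2 colonies")
    prec = np.linalg.inv(cov)
    k = len(classes)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if pair_stat == "centroid":
                diff = cents[i] - cents[j]
                val = float(diff @ prec @ diff)
            elif pair_stat == "mean_exemplar":
                xi, xj = x[y == classes[i]], x[y == classes[j]]
                di = xi - cents[j]
                dj = xj - cents[i]
                val = 0.5 * (
                    float(np.einsum("ij,jk,ik->i", di, prec, di).mean())
                    + float(np.einsum("ij,jk,ik->i", dj, prec, dj).mean()))
            else:
                raise ValueError("pair_stat must be 'centroid' or 'mean_exemplar'")
            d[i, j] = d[j, i] = val
    return DistanceMatrix([str(c) for c in classes], d, "acoustic_mahalanobis_sq")
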