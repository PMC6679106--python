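"""PCA and PLS-DA for preprocessed spectra.

PCA (mean-centred, 10 components by default) is used for unsupervised
visualisation with 95% covariance ellipses per class.  Classification uses
PLS-DA: a PLS1 regression of the 0/1-coded class on the spectra, with the
0.5 decision threshold.  The number of latent variables (LVs) is chosen by
a repeated, patient-stratified cross-validation: in each round 90% of the
patients of each group (all their replicate spectra) train the model and
the spectra of the held-out patients are predicted; sensitivity and
specificity are averaged over rounds for every LV count in 1..m_max, and
the LV count maximising balanced accuracy (smallest on ties) is selected.
Splits are patient-disjoint — no patient contributes spectra to both sides
of a split — and identical across LV counts, so the LV comparison is paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SKPCA

from .cohort import SpectralDataset
from .group_statistics import patient_mean_spectra

__all__ = [
    "PCAResult",
    "pca_fit",
    "CovarianceEllipse",
    "covariance_ellipse",
    "ConfusionCounts",
    "sensitivity_specificity",
    "PLSDA",
    "PLSDAResults",
    "plsda_fit",
    "plsda_predict",
    "CVResult",
    "cross_validate",
    "select_optimal_lv",
]


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Scores, loadings and explained variance of a mean-centred PCA."""

    scores: np.ndarray           # units x components
    loadings: np.ndarray         # components x grid
    explained_variance_pct: np.ndarray
    n_components: int
    grid: np.ndarray | None = None
    unit_meta: pd.DataFrame | None = None
    mean_: np.ndarray | None = None

    def summary(self) -> str:
        lines = ["PCA summary", "-----------",
                 f"units: {self.scores.shape[0]}   components: {self.n_components}"]
        for i, v in enumerate(self.explained_variance_pct, start=1):
            lines.append(f"PC-{i}: {v:6.2f}% of total variance")
        lines.append(f"cumulative: {self.explained_variance_pct.sum():.2f}%")
        return "\n".join(lines)

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"PC{i+1}": self.scores[:, i] for i in range(self.n_components)}
        df = pd.DataFrame(cols)
        if self.unit_meta is not None:
            df = pd.concat([self.unit_meta.reset_index(drop=True), df], axis=1)
        return df


def pca_fit(d: SpectralDataset | np.ndarray, n_components: int = 10,
            unit: str = "patient_mean") -> PCAResult:
    """Mean-centred PCA of a dataset or raw matrix.

    When given a :class:`SpectralDataset`, the units entering the PCA are
    patient-mean spectra by default (``unit="replicate"`` uses every
    spectrum).
    """
    grid = meta = None
    if isinstance(d, SpectralDataset):
        if unit == "patient_mean":
            d = patient_mean_spectra(d)
        X = d.data
        grid = d.wavenumbers
        meta = d.metadata[["spectrum_id", "patient_id", "group"]].copy()
    else:
        X = np.asarray(d, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two units")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_units-1, n_points)={min(n - 1, p)}"
        )
    pca = _SKPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(
        scores=scores,
        loadings=pca.components_,
        explained_variance_pct=pca.explained_variance_ratio_ * 100.0,
        n_components=n_components,
        grid=grid,
        unit_meta=meta,
        mean_=pca.mean_,
    )


@dataclass
class CovarianceEllipse:
    """A confidence ellipse of a 2-D point cloud.

    ``axes`` are the semi-axis lengths ``sqrt(chi2_2(confidence) * eigval)``
    of the sample covariance; ``rotation`` is the angle (radians) of the
    major axis against the first coordinate.
    """

    center: np.ndarray
    axes: np.ndarray
    rotation: float
    confidence: float
    covariance: np.ndarray

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse (Mahalanobis test)."""
        pts = np.atleast_2d(points) - self.center
        inv = np.linalg.pinv(self.covariance)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return d2 <= stats.chi2.ppf(self.confidence, df=2)


def covariance_ellipse(scores_2d: np.ndarray, confidence: float = 0.95) -> CovarianceEllipse:
    """95% (by default) covariance ellipse of 2-D scores."""
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least three 2-D points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    scale = stats.chi2.ppf(confidence, df=2)
    axes = np.sqrt(scale * evals)
    rotation = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return CovarianceEllipse(center, axes, rotation, confidence, cov)


# ---------------------------------------------------------------------------
# confusion counts


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
        )


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity %, specificity %) = (100 TP/(TP+FN), 100 TN/(TN+FP))."""
    if c.tp + c.fn < 1:
        raise ValueError("no positive-class units")
    if c.tn + c.fp < 1:
        raise ValueError("no negative-class units")
    return 100.0 * c.tp / (c.tp + c.fn), 100.0 * c.tn / (c.tn + c.fp)


# ---------------------------------------------------------------------------
# PLS-DA model / results


class PLSDA:
    """Two-class PLS-DA model specification.

    Wraps a ``units x grid`` matrix ``X`` and a binary class vector ``y``
    (0 = negative/reference class, 1 = positive class).  ``fit`` returns a
    :class:`PLSDAResults` carrying the latent-variable decomposition,
    regression coefficients and prediction facilities.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 class_labels: tuple[str, str] = ("negative", "positive")):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be (units, grid) with one label per unit")
        classes = np.unique(self.y)
        if not np.all(np.isin(classes, [0.0, 1.0])) or len(classes) != 2:
            raise ValueError("y must contain both classes, coded 0/1")
        self.class_labels = class_labels

    @classmethod
    def from_dataset(cls, d: SpectralDataset, group_a: str, group_b: str,
                     unit: str = "replicate") -> "PLSDA":
        """Build the design from a preprocessed dataset: ``group_a`` is the
        negative class, ``group_b`` the positive one."""
        sub = d.subset_groups([group_a, group_b])
        if unit == "patient_mean":
            sub = patient_mean_spectra(sub)
        y = (sub.metadata["group"] == group_b).to_numpy(dtype=float)
        if y.all() or not y.any():
            raise ValueError("both groups must be present in the dataset")
        return cls(sub.data, y, class_labels=(group_a, group_b))

    @property
    def max_lv(self) -> int:
        return min(self.X.shape[0] - 1, self.X.shape[1])

    def fit(self, n_lv: int) -> "PLSDAResults":
        if not 1 <= n_lv <= self.max_lv:
            raise ValueError(f"n_lv must be in [1, {self.max_lv}], got {n_lv}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls = PLSRegression(n_components=n_lv, scale=False)
            pls.fit(self.X, self.y.reshape(-1, 1))
        return PLSDAResults(self, pls, n_lv)


class PLSDAResults:
    """Fitted PLS-DA model: latent variables, coefficients, predictions."""

    decision_threshold: float = 0.5
    class_coding = {"negative": 0, "positive": 1}

    def __init__(self, model: PLSDA, pls: PLSRegression, n_lv: int):
        self.model = model
        self._pls = pls
        self.n_lv = n_lv
        self.x_weights = pls.x_weights_
        self.x_loadings = pls.x_loadings_
        self.x_rotations = pls.x_rotations_
        self.y_loadings = pls.y_loadings_.ravel()
        self.x_mean = pls._x_mean
        self.y_mean = float(pls._y_mean.ravel()[0])
        self.regression_coefficients = (pls.x_rotations_ @ pls.y_loadings_.T).ravel()
        self.intercept = self.y_mean - float(self.x_mean @ self.regression_coefficients)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)[0]

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Regression scores and thresholded class labels for new spectra."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"grid mismatch: model has {self.model.X.shape[1]} points, "
                f"input has {X.shape[1]}"
            )
        scores = X @ self.regression_coefficients + self.intercept
        labels = scores >= self.decision_threshold
        return scores, labels

    def coefficients_for(self, k: int) -> tuple[np.ndarray, float]:
        """Regression coefficients of the nested k-LV model (k <= n_lv).

        NIPALS components are nested: truncating the rotation/loading
        matrices to the first k columns reproduces the k-component fit.
        """
        if not 1 <= k <= self.n_lv:
            raise ValueError(f"k must be in [1, {self.n_lv}]")
        coef = (self.x_rotations[:, :k] @ self.y_loadings[:k].reshape(-1, 1)).ravel()
        intercept = self.y_mean - float(self.x_mean @ coef)
        return coef, intercept

    def summary(self) -> str:
        scores, labels = self.predict(self.model.X)
        cc = ConfusionCounts.from_labels(self.model.y.astype(bool), labels)
        sens, spec = sensitivity_specificity(cc)
        neg, pos = self.model.class_labels
        lines = [
            "PLS-DA results",
            "--------------",
            f"classes: {neg} (0) vs {pos} (1)   units: {len(self.model.y)}",
            f"latent variables: {self.n_lv}   threshold: {self.decision_threshold}",
            f"training sensitivity: {sens:.1f}%   training specificity: {spec:.1f}%",
        ]
        return "\n".join(lines)


def plsda_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSDAResults:
    """Fit a PLS1 discriminant regression of 0/1 labels on spectra."""
    return PLSDA(X, y).fit(n_lv)


def plsda_predict(model: PLSDAResults, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores and binary labels for new spectra under a fitted model."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# repeated patient-stratified cross-validation


@dataclass
class CVResult:
    """Per-LV averaged sensitivity/specificity over repeated CV rounds."""

    table: pd.DataFrame
    rounds: int
    train_fraction: float
    seed: int | None
    group_a: str
    group_b: str
    chosen_m: int = 0
    redraw_log: list = field(default_factory=list)
    splits: list[dict] = field(default_factory=list)  # per-round patient split

    def summary(self) -> str:
        row = self.table.loc[self.table["lv"] == self.chosen_m].iloc[0]
        lines = [
            "PLS-DA cross-validation",
            "-----------------------",
            f"comparison: {self.group_a} vs {self.group_b} (positive class: {self.group_b})",
            f"rounds: {self.rounds}   train fraction: {self.train_fraction}",
            f"selected LVs: {self.chosen_m}",
            f"sensitivity: {row['sensitivity_mean']:.1f}% (SD {row['sensitivity_sd']:.1f})",
            f"specificity: {row['specificity_mean']:.1f}% (SD {row['specificity_sd']:.1f})",
        ]
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _stratified_patient_split(rng: np.random.Generator, patients: np.ndarray,
                              train_fraction: float) -> np.ndarray:
    """Held-out patient ids for one group (at least one held out)."""
    n_val = max(1, int(round((1.0 - train_fraction) * len(patients))))
    if n_val >= len(patients):
        raise ValueError("a group has too few patients for patient-disjoint splitting")
    return rng.choice(patients, size=n_val, replace=False)


def cross_validate(
    d: SpectralDataset,
    group_a: str,
    group_b: str,
    m_max: int = 50,
    rounds: int = 20,
    train_fraction: float = 0.9,
    seed: int | None = None,
    unit: str = "replicate",
    max_redraws: int = 100,
) -> CVResult:
    """Repeated patient-stratified cross-validation with an LV sweep.

    In each of ``rounds`` rounds, ``train_fraction`` of the patients of each
    group (stratified, all their spectra) train the model; all spectra of
    the held-out patients are predicted.  Sensitivity (positive class =
    ``group_b``) and specificity are recorded for every LV count 1..m_max
    using the same split for all counts, then averaged over rounds.
    """
    sub = d.subset_groups([group_a, group_b])
    if unit == "patient_mean":
        sub = patient_mean_spectra(sub)
    elif unit != "replicate":
        raise ValueError(f"unknown unit {unit!r}")
    meta = sub.metadata
    pats_a = meta.loc[meta["group"] == group_a, "patient_id"].unique()
    pats_b = meta.loc[meta["group"] == group_b, "patient_id"].unique()
    if len(pats_a) < 2 or len(pats_b) < 2:
        raise ValueError("each group needs at least two patients")

    rng = np.random.default_rng(seed)
    y_all = (meta["group"] == group_b).to_numpy()
    pid = meta["patient_id"].to_numpy()

    n_train_min = (len(pats_a) - max(1, int(round((1 - train_fraction) * len(pats_a))))
                   + len(pats_b) - max(1, int(round((1 - train_fraction) * len(pats_b)))))
    hard_cap = min(n_train_min - 1, sub.data.shape[1])
    if m_max > hard_cap:
        raise ValueError(f"m_max={m_max} exceeds the LV bound {hard_cap}")

    sens = np.empty((rounds, m_max))
    spec = np.empty((rounds, m_max))
    redraw_log: list[str] = []
    splits: list[dict] = []

    for r in range(rounds):
        for attempt in range(max_redraws):
            val = np.concatenate([
                _stratified_patient_split(rng, pats_a, train_fraction),
                _stratified_patient_split(rng, pats_b, train_fraction),
            ])
            val_mask = np.isin(pid, val)
            y_val = y_all[val_mask]
            if y_val.any() and not y_val.all():
                break
            redraw_log.append(f"round {r}: validation fold lacked a class, redrawn")
        else:
            raise ValueError("could not draw a validation fold containing both classes")

        splits.append(
            {
                "validation": sorted(val.tolist()),
                "train": sorted(np.unique(pid[~val_mask]).tolist()),
            }
        )
        X_tr, y_tr = sub.data[~val_mask], y_all[~val_mask].astype(float)
        X_va = sub.data[val_mask]
        fit = PLSDA(X_tr, y_tr, class_labels=(group_a, group_b)).fit(m_max)
        for k in range(1, m_max + 1):
            coef, intercept = fit.coefficients_for(k)
            labels = X_va @ coef + intercept >= fit.decision_threshold
            cc = ConfusionCounts.from_labels(y_val, labels)
            sens[r, k - 1], spec[r, k - 1] = sensitivity_specificity(cc)

    table = pd.DataFrame(
        {
            "lv": np.arange(1, m_max + 1),
            "sensitivity_mean": sens.mean(axis=0),
            "sensitivity_sd": sens.std(axis=0, ddof=1),
            "specificity_mean": spec.mean(axis=0),
            "specificity_sd": spec.std(axis=0, ddof=1),
        }
    )
    table["balanced_accuracy"] = (table["sensitivity_mean"] + table["specificity_mean"]) / 2.0
    result = CVResult(
        table=table,
        rounds=rounds,
        train_fraction=train_fraction,
        seed=seed,
        group_a=group_a,
        group_b=group_b,
        redraw_log=redraw_log,
        splits=splits,
    )
    result.chosen_m = select_optimal_lv(result)
    return result


def select_optimal_lv(r: CVResult) -> int:
    """LV count maximising mean balanced accuracy; smallest m on ties."""
    if len(r.table) == 0:
        raise ValueError("empty CV table")
    ba = r.table["balanced_accuracy"].to_numpy()
    return int(r.table["lv"].iloc[int(np.argmax(ba))])
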