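"""Standardized principal component analysis for weekly biomechanical profiles.

The monitoring model is an ordinary PCA computed by singular value
decomposition of the column-standardized training matrix (each variable
centred to mean zero and scaled to unit population standard deviation).
Components are retained until their cumulative explained variance reaches a
threshold (default >= 90%), and new athlete-weeks are projected with the
*training* standardization and loadings only — the model is never refit on
in-season data.

Sign convention: since SVD signs are arbitrary, each component is flipped so
that its largest-magnitude loading coefficient is positive, making fitted
models reproducible across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PCAError(ValueError):
    pass


@dataclass
class PCAModel:
    """A fitted standardized-PCA model.

    ``loadings`` has shape (n_variables, n_components) with orthonormal
    columns; ``explained_variance_ratio`` covers *all* components (sums to 1)
    while ``n_retained`` marks how many are used for projection.
    """

    variable_names: list
    train_mean: np.ndarray
    train_sd: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    n_retained: int
    retention_threshold: float
    n_train_rows: int

    @property
    def component_names(self) -> list:
        return [f"PC{i + 1}" for i in range(self.n_retained)]

    def to_dict(self) -> dict:
        return {
            "format": "courtwatch-pca-v1",
            "variable_names": list(self.variable_names),
            "train_mean": [float(x) for x in self.train_mean],
            "train_sd": [float(x) for x in self.train_sd],
            "loadings": [[float(x) for x in row] for row in self.loadings],
            "explained_variance_ratio":
                [float(x) for x in self.explained_variance_ratio],
            "n_retained": int(self.n_retained),
            "retention_threshold": float(self.retention_threshold),
            "n_train_rows": int(self.n_train_rows),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PCAModel":
        if payload.get("format") != "courtwatch-pca-v1":
            raise PCAError(f"unsupported model format {payload.get('format')!r}")
        return cls(
            variable_names=list(payload["variable_names"]),
            train_mean=np.asarray(payload["train_mean"], dtype=float),
            train_sd=np.asarray(payload["train_sd"], dtype=float),
            loadings=np.asarray(payload["loadings"], dtype=float),
            explained_variance_ratio=np.asarray(
                payload["explained_variance_ratio"], dtype=float),
            n_retained=int(payload["n_retained"]),
            retention_threshold=float(payload["retention_threshold"]),
            n_train_rows=int(payload["n_train_rows"]),
        )


def fit_pca(matrix: pd.DataFrame, retention_threshold: float = 0.90) -> PCAModel:
    """Fit the standardized SVD-based PCA on a training analysis matrix.

    Standardization uses the population (ddof=0) standard deviation so the
    training columns have SD exactly one.  Constant columns are rejected by
    name.  ``n_retained`` is the smallest count of leading components whose
    cumulative explained variance ratio reaches the threshold.
    """
    if not 0.0 < retention_threshold <= 1.0:
        raise PCAError(f"retention_threshold must be in (0, 1], got {retention_threshold}")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise PCAError("training matrix contains missing values")
    n, p = X.shape
    if n < 2:
        raise PCAError("need at least two training rows")
    if n <= p:
        logger.warning("PCA training matrix has %d rows for %d variables; "
                       "loadings will be poorly determined", n, p)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = np.flatnonzero(sd == 0.0)
    if constant.size:
        names = [matrix.columns[i] for i in constant]
        raise PCAError(f"constant column(s) cannot be standardized: {names}")

    Z = (X - mean) / sd
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    evr = s ** 2 / np.sum(s ** 2)
    loadings = vt.T
    # sign rule: largest-|loading| coefficient of each component positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip

    n_retained = int(np.searchsorted(np.cumsum(evr),
                                     retention_threshold - 1e-12) + 1)
    n_retained = min(n_retained, loadings.shape[1])
    logger.info("PCA: %d rows x %d variables; retained %d components "
                "(cumulative EVR %.3f)", n, p, n_retained,
                float(np.cumsum(evr)[n_retained - 1]))
    return PCAModel(variable_names=list(matrix.columns),
                    train_mean=mean, train_sd=sd, loadings=loadings,
                    explained_variance_ratio=evr, n_retained=n_retained,
                    retention_threshold=retention_threshold, n_train_rows=n)


def project(model: PCAModel, observations: pd.DataFrame) -> pd.DataFrame:
    """Project observations onto the retained components.

    ``observations`` must contain every training variable (extra columns are
    ignored); rows keep their index.  Uses the training standardization only.
    """
    missing = [v for v in model.variable_names if v not in observations.columns]
    if missing:
        raise PCAError(f"cannot project: missing variable(s) {missing}")
    X = observations[model.variable_names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise PCAError("cannot project rows with missing values")
    Z = (X - model.train_mean) / model.train_sd
    scores = Z @ model.loadings[:, :model.n_retained]
    return pd.DataFrame(scores, index=observations.index,
                        columns=model.component_names)


def inverse_transform(model: PCAModel, scores: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct (standardized-scale back to original units) from retained
    component scores."""
    Z = scores.to_numpy(dtype=float) @ model.loadings[:, :model.n_retained].T
    X = Z * model.train_sd + model.train_mean
    return pd.DataFrame(X, index=scores.index, columns=model.variable_names)


def loading_table(model: PCAModel) -> pd.DataFrame:
    """Labelled loading-coefficient table for the retained components.

    Rows are the original variables; an extra ``% Var. Exp.`` row gives each
    retained component's percent variance explained.
    """
    cols = model.component_names
    table = pd.DataFrame(model.loadings[:, :model.n_retained],
                         index=model.variable_names, columns=cols)
    table.loc["% Var. Exp."] = (
        model.explained_variance_ratio[:model.n_retained] * 100.0)
    return table


def retention_diagnostics(model: PCAModel) -> dict:
    """Alternative retention rules, reported for comparison only.

    ``scree_elbow``: component count at the largest drop in the eigenvalue
    spectrum; ``eigenvalue_gt_0p7``: count of standardized eigenvalues
    (EVR * n_variables) above 0.7.
    """
    evr = model.explained_variance_ratio
    eig = evr * len(model.variable_names)
    drops = -np.diff(eig)
    scree = int(np.argmax(drops) + 1) if drops.size else 1
    return {"scree_elbow": scree,
            "eigenvalue_gt_0p7": int(np.sum(eig > 0.7)),
            "cumulative_evr_rule": model.n_retained}
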