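"""PCA, SIMCA and Fisher linear discriminant classifiers.

PCA is the shared primitive: mean-centre the calibration matrix, take the
top-k right singular directions, report per-component explained-variance
shares.

SIMCA (soft independent modelling of class analogy) fits one PCA model per
class and classifies by the scaled orthogonal residual distance: for sample
``x`` and class ``c`` with ``k_c`` components,

    d(x, c) = (||r||^2 / (m - k_c)) / s0_c^2,
    s0_c^2  = RSS_c / ((n_c - k_c - 1) (m - k_c)),

where ``r`` is the orthogonal reconstruction residual of ``x`` under class
``c``'s PCA and RSS_c is the summed squared residual of the class's own
calibration rows.  Assignment is forced to the class of minimal distance,
so per-class accuracies of 0% remain expressible.

FLD (Fisher's linear discriminant) operates on PCA scores: directions are
the leading generalized eigenvectors of the between-class versus
within-class scatter pencil, and prediction assigns the nearest class
centroid in discriminant space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .spectra_io import SpectraSet

logger = logging.getLogger(__name__)

#: Floor for per-class residual variance (degenerate duplicated-row classes).
RESIDUAL_FLOOR = 1e-12
#: Ridge factor applied to a singular within-class scatter: eps * trace / d.
FLD_RIDGE = 1e-8


def _matrix(s) -> np.ndarray:
    return s.intensities if isinstance(s, SpectraSet) else np.asarray(s, dtype=float)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaModel:
    """Mean vector, orthonormal loading columns, explained-variance shares."""

    mean: np.ndarray
    loadings: np.ndarray  # m x k
    explained_ratio: np.ndarray  # length k, non-increasing

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def pca_fit(cal: SpectraSet | np.ndarray, k: int) -> PcaModel:
    """PCA of the mean-centred calibration matrix via SVD."""
    x = _matrix(cal)
    n, m = x.shape
    if not (1 <= k <= min(n - 1, m)):
        raise ValueError(f"k must be in [1, min(n-1, m)] = [1, {min(n - 1, m)}], got {k}")
    mean = x.mean(axis=0)
    xc = x - mean
    _, sv, vt = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(sv**2))
    if total <= 0:
        # all rows identical: zero variance, arbitrary orthonormal loadings
        ratio = np.zeros(k)
        return PcaModel(mean=mean, loadings=np.eye(m, k), explained_ratio=ratio)
    load = vt[:k].T
    # deterministic sign: largest-|.| element of each loading is positive
    piv = np.argmax(np.abs(load), axis=0)
    load = load * np.sign(load[piv, np.arange(k)])
    return PcaModel(mean=mean, loadings=load, explained_ratio=sv[:k] ** 2 / total)


def pca_scores(model: PcaModel, s: SpectraSet | np.ndarray) -> np.ndarray:
    """Project spectra into model space: ``(X - mean) @ loadings``."""
    x = _matrix(s)
    if x.shape[1] != model.mean.size:
        raise ValueError(f"{x.shape[1]} channels vs model's {model.mean.size}")
    return (x - model.mean) @ model.loadings


# ---------------------------------------------------------------------------
# SIMCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimcaModel:
    """One PCA submodel and residual scale per training class."""

    class_models: Mapping[object, tuple[PcaModel, float]]

    @property
    def classes(self) -> tuple:
        return tuple(self.class_models)


def _auto_k(x: np.ndarray, target: float = 0.95, cap: int = 10) -> int:
    """Smallest k explaining >= ``target`` within-class variance, capped."""
    n, m = x.shape
    kmax = min(n - 2, m, cap)
    xc = x - x.mean(axis=0)
    sv = np.linalg.svd(xc, compute_uv=False)
    total = np.sum(sv**2)
    if total <= 0:
        return 1
    cum = np.cumsum(sv**2) / total
    k = int(np.searchsorted(cum, target) + 1)
    return max(1, min(k, kmax))


def simca_fit(cal: SpectraSet, k_per_class: int | str = "auto") -> SimcaModel:
    """Fit one PCA model per class on the calibration set.

    ``k_per_class`` is either an int or ``"auto"`` (smallest k explaining
    >= 95% of within-class variance, capped at 10).
    """
    x, labels = cal.intensities, cal.labels
    m = x.shape[1]
    models: dict = {}
    for c in cal.classes:
        rows = x[np.array([lab == c for lab in labels])]
        n_c = rows.shape[0]
        k = _auto_k(rows) if k_per_class == "auto" else int(k_per_class)
        if n_c < k + 2:
            raise ValueError(f"class {c!r} has {n_c} samples; needs >= k+2 = {k + 2}")
        pca = pca_fit(rows, k)
        resid = (rows - pca.mean) - pca_scores(pca, rows) @ pca.loadings.T
        rss = float(np.sum(resid**2))
        dof = (n_c - k - 1) * (m - k)
        s0sq = max(rss / dof if dof > 0 else rss, RESIDUAL_FLOOR)
        models[c] = (pca, s0sq)
    return SimcaModel(class_models=models)


def simca_distances(model: SimcaModel, s: SpectraSet | np.ndarray) -> np.ndarray:
    """Reduced residual distance of every sample to every class (n x C)."""
    x = _matrix(s)
    out = np.empty((x.shape[0], len(model.class_models)))
    for j, (c, (pca, s0sq)) in enumerate(model.class_models.items()):
        xc = x - pca.mean
        resid = xc - (xc @ pca.loadings) @ pca.loadings.T
        ssq = np.sum(resid**2, axis=1) / (x.shape[1] - pca.k)
        out[:, j] = ssq / s0sq
    return out


def simca_predict(model: SimcaModel, s: SpectraSet | np.ndarray):
    """Forced assignment to the class of minimal reduced distance.

    Returns ``(labels, distance_matrix)``; the matrix columns follow
    ``model.classes`` order.
    """
    d = simca_distances(model, s)
    classes = model.classes
    idx = np.argmin(d, axis=1)  # first minimum -> class-order tie rule
    return [classes[i] for i in idx], d


# ---------------------------------------------------------------------------
# FLD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FldModel:
    """Discriminant directions (unit columns) and class centroids."""

    directions: np.ndarray  # d x r
    centroids: Mapping[object, np.ndarray]  # class -> length-r vector

    @property
    def classes(self) -> tuple:
        return tuple(self.centroids)


def fld_fit(scores: np.ndarray, labels: Sequence, r: int | None = None) -> FldModel:
    """Fisher discriminant directions from between/within scatter matrices.

    ``r`` defaults to ``n_classes - 1``.  A singular within-class scatter is
    regularised by a ridge of ``1e-8 * trace / d`` on the diagonal.
    """
    x = np.asarray(scores, dtype=float)
    labels = list(labels)
    n, d = x.shape
    classes = sorted(set(labels), key=lambda v: (str(type(v)), v))
    if r is None:
        r = len(classes) - 1
    if not (1 <= r <= min(d, len(classes) - 1)):
        raise ValueError(f"r must be in [1, min(d, n_classes-1)], got {r}")
    mu = x.mean(axis=0)
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    means = {}
    for c in classes:
        rows = x[np.array([lab == c for lab in labels])]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        mc = rows.mean(axis=0)
        means[c] = mc
        xc = rows - mc
        sw += xc.T @ xc
        db = (mc - mu)[:, None]
        sb += rows.shape[0] * (db @ db.T)
    if not np.any(np.abs(sb) > 1e-12 * max(1.0, np.abs(sw).max())):
        raise ValueError("no discriminative signal: between-class scatter is zero")
    # ridge keeps the pencil definite when Sw is singular
    eigvals_w = np.linalg.eigvalsh(sw)
    if eigvals_w[0] <= FLD_RIDGE * np.trace(sw) / d:
        logger.info("FLD within-class scatter near-singular; applying ridge")
        sw = sw + (FLD_RIDGE * np.trace(sw) / d + 1e-30) * np.eye(d)
    vals, vecs = scipy.linalg.eigh(sb, sw)
    order = np.argsort(vals)[::-1][:r]
    w = vecs[:, order]
    w = w / np.linalg.norm(w, axis=0, keepdims=True)
    # deterministic sign convention
    piv = np.argmax(np.abs(w), axis=0)
    w = w * np.sign(w[piv, np.arange(w.shape[1])])
    centroids = {c: means[c] @ w for c in classes}
    return FldModel(directions=w, centroids=centroids)


def fld_transform(model: FldModel, scores: np.ndarray) -> np.ndarray:
    """Project score rows onto the discriminant directions."""
    x = np.asarray(scores, dtype=float)
    if x.shape[1] != model.directions.shape[0]:
        raise ValueError(
            f"{x.shape[1]} features vs model's {model.directions.shape[0]}"
        )
    return x @ model.directions


def fld_predict(model: FldModel, scores: np.ndarray) -> list:
    """Nearest-centroid assignment in discriminant space (ties: class order)."""
    z = fld_transform(model, scores)
    classes = model.classes
    cents = np.stack([model.centroids[c] for c in classes])
    d2 = np.sum((z[:, None, :] - cents[None, :, :]) ** 2, axis=2)
    idx = np.argmin(d2, axis=1)  # first minimum -> first class on ties
    return [classes[i] for i in idx]
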