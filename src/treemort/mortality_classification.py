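"""Gaussian maximum-likelihood pixel classification and crown dieback status.

Pixels of the 4-band imagery are assigned to spectral classes (sunlit/shaded
x live/dead plus background) by maximum Gaussian likelihood; the dead
classes collapse to a binary raster; each crown's dieback fraction is the
mean of that binary raster over its pixels; and a crown is called a dead
tree when its dieback fraction exceeds a threshold (default 0.375,
calibratable against validation labels by grid search).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.375


@dataclass
class MLCModel:
    """Per-class Gaussian model for maximum-likelihood classification."""

    class_names: list
    means: np.ndarray       # (k, bands)
    covs: np.ndarray        # (k, bands, bands)
    priors: np.ndarray      # (k,), sums to 1
    ridge_applied: dict = field(default_factory=dict)

    def validate(self) -> None:
        k = len(self.class_names)
        assert self.means.shape[0] == k and self.covs.shape[0] == k
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")
        for i, name in enumerate(self.class_names):
            c = self.covs[i]
            if not np.allclose(c, c.T):
                raise ValueError(f"covariance for {name!r} not symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError(f"covariance for {name!r} not positive definite")


def train_mlc(pixels: np.ndarray, labels, class_names=None,
              priors=None, ridge_rel: float = 1e-6) -> MLCModel:
    """Fit per-class means and covariances from labeled band vectors.

    `pixels` is (n, bands); `labels` gives each pixel's class name. Requires
    at least two classes and five pixels per class. Near-singular sample
    covariances are ridge-regularized with eps = ridge_rel * trace / bands
    (eps = ridge_rel when the trace is zero), and the regularization is
    recorded on the model. Priors default to equal.
    """
    pixels = np.asarray(pixels, dtype=float)
    labels = np.asarray(labels)
    if class_names is None:
        class_names = sorted(set(labels.tolist()))
    if len(class_names) < 2:
        raise ValueError("need at least 2 classes")
    bands = pixels.shape[1]
    means = np.zeros((len(class_names), bands))
    covs = np.zeros((len(class_names), bands, bands))
    ridge_applied = {}
    for i, name in enumerate(class_names):
        sel = pixels[labels == name]
        if len(sel) < 5:
            raise ValueError(f"class {name!r} has {len(sel)} pixels; need >= 5")
        means[i] = sel.mean(axis=0)
        cov = np.cov(sel, rowvar=False, ddof=1)
        if np.linalg.eigvalsh(cov).min() <= 1e-10 * max(np.trace(cov), 1.0):
            eps = ridge_rel * np.trace(cov) / bands
            if eps <= 0:
                eps = ridge_rel
            cov = cov + eps * np.eye(bands)
            ridge_applied[name] = eps
            logger.info("ridge-regularized covariance for class %r (eps=%.3g)",
                        name, eps)
        covs[i] = cov
    if priors is None:
        priors = np.full(len(class_names), 1.0 / len(class_names))
    model = MLCModel(class_names=list(class_names), means=means, covs=covs,
                     priors=np.asarray(priors, dtype=float),
                     ridge_applied=ridge_applied)
    model.validate()
    return model


def _log_densities(vectors: np.ndarray, model: MLCModel) -> np.ndarray:
    """(n, k) Gaussian log-density + log-prior for each pixel and class."""
    n, bands = vectors.shape
    out = np.empty((n, len(model.class_names)))
    for i in range(len(model.class_names)):
        chol = np.linalg.cholesky(model.covs[i])
        diff = vectors - model.means[i]
        z = np.linalg.solve(chol, diff.T)
        maha = np.sum(z ** 2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, i] = (-0.5 * (maha + logdet + bands * np.log(2 * np.pi))
                     + np.log(model.priors[i]))
    return out


def classify_pixels(imagery: np.ndarray, model: MLCModel) -> np.ndarray:
    """Assign each pixel the argmax class of Gaussian log-density + log-prior.

    `imagery` is (bands, rows, cols) or (n, bands). Ties go to the lowest
    class index. Pixels with any non-finite band are assigned the
    'background' class (which must then exist in the model) and tallied in
    the log.
    """
    arr = np.asarray(imagery, dtype=float)
    if arr.ndim == 3:
        bands, rows, cols = arr.shape
        flat = arr.reshape(bands, -1).T
        out_shape = (rows, cols)
    else:
        flat = arr
        out_shape = (arr.shape[0],)
    if flat.shape[1] != model.means.shape[1]:
        raise ValueError("band count does not match model")
    finite = np.isfinite(flat).all(axis=1)
    labels = np.zeros(flat.shape[0], dtype=np.int32)
    if finite.any():
        dens = _log_densities(flat[finite], model)
        labels[finite] = np.argmax(dens, axis=1)  # argmax ties -> lowest index
    n_bad = int((~finite).sum())
    if n_bad:
        if "background" not in model.class_names:
            raise ValueError("non-finite pixels present but model has no "
                             "'background' class")
        labels[~finite] = model.class_names.index("background")
        logger.warning("%d pixels had non-finite bands; classified as background",
                       n_bad)
    return labels.reshape(out_shape)


def collapse_to_dead(class_raster: np.ndarray, class_names) -> np.ndarray:
    """Map dead classes to 1 and everything else to 0."""
    dead_idx = [i for i, n in enumerate(class_names) if "dead" in n]
    return np.isin(class_raster, dead_idx).astype(np.uint8)


def crown_dead_fraction(crown_labels: np.ndarray, dead_raster: np.ndarray) -> pd.DataFrame:
    """Per-crown dieback fraction: mean of the binary dead raster over each
    crown's pixels. Returns crown_id, dead_fraction, pixel_count."""
    crown_labels = np.asarray(crown_labels)
    dead_raster = np.asarray(dead_raster)
    if crown_labels.shape != dead_raster.shape:
        raise ValueError("crown label raster and dead raster shapes differ")
    ids = np.unique(crown_labels[crown_labels > 0])
    recs = []
    for cid in ids:
        m = crown_labels == cid
        npx = int(m.sum())
        if npx == 0:
            raise ValueError(f"crown {cid} has zero pixels")
        recs.append({"crown_id": int(cid),
                     "dead_fraction": float(dead_raster[m].mean()),
                     "pixel_count": npx})
    return pd.DataFrame(recs, columns=["crown_id", "dead_fraction", "pixel_count"])


def classify_crown_status(dead_fraction, threshold: float = DEFAULT_THRESHOLD):
    """Dead iff dead_fraction strictly exceeds the threshold.

    Accepts a scalar or array; returns 'dead'/'live' (scalar) or a boolean
    array (True = dead).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    frac = np.asarray(dead_fraction, dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("dead_fraction must be in [0, 1]")
    dead = frac > threshold
    if np.isscalar(dead_fraction) or frac.ndim == 0:
        return "dead" if bool(dead) else "live"
    return dead


@dataclass
class ThresholdCurve:
    """Threshold sensitivity curve from validation labels.

    ``curve`` has one row per grid threshold with overall accuracy, the
    false-positive rate (live crowns called dead), the false-negative rate
    (dead crowns called live), and bias = FPR - FNR. ``selected`` is the
    accuracy-maximizing threshold; near-ties in accuracy (within
    ``tie_tol``) are broken by minimum |bias| ("unbiased"), then by the
    smaller threshold.
    """

    curve: pd.DataFrame
    selected: float
    selected_accuracy: float
    tie_tol: float


def calibrate_threshold(dead_fractions, truth_dead, grid_step: float = 0.025,
                        tie_tol: float = 0.005) -> ThresholdCurve:
    """Grid-search the crown dieback threshold against validation labels."""
    frac = np.asarray(dead_fractions, dtype=float)
    truth = np.asarray(truth_dead, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one true-dead and one true-live crown")
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    recs = []
    for t in grid:
        pred = frac > t
        tp = int((pred & truth).sum())
        fp = int((pred & ~truth).sum())
        fn = int((~pred & truth).sum())
        tn = int((~pred & ~truth).sum())
        acc = (tp + tn) / len(truth)
        fpr = fp / n_neg
        fnr = fn / n_pos
        recs.append({"threshold": t, "accuracy": acc, "fpr": fpr, "fnr": fnr,
                     "bias": fpr - fnr})
    curve = pd.DataFrame(recs)
    best_acc = curve["accuracy"].max()
    near = curve[curve["accuracy"] >= best_acc - tie_tol].copy()
    near["absbias"] = near["bias"].abs()
    near = near.sort_values(["absbias", "threshold"], kind="stable")
    sel = near.iloc[0]
    return ThresholdCurve(curve=curve, selected=float(sel["threshold"]),
                          selected_accuracy=float(sel["accuracy"]), tie_tol=tie_tol)
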