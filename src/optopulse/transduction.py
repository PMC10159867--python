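"""Transduction quantification from per-soma fluorescence brightness.

The brightness distribution of immunolabeled neuron somas is fitted with a
Gaussian mixture (up to three components, selected by BIC); somas brighter
than mean + 3 SD of the lowest-mean component — i.e. beyond the
non-expressing background — count as transduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = ["BrightnessModel", "gmm_threshold", "transduction_rate", "correlate"]


@dataclass
class BrightnessModel:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    n_components: int
    threshold: float  # mean_low + 3 * sd_low
    bic: float

    @property
    def low_component(self) -> int:
        return int(np.argmin(self.means))


def gmm_threshold(
    brightness,
    max_components: int = 3,
    seed: int | None = None,
    n_restarts: int = 10,
) -> BrightnessModel:
    """Mixture-model brightness threshold: mu_low + 3 * sigma_low.

    Fits 1..max_components Gaussian mixtures by EM (seeded, ``n_restarts``
    initializations each), keeps the BIC-best model and derives the
    threshold from its lowest-mean component.
    """
    x = np.asarray(brightness, dtype=float).reshape(-1, 1)
    if x.shape[0] < 20:
        raise ValueError("at least 20 brightness values are required")
    if seed is None:
        raise ValueError("a seed is required")
    best = None
    best_bic = np.inf
    for n in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=n, n_init=n_restarts, random_state=seed,
            covariance_type="full",
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best, best_bic = gm, bic
    means = best.means_.ravel()
    sds = np.sqrt(best.covariances_.reshape(-1))
    if np.any(sds < 1e-9):
        raise RuntimeError("degenerate mixture fit: a component has zero variance")
    low = int(np.argmin(means))
    return BrightnessModel(
        means=means, sds=sds, weights=best.weights_.ravel(),
        n_components=best.n_components,
        threshold=float(means[low] + 3.0 * sds[low]),
        bic=float(best_bic),
    )


def transduction_rate(brightness, threshold: float) -> float:
    """Fraction of somas brighter than the mixture threshold."""
    x = np.asarray(brightness, dtype=float)
    if x.size == 0:
        raise ValueError("no brightness values provided")
    return float(np.mean(x > threshold))


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
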