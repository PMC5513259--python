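"""Shared statistical primitives.

Two conventions are fixed here once and used everywhere in the package:

* **Percentiles** use linear interpolation between order statistics,
  evaluating at rank ``h = (n - 1) * p / 100 + 1`` (the same convention as
  ``numpy.percentile`` with ``method="linear"`` and R's ``quantile`` type 7).
* **Distance correlation** (Székely, Rizzo & Bakirov) is the dependence
  measure used both for FAPAR neighbor-pixel screening and for trait–capacity
  association.  It lies in [0, 1] and detects nonlinear dependence.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["percentile", "distance_correlation", "r_squared"]


def percentile(values, p: float) -> float:
    """Percentile with the repo-wide linear-interpolation convention.

    Parameters
    ----------
    values : array-like
        Sample values; NaN entries are dropped.
    p : float
        Percentile in [0, 100].

    Raises
    ------
    ValueError
        If no finite values remain or ``p`` is out of range.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("percentile of an empty sample")
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentile p={p} outside [0, 100]")
    return float(np.percentile(v, p, method="linear"))


def _centered_distances(x: np.ndarray) -> np.ndarray:
    """Double-centered Euclidean distance matrix of a 1-D sample."""
    d = squareform(pdist(x[:, None]))
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x, y) -> float:
    """Sample distance correlation of two 1-D samples (biased V-statistic).

    Computed by double-centering the pairwise Euclidean distance matrices:
    ``dcor² = <A, B> / sqrt(<A, A> <B, B>)``.  Returns a value in [0, 1];
    1 for exact affine dependence, 0 only under independence (in population).

    Raises
    ------
    ValueError
        If the samples differ in length, have fewer than 4 points, contain
        NaN, or either sample is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("distance_correlation expects two equal-length 1-D samples")
    if x.size < 4:
        raise ValueError("distance_correlation needs at least 4 points")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("distance_correlation: NaN in input")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("distance_correlation undefined for a constant sample")
    a = _centered_distances(x)
    b = _centered_distances(y)
    dcov2 = (a * b).mean()
    dvar_x = (a * a).mean()
    dvar_y = (b * b).mean()
    denom = np.sqrt(dvar_x * dvar_y)
    if denom <= 0.0:
        raise ValueError("distance_correlation: degenerate distance variance")
    # tiny negative values can arise from rounding
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SSE/SST (SST about the observed mean).

    May be negative when the predictions are worse than the mean.

    Raises
    ------
    ValueError
        If fewer than 2 points or the observations have zero variance.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("r_squared needs >= 2 paired points")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("r_squared undefined: observed values have zero variance")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst
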