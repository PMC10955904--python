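"""Descriptive force metrics, parameter-space PCA and the named skill axes.

The regime model compresses each trial into six parameters
(v_L, v_U, sigma2_L, sigma2_U, q12, q21). A PCA of the standardized
per-trial parameter vectors yields three interpretable components:
PC1 loads on a drop in v_L together with a rise in q21 (frequent,
drastic force loss), PC2 on a rise in q12 (sharp force onsets), PC3 on a
drop in v_U. Three diagonal axes in this space name the behaviours:

- Abruptness = (PC1 + PC2)/sqrt(2): discontinuity of execution;
- Energy     = -(PC1 + PC3)/sqrt(2): high forces held for long;
- Confidence = (PC3 - PC1)/sqrt(2): steady, narrow-envelope force
  application, orthogonal to Energy by construction.

Score surfaces linearly interpolate expert grades over 2-D feature
coordinates (Delaunay triangulation / barycentric interpolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError
from sklearn.decomposition import PCA

from .profiles import ForceProfile
from .regime import RegimeModel

__all__ = [
    "DescriptiveMetrics",
    "FeatureSpace",
    "descriptive_metrics",
    "parameter_vector",
    "PARAMETER_NAMES",
    "fit_feature_space",
    "skill_axes",
    "score_surface",
]

PARAMETER_NAMES = ("v_L", "v_U", "sigma2_L", "sigma2_U", "q12", "q21")
# (feature index, wanted sign of its loading) per retained component:
# PC1 loads positively on q21, PC2 positively on q12, PC3 negatively on v_U
_SIGN_ANCHORS = ((5, +1.0), (4, +1.0), (1, -1.0))


@dataclass(frozen=True)
class DescriptiveMetrics:
    """The six conventional force-based performance metrics.

    mean_force and force_std summarize amplitude and variability;
    peak_force the maximum; scaled_force = mean/peak flags overshoot
    (low values mean a transient spike dominates); force_derivative is
    the mean absolute forward-difference slope (units s^-1, an
    aggressiveness proxy); force_integral is the trapezoid integral over
    the profile duration (a cutting-energy proxy).
    """

    mean_force: float
    force_std: float
    peak_force: float
    scaled_force: float
    force_derivative: float
    force_integral: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_force": self.mean_force,
            "force_std": self.force_std,
            "peak_force": self.peak_force,
            "scaled_force": self.scaled_force,
            "force_derivative": self.force_derivative,
            "force_integral": self.force_integral,
        }


def descriptive_metrics(f: ForceProfile) -> DescriptiveMetrics:
    """Compute the six descriptive metrics for one profile.

    Requires at least 2 samples; an all-zero profile has no defined
    scaled force and raises.
    """
    s = f.samples
    if s.size < 2:
        raise ValueError("need at least 2 samples for descriptive metrics")
    peak = float(s.max())
    if peak <= 0:
        raise ValueError("scaled force undefined for an all-zero (or negative) profile")
    mean = float(s.mean())
    return DescriptiveMetrics(
        mean_force=mean,
        force_std=float(s.std(ddof=1)),
        peak_force=peak,
        scaled_force=mean / peak,
        force_derivative=float(np.mean(np.abs(np.diff(s))) * f.rate),
        force_integral=float(np.trapezoid(s, dx=f.dt)),
    )


def parameter_vector(m: RegimeModel) -> np.ndarray:
    """Fixed-layout feature vector (v_L, v_U, sigma2_L, sigma2_U, q12, q21).

    q11 and q22 are excluded: rows of Q sum to 1 so they are exactly
    collinear with q12 and q21. Defined only for 2-regime models.
    """
    if m.K != 2:
        raise ValueError("parameter vector is defined only for 2-regime models")
    return np.array(
        [m.v[0], m.v[1], m.sigma2[0], m.sigma2[1], m.Q[0, 1], m.Q[1, 0]], dtype=float
    )


@dataclass(frozen=True)
class FeatureSpace:
    """Standardized-PCA representation of per-trial parameter vectors."""

    mean: np.ndarray  # per-coordinate standardization mean
    scale: np.ndarray  # per-coordinate standardization sd
    kept: np.ndarray  # indices into PARAMETER_NAMES that survived
    loadings: np.ndarray  # (n_components, len(kept)), orthonormal rows
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n_trials, n_components)
    labels: tuple = ()

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        """Project new parameter vectors into the fitted space."""
        X = np.atleast_2d(np.asarray(vectors, dtype=float))
        Z = (X[:, self.kept] - self.mean) / self.scale
        return Z @ self.loadings.T


def fit_feature_space(
    vectors: Sequence[np.ndarray] | np.ndarray,
    n_components: int = 3,
    standardize: bool = True,
    labels: Sequence | None = None,
) -> FeatureSpace:
    """Z-score the parameter vectors, run PCA, orient component signs.

    Coordinates with zero variance carry no information and are dropped
    with a warning. Sign orientation is deterministic: PC1 is flipped to
    load positively on q21, PC2 positively on q12, PC3 negatively on
    v_U; if an anchor coordinate was dropped or its loading vanishes,
    the component's largest-magnitude loading is made positive instead.
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[0] < 4:
        raise ValueError("need at least 4 parameter vectors to fit the feature space")
    sd = X.std(axis=0, ddof=0)
    # round-off guard: a numerically constant column is zero-variance
    tiny = np.maximum(np.abs(X).max(axis=0), 1.0) * 1e-12
    keep_mask = sd > tiny
    kept = np.nonzero(keep_mask)[0]
    if kept.size < X.shape[1]:
        dropped = [PARAMETER_NAMES[i] if i < len(PARAMETER_NAMES) else str(i)
                   for i in np.nonzero(~keep_mask)[0]]
        warnings.warn(
            f"dropping zero-variance coordinates: {dropped}", RuntimeWarning
        )
    Xk = X[:, kept]
    mean = Xk.mean(axis=0)
    scale = Xk.std(axis=0, ddof=0) if standardize else np.ones(kept.size)
    Z = (Xk - mean) / scale
    k = min(n_components, kept.size, X.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.copy()

    kept_list = kept.tolist()
    for comp, (feat, want) in enumerate(_SIGN_ANCHORS[:k]):
        if feat in kept_list:
            load = loadings[comp, kept_list.index(feat)]
        else:
            load = 0.0
        if load == 0.0:
            j = int(np.argmax(np.abs(loadings[comp])))
            flip = loadings[comp, j] < 0
        else:
            flip = (load * want) < 0
        if flip:
            loadings[comp] *= -1.0
            scores[:, comp] *= -1.0

    return FeatureSpace(
        mean=mean,
        scale=scale,
        kept=kept,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
        labels=tuple(labels) if labels is not None else (),
    )


def skill_axes(space: FeatureSpace, scores: np.ndarray | None = None) -> pd.DataFrame:
    """Per-trial (abruptness, energy, confidence) from PCA scores.

    The axes are unit-normalized +/-45-degree rotations of the component
    planes; energy and confidence are orthogonal by construction.
    """
    pcs = space.scores if scores is None else np.atleast_2d(scores)
    if pcs.shape[1] < 3:
        raise ValueError("skill axes require 3 retained components")
    pc1, pc2, pc3 = pcs[:, 0], pcs[:, 1], pcs[:, 2]
    rt2 = np.sqrt(2.0)
    frame = pd.DataFrame(
        {
            "abruptness": (pc1 + pc2) / rt2,
            "energy": -(pc1 + pc3) / rt2,
            "confidence": (pc3 - pc1) / rt2,
        }
    )
    if scores is None and space.labels:
        frame.index = pd.Index(space.labels, name="trial")
    return frame


def score_surface(
    points: np.ndarray,
    scores: np.ndarray,
    grid: int | tuple[np.ndarray, np.ndarray] = 50,
):
    """Piecewise-linear interpolation of expert grades over 2-D features.

    Triangulates the points (Delaunay) and interpolates barycentrically;
    grid nodes outside the convex hull are NaN. Returns (gx, gy, values)
    with ``values`` shaped (len(gy), len(gx)).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vals = np.asarray(scores, dtype=float)
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("need at least 3 two-dimensional points")
    if vals.shape[0] != pts.shape[0]:
        raise ValueError("scores must match points")
    try:
        interp = LinearNDInterpolator(pts, vals)
    except QhullError as exc:
        raise ValueError(f"points are collinear or degenerate: {exc}") from None
    if isinstance(grid, int):
        gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid)
        gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid)
    else:
        gx, gy = (np.asarray(g, dtype=float) for g in grid)
    GX, GY = np.meshgrid(gx, gy)
    return gx, gy, interp(GX, GY)
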