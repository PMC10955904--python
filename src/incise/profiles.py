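"""Fixed-rate time-series containers for force, displacement and velocity.

All profiles are immutable-by-convention wrappers around 1-D float arrays
with sampling metadata. Forces are in newtons or, after dataset
normalisation, in dimensionless units on [0, 1]. Displacements are nominal
centimetres and velocities nominal cm s^-1: under the Maxwell model they
are "virtual" kinematic quantities implied by the measured force, not
measured ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["ForceProfile", "DisplacementProfile", "VelocityProfile"]


def _as_samples(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} samples must be 1-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} must contain at least one sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} samples must all be finite")
    return arr


@dataclass(frozen=True)
class _Profile:
    samples: np.ndarray
    rate: float = 30.0
    label: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(
            self, "samples", _as_samples(self.samples, type(self).__name__)
        )
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Time spanned by the samples, (n - 1) / rate, in seconds."""
        return (len(self) - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate

    def with_samples(self, samples) -> "_Profile":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class ForceProfile(_Profile):
    """A fixed-rate sequence of scalar cutting-force samples.

    Parameters
    ----------
    samples : array-like
        Force values, newtons or normalized units.
    rate : float
        Sampling rate in Hz (the study instrument records at 30 Hz).
    label : str, optional
        Subject/trial identifier.
    normalized : bool
        True once the profile has been divided by a dataset-global
        maximum; normalized samples must lie in [0, 1].
    """

    normalized: bool = False

    def __post_init__(self):
        super().__post_init__()
        if self.normalized:
            if self.samples.min() < 0 or self.samples.max() > 1 + 1e-12:
                raise ValueError("normalized force samples must lie in [0, 1]")


@dataclass(frozen=True)
class DisplacementProfile(_Profile):
    """Virtual blade displacement, nominal cm."""


@dataclass(frozen=True)
class VelocityProfile(_Profile):
    """Virtual blade velocity, nominal cm s^-1.

    Produced by forward finite differences of a displacement profile, so
    it is one sample shorter than its source.
    """
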