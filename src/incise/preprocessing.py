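"""Raw-recording preprocessing: onset alignment, fixed-length cropping,
dataset-global normalization.

The study protocol crops every recording to 120 samples (4 s at 30 Hz)
and divides all samples by the single maximum force observed across the
entire dataset, so profiles share one scale and the global maximum maps
to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .profiles import ForceProfile

__all__ = ["align_and_crop", "normalize_dataset", "NormalizedDataset"]

DEFAULT_TARGET_LEN = 120
DEFAULT_ONSET_FRACTION = 0.10


def align_and_crop(
    recording: ForceProfile,
    target_len: int = DEFAULT_TARGET_LEN,
    onset_fraction: float = DEFAULT_ONSET_FRACTION,
) -> ForceProfile:
    """Align a raw recording to its force onset and crop to a fixed length.

    The onset is the first sample exceeding ``onset_fraction`` times the
    recording's own maximum; the output is the ``target_len`` samples
    starting there, copied bit-exactly (no resampling or filtering).

    Raises
    ------
    ValueError
        If the recording has no positive sample (no detectable onset) or
        has fewer than ``target_len`` samples after the onset; the error
        message names the deficit.
    """
    if target_len < 1:
        raise ValueError("target_len must be at least 1")
    if not 0 <= onset_fraction < 1:
        raise ValueError("onset_fraction must lie in [0, 1)")
    s = recording.samples
    peak = s.max()
    if peak <= 0:
        raise ValueError("recording has no positive samples; cannot detect an onset")
    above = np.nonzero(s > onset_fraction * peak)[0]
    onset = int(above[0])
    available = s.size - onset
    if available < target_len:
        raise ValueError(
            f"recording too short: need {target_len} samples from onset at "
            f"index {onset}, only {available} available (deficit "
            f"{target_len - available})"
        )
    return ForceProfile(
        samples=s[onset : onset + target_len].copy(),
        rate=recording.rate,
        label=recording.label,
    )


@dataclass(frozen=True)
class NormalizedDataset:
    """Profiles rescaled by one shared constant.

    ``constant`` is the pre-normalization global maximum; it is kept with
    the dataset so simulated and measured profiles can share a scale and
    the normalization can be undone.
    """

    profiles: tuple[ForceProfile, ...]
    constant: float

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, i):
        return self.profiles[i]


def normalize_dataset(profiles: Iterable[ForceProfile]) -> NormalizedDataset:
    """Divide every sample of every profile by the dataset-global maximum.

    After normalization the global maximum is exactly 1 and every
    per-profile maximum is <= 1. Idempotent: renormalizing a normalized
    dataset changes nothing. Order of profiles does not affect the
    constant.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cannot normalize an empty dataset")
    global_max = max(float(p.samples.max()) for p in profiles)
    if global_max <= 0:
        raise ValueError("dataset-global maximum must be positive to normalize")
    out = tuple(
        replace(p, samples=p.samples / global_max, normalized=True) for p in profiles
    )
    return NormalizedDataset(profiles=out, constant=global_max)
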