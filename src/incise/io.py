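"""CSV/JSON/YAML interchange and run configuration.

Exchange formats are plain text. Force profiles travel as a long-format
CSV with columns (subject, trial, cut, sample_index, force); expert
scores as (subject_trial, rater, score); fitted models as versioned
JSON; run configuration as YAML with unknown keys rejected.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import TrialSet
from .profiles import ForceProfile
from .regime import RegimeModel

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_scores",
    "write_scores",
    "read_model",
    "write_model",
    "MaxwellConfig",
    "HmmConfig",
    "RunConfig",
]

PROFILE_COLUMNS = ["subject", "trial", "cut", "sample_index", "force"]
SCORE_COLUMNS = ["subject_trial", "rater", "score"]
MODEL_SCHEMA_VERSION = 1


def write_profiles(trialset: TrialSet, path) -> None:
    """Write a TrialSet as the documented long-format CSV."""
    trialset.to_long_frame().to_csv(path, index=False, float_format="%.17g")


def read_profiles(path, rate: float = 30.0) -> TrialSet:
    """Read a long-format profile CSV back into a TrialSet.

    Missing required columns raise an error naming them; malformed
    (non-numeric) force rows are reported with their line numbers.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    missing = [c for c in PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    force = pd.to_numeric(frame["force"], errors="coerce")
    bad = np.nonzero(~np.isfinite(force.to_numpy()))[0]
    if bad.size:
        # +2: header line plus 1-based indexing
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"{path}: malformed force values at line(s) {lines}")
    frame = frame.assign(force=force)
    subjects, trials, cuts, profiles = [], [], [], []
    for (subj, trial, cut), g in frame.groupby(
        ["subject", "trial", "cut"], sort=True
    ):
        g = g.sort_values("sample_index")
        subjects.append(str(subj))
        trials.append(int(trial))
        cuts.append(int(cut))
        profiles.append(
            ForceProfile(
                samples=g["force"].to_numpy(),
                rate=rate,
                label=f"{subj}:{trial}:{cut}",
            )
        )
    return TrialSet(subjects=subjects, trials=trials, cuts=cuts, profiles=profiles)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores[SCORE_COLUMNS].to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return frame


def write_model(model: RegimeModel, path) -> None:
    d = model.to_dict()
    d["schema_version"] = MODEL_SCHEMA_VERSION
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_model(path) -> RegimeModel:
    d = json.loads(Path(path).read_text())
    return RegimeModel.from_dict(d)


@dataclass
class MaxwellConfig:
    E: float = 1.0
    eta: float = 0.5


@dataclass
class HmmConfig:
    K: int = 2
    max_iter: int = 200
    tol: float = 1e-4
    seed: int = 0


@dataclass
class RunConfig:
    """Pipeline configuration; seeds are explicit, never global.

    All numeric fields must be positive; unknown keys in a YAML source
    are rejected so typos fail loudly.
    """

    rate: float = 30.0
    target_len: int = 120
    onset_fraction: float = 0.10
    maxwell: MaxwellConfig = field(default_factory=MaxwellConfig)
    hmm: HmmConfig = field(default_factory=HmmConfig)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.maxwell, dict):
            self.maxwell = _from_mapping(MaxwellConfig, self.maxwell)
        if isinstance(self.hmm, dict):
            self.hmm = _from_mapping(HmmConfig, self.hmm)
        for name, val in (
            ("rate", self.rate),
            ("target_len", self.target_len),
            ("maxwell.E", self.maxwell.E),
            ("maxwell.eta", self.maxwell.eta),
            ("hmm.K", self.hmm.K),
            ("hmm.max_iter", self.hmm.max_iter),
            ("hmm.tol", self.hmm.tol),
        ):
            if not val > 0:
                raise ValueError(f"config field {name} must be positive")
        if not 0 <= self.onset_fraction < 1:
            raise ValueError("onset_fraction must lie in [0, 1)")
        if self.seed < 0 or self.hmm.seed < 0:
            raise ValueError("seeds must be non-negative")

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            text = Path(source)
            data = yaml.safe_load(text.read_text()) if text.exists() else yaml.safe_load(str(source))
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        return _from_mapping(cls, data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _from_mapping(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)
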