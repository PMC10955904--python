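"""Synthetic-cohort generation: regime model -> velocity path -> Maxwell
force rendering, plus archetype cohorts with optional synthetic expert
scores.

The generative direction mirrors the study conditions: 120-sample force
profiles at 30 Hz, produced by a 2-state Markov chain over blade
velocities with Gaussian velocity noise (sd 0.35, velocities within
[0, 8]), rendered through a Maxwell body with E = 1 N cm^-1 and
eta = 0.5 N s cm^-1. A trial comprises six excisions of two cuts each,
i.e. 12 profiles. Four named archetypes, loosely styled on the
qualitative behaviours described for the study's subjects, give every
downstream statistic a ground-truthed fixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .maxwell import MaxwellParams, simulate_force
from .profiles import ForceProfile, VelocityProfile
from .regime import RegimeModel, sample

__all__ = [
    "ArchetypeSpec",
    "TrialSet",
    "generate_profile",
    "generate_trial",
    "generate_cohort",
    "default_archetypes",
    "linear_score_rule",
]

VELOCITY_RANGE = (0.0, 8.0)  # nominal mm s^-1 band of plausible blade speeds
DEFAULT_SIGMA = 0.35  # velocity noise sd within a regime


@dataclass(frozen=True)
class ArchetypeSpec:
    """A named generative behaviour: regime parameters + Maxwell body.

    ``v_L``/``v_U`` are the lower/upper regime mean velocities, ``sigma_L``
    and ``sigma_U`` the within-regime velocity standard deviations, and
    ``q12``/``q21`` the L->U and U->L switching probabilities per 1/rate
    step. Default geometry matches the study: 12 profiles of 120 samples
    per trial at 30 Hz.
    """

    name: str
    v_L: float
    v_U: float
    q12: float
    q21: float
    sigma_L: float = DEFAULT_SIGMA
    sigma_U: float = DEFAULT_SIGMA
    maxwell: MaxwellParams = field(default_factory=MaxwellParams)
    profiles_per_trial: int = 12
    length: int = 120
    seed: int = 0

    def __post_init__(self):
        lo, hi = VELOCITY_RANGE
        if not (lo <= self.v_L <= hi and lo <= self.v_U <= hi):
            raise ValueError(
                f"regime mean velocities must lie in [{lo}, {hi}] "
                f"(got v_L={self.v_L}, v_U={self.v_U})"
            )
        if self.v_L > self.v_U:
            raise ValueError("require v_L <= v_U")
        if not (0 <= self.q12 <= 1 and 0 <= self.q21 <= 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if self.sigma_L < 0 or self.sigma_U < 0:
            raise ValueError("velocity noise sd must be non-negative")
        if self.profiles_per_trial < 1:
            raise ValueError("profiles_per_trial must be at least 1")
        if self.length < 2:
            raise ValueError("profile length must be at least 2")

    @property
    def rate(self) -> float:
        return 1.0 / self.maxwell.dt

    def regime_model(self) -> RegimeModel:
        """The exact RegimeModel this archetype samples from."""
        var_floor = 1e-12
        return RegimeModel(
            v=[self.v_L, self.v_U],
            sigma2=[max(self.sigma_L**2, var_floor), max(self.sigma_U**2, var_floor)],
            Q=[[1 - self.q12, self.q12], [self.q21, 1 - self.q21]],
            pi0=[0.5, 0.5],
            meta={"dt": self.maxwell.dt, "archetype": self.name},
        )


@dataclass
class TrialSet:
    """Profiles grouped by subject and trial, with optional expert scores.

    ``records`` is a long table with columns (subject, trial, cut) and a
    parallel list of profiles; ``scores``, when present, is a tidy frame
    with columns (subject_trial, rater, score), scores in {0, 1, 2, 3}.
    """

    subjects: list[str]
    trials: list[int]
    cuts: list[int]
    profiles: list[ForceProfile]
    scores: Optional[pd.DataFrame] = None

    def __post_init__(self):
        n = len(self.profiles)
        if not (len(self.subjects) == len(self.trials) == len(self.cuts) == n):
            raise ValueError("subjects/trials/cuts/profiles must have equal length")
        if n:
            L, r = len(self.profiles[0]), self.profiles[0].rate
            if any(len(p) != L or p.rate != r for p in self.profiles):
                raise ValueError("all profiles in a TrialSet must share length and rate")
        if self.scores is not None:
            bad = set(self.scores["score"]) - {0, 1, 2, 3}
            if bad:
                raise ValueError(f"expert scores must be in {{0,1,2,3}}, got {bad}")

    def __len__(self) -> int:
        return len(self.profiles)

    def by_trial(self) -> dict[tuple[str, int], list[ForceProfile]]:
        """Profiles grouped by (subject, trial)."""
        out: dict[tuple[str, int], list[ForceProfile]] = {}
        for s, t, p in zip(self.subjects, self.trials, self.profiles):
            out.setdefault((s, t), []).append(p)
        return out

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: subject, trial, cut, sample_index, force."""
        frames = []
        for s, t, c, p in zip(self.subjects, self.trials, self.cuts, self.profiles):
            frames.append(
                pd.DataFrame(
                    {
                        "subject": s,
                        "trial": t,
                        "cut": c,
                        "sample_index": np.arange(len(p)),
                        "force": p.samples,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def rater_table(self) -> pd.DataFrame:
        """Scores pivoted to trials x raters (for ICC)."""
        if self.scores is None:
            raise ValueError("this TrialSet has no expert scores")
        return self.scores.pivot(index="subject_trial", columns="rater", values="score")

    @staticmethod
    def concat(parts: Sequence["TrialSet"]) -> "TrialSet":
        scores = [p.scores for p in parts if p.scores is not None]
        return TrialSet(
            subjects=sum((p.subjects for p in parts), []),
            trials=sum((p.trials for p in parts), []),
            cuts=sum((p.cuts for p in parts), []),
            profiles=sum((p.profiles for p in parts), []),
            scores=pd.concat(scores, ignore_index=True) if scores else None,
        )


def generate_profile(spec: ArchetypeSpec, seed: int | np.random.Generator = 0) -> ForceProfile:
    """Render one force profile: regime path -> velocity -> Maxwell force.

    Samples ``spec.length`` velocity steps from the archetype's regime
    model and integrates them through the Maxwell body from rest
    (f0 = 0), so the force rises step-like toward eta * v_k and is
    modulated by the regime switches. Deterministic under a fixed seed.
    """
    model = spec.regime_model()
    _, vel = sample(model, spec.length, seed)
    return ForceProfile(
        samples=simulate_force(vel, spec.maxwell, f0=0.0).samples,
        rate=spec.rate,
        label=spec.name,
    )


def generate_trial(
    spec: ArchetypeSpec,
    trial: int = 1,
    seed: int | np.random.SeedSequence | None = None,
) -> TrialSet:
    """One trial: six excisions x two cuts = ``profiles_per_trial`` profiles.

    Per-profile seeds are spawned deterministically from the trial seed,
    so a rerun is bit-identical and profiles are mutually independent.
    """
    if seed is None:
        seed = spec.seed
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = root.spawn(spec.profiles_per_trial)
    profiles = [
        generate_profile(spec, np.random.default_rng(child)) for child in children
    ]
    n = spec.profiles_per_trial
    return TrialSet(
        subjects=[spec.name] * n,
        trials=[trial] * n,
        cuts=list(range(1, n + 1)),
        profiles=profiles,
    )


ScoreRule = Callable[[ArchetypeSpec, str], float]


def linear_score_rule(
    base_scores: Mapping[str, float],
    rater_bias: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ScoreRule:
    """Deterministic-plus-noise scoring rule for synthetic raters.

    Each rater grades archetype ``a`` as round(base_scores[a.name] +
    rater_bias[rater] + noise), clipped to the 0-3 proficiency scale.
    With no bias and no noise all raters agree exactly (ICC = 1
    downstream); with large noise agreement washes out (ICC ~ 0).
    """
    rng = np.random.default_rng(seed)

    def rule(spec: ArchetypeSpec, rater: str) -> float:
        val = float(base_scores[spec.name])
        if rater_bias is not None:
            val += float(rater_bias.get(rater, 0.0))
        if noise_sd > 0:
            val += rng.normal(0.0, noise_sd)
        return val

    return rule


def generate_cohort(
    archetypes: Sequence[ArchetypeSpec],
    trials_per_archetype: int = 1,
    score_rule: ScoreRule | None = None,
    raters: Sequence[str] = ("R1", "R2", "R3", "R4"),
    seed: int = 0,
) -> TrialSet:
    """A cohort of archetype subjects with optional synthetic expert scores.

    One TrialSet per archetype per trial, concatenated; if ``score_rule``
    is given, every rater grades every subject-trial on the 0-3 scale.
    """
    archetypes = list(archetypes)
    if not archetypes:
        raise ValueError("need at least one archetype to generate a cohort")
    root = np.random.SeedSequence(seed)
    parts = []
    score_rows = []
    trial_seeds = root.spawn(len(archetypes) * trials_per_archetype)
    i = 0
    for spec in archetypes:
        for trial in range(1, trials_per_archetype + 1):
            ts = generate_trial(spec, trial=trial, seed=trial_seeds[i])
            i += 1
            parts.append(ts)
            if score_rule is not None:
                key = f"{spec.name}:{trial}"
                for rater in raters:
                    raw = score_rule(spec, rater)
                    score_rows.append(
                        {
                            "subject_trial": key,
                            "rater": rater,
                            "score": int(np.clip(round(raw), 0, 3)),
                        }
                    )
    cohort = TrialSet.concat(parts)
    if score_rows:
        cohort.scores = pd.DataFrame(score_rows)
    return cohort


def default_archetypes(seed: int = 0, **overrides) -> list[ArchetypeSpec]:
    """Four named behaviours spanning the cohort's qualitative range.

    - smooth_steady: symmetric, infrequent switching (balanced low
      transition probabilities), mid amplitude, narrow envelope.
    - steady_high_persistence: strongly favours the upper regime (rare
      drop-outs, quick recoveries), high steady force.
    - abrupt_with_recovery: frequent drops and rapid recoveries -- a
      discontinuous, re-tensioning-heavy execution.
    - interrupted: drops often and lingers in the lower regime, wide
      force envelope and low energy.
    """
    mk = MaxwellParams()
    base = dict(maxwell=mk, seed=seed, **overrides)
    return [
        ArchetypeSpec("smooth_steady", v_L=2.6, v_U=4.0, q12=0.037, q21=0.037, **base),
        ArchetypeSpec(
            "steady_high_persistence", v_L=3.0, v_U=5.5, q12=0.124, q21=0.028, **base
        ),
        ArchetypeSpec(
            "abrupt_with_recovery", v_L=1.2, v_U=5.0, q12=0.25, q21=0.20, **base
        ),
        ArchetypeSpec("interrupted", v_L=0.8, v_U=4.5, q12=0.06, q21=0.18, **base),
    ]
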