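"""Two-regime switching model of the virtual blade velocity.

Under the Maxwell model the virtual velocity is treated as fully
observable, which reduces the switching linear dynamical system to a
Gaussian hidden Markov model: a discrete cutting regime s_t in {L, U}
evolves by a 2x2 row-stochastic transition matrix Q, and within regime k
the velocity is Normal(v_k, sigma2_k). The regimes are canonically
labelled so that v_L < v_U (L = lower, U = upper force level). Fitting is
done by Expectation-Maximization over multiple independent sequences
(one per cut); the long-run fraction of time in the upper regime is the
stationary probability pi_U = q12 / (q12 + q21).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor

from .profiles import VelocityProfile

__all__ = [
    "RegimeModel",
    "StatePath",
    "StationaryResult",
    "fit",
    "decode",
    "sample",
    "stationary_distribution",
]

VARIANCE_FLOOR = 1e-6


class _HistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the full log-likelihood trace."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


@dataclass(frozen=True)
class RegimeModel:
    """A fitted or specified K-regime Gaussian switching model.

    Attributes
    ----------
    v : ndarray, shape (K,)
        Per-regime mean velocities, sorted ascending (v_L < v_U for K=2).
    sigma2 : ndarray, shape (K,)
        Per-regime velocity variances (> 0).
    Q : ndarray, shape (K, K)
        Row-stochastic transition matrix; Q[i, j] is the probability of
        moving from regime i to regime j in one 1/rate step.
    pi0 : ndarray, shape (K,)
        Initial regime distribution.
    meta : dict
        Free-form provenance (Maxwell coefficients, dt, normalization
        constant, EM log-likelihood trace, ...).
    """

    v: np.ndarray
    sigma2: np.ndarray
    Q: np.ndarray
    pi0: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.atleast_1d(np.asarray(self.v, dtype=float))
        sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        pi0 = np.atleast_1d(np.asarray(self.pi0, dtype=float))
        K = v.size
        if sigma2.size != K or Q.shape != (K, K) or pi0.size != K:
            raise ValueError("inconsistent parameter shapes for K regimes")
        if np.any(sigma2 <= 0):
            raise ValueError("regime variances must be positive")
        if np.any(Q < -1e-12) or np.any(Q > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of the transition matrix must sum to 1")
        if not np.allclose(pi0.sum(), 1.0, atol=1e-8):
            raise ValueError("initial distribution must sum to 1")
        for name, val in (("v", v), ("sigma2", sigma2), ("Q", Q), ("pi0", pi0)):
            object.__setattr__(self, name, val)

    @property
    def K(self) -> int:
        return self.v.size

    @property
    def v_L(self) -> float:
        return float(self.v[0])

    @property
    def v_U(self) -> float:
        return float(self.v[-1])

    @property
    def stationary(self) -> "StationaryResult":
        return stationary_distribution(self.Q)

    @property
    def pi_U(self) -> float:
        """Long-run probability of the upper regime."""
        return float(self.stationary.pi[-1])

    def canonicalized(self) -> "RegimeModel":
        """Relabel regimes so means are ascending (v_L < v_U)."""
        order = np.argsort(self.v, kind="stable")
        return RegimeModel(
            v=self.v[order],
            sigma2=self.sigma2[order],
            Q=self.Q[np.ix_(order, order)],
            pi0=self.pi0[order],
            meta=dict(self.meta),
        )

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "v": self.v.tolist(),
            "sigma2": self.sigma2.tolist(),
            "Q": self.Q.tolist(),
            "pi0": self.pi0.tolist(),
            "meta": self.meta,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RegimeModel":
        return cls(
            v=np.asarray(d["v"], dtype=float),
            sigma2=np.asarray(d["sigma2"], dtype=float),
            Q=np.asarray(d["Q"], dtype=float),
            pi0=np.asarray(d["pi0"], dtype=float),
            meta=d.get("meta", {}),
        )

    @classmethod
    def from_json(cls, source) -> "RegimeModel":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)

    def _to_hmm(self) -> GaussianHMM:
        hmm = GaussianHMM(n_components=self.K, covariance_type="diag", init_params="")
        hmm.startprob_ = self.pi0.copy()
        hmm.transmat_ = self.Q.copy()
        hmm.means_ = self.v.reshape(-1, 1).copy()
        hmm.covars_ = self.sigma2.reshape(-1, 1).copy()
        hmm.n_features = 1
        return hmm


@dataclass(frozen=True)
class StatePath:
    """A decoded or sampled regime path with per-sample posteriors."""

    states: np.ndarray  # int array over {0..K-1}; 0 = L, last = U for K=2
    posteriors: np.ndarray  # shape (T, K), rows sum to 1

    def __post_init__(self):
        states = np.asarray(self.states, dtype=int)
        post = np.asarray(self.posteriors, dtype=float)
        if post.ndim != 2 or post.shape[0] != states.size:
            raise ValueError("posteriors must be (T, K) matching the state path")
        if not np.allclose(post.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("posteriors must sum to 1 per sample")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "posteriors", post)

    def __len__(self) -> int:
        return self.states.size

    @property
    def labels(self) -> np.ndarray:
        """States as 'L'/'U' labels (2-regime models only)."""
        if self.posteriors.shape[1] != 2:
            raise ValueError("L/U labels are defined only for 2-regime models")
        return np.where(self.states == 0, "L", "U")

    def n_switches(self) -> int:
        return int(np.count_nonzero(np.diff(self.states)))


@dataclass(frozen=True)
class StationaryResult:
    """Stationary distribution of a Markov chain, with an irreducibility flag.

    For reducible/absorbing chains ``pi`` is the long-run distribution
    reached by power iteration from the uniform start and ``irreducible``
    is False.
    """

    pi: np.ndarray
    irreducible: bool


def stationary_distribution(Q) -> StationaryResult:
    """Solve pi @ Q = pi, sum(pi) = 1 for a row-stochastic Q.

    For K = 2 this is pi_U = q12 / (q12 + q21). The linear solve is exact
    to machine precision (||pi Q - pi||_inf <= 1e-12); if the chain is
    reducible (the system is singular or the solution leaves the simplex)
    the absorbing distribution is found by power iteration and flagged.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    K = Q.shape[0]
    if Q.shape != (K, K):
        raise ValueError("transition matrix must be square")
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")
    A = Q.T - np.eye(K)
    A[-1, :] = 1.0
    b = np.zeros(K)
    b[-1] = 1.0
    pi = None
    try:
        cand = np.linalg.solve(A, b)
        if np.all(cand >= -1e-10):
            pi = np.clip(cand, 0.0, None)
            pi /= pi.sum()
    except np.linalg.LinAlgError:
        pass
    if pi is None:
        pi = np.full(K, 1.0 / K)
        for _ in range(100_000):
            nxt = pi @ Q
            if np.max(np.abs(nxt - pi)) < 1e-15:
                pi = nxt
                break
            pi = nxt
        pi = pi / pi.sum()
    irreducible = bool(np.all(pi > 1e-12) and np.all(Q @ np.ones(K) > 0))
    # a zero-mass state means the chain is effectively absorbing
    if np.any(pi <= 1e-12):
        irreducible = False
    return StationaryResult(pi=pi, irreducible=irreducible)


def _stack(velocities: Sequence[VelocityProfile]):
    seqs = [np.asarray(v.samples, dtype=float).reshape(-1, 1) for v in velocities]
    X = np.concatenate(seqs, axis=0)
    lengths = [s.shape[0] for s in seqs]
    return X, lengths


def fit(
    velocities: Iterable[VelocityProfile],
    K: int = 2,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    var_floor: float = VARIANCE_FLOOR,
    meta: dict | None = None,
) -> RegimeModel:
    """Fit a K-regime Gaussian HMM to velocity profiles by EM.

    Each profile is treated as an independent sequence (trials are
    independent executions; the chain is not continued across profile
    boundaries). Initialization is deterministic: regime means start at
    the means of the K quantile bins of the pooled velocities, variances
    at the pooled variance, the transition matrix sticky-diagonal, so the
    fit does not depend on ``seed`` unless hmmlearn needs to break a tie.
    States are relabelled ascending-mean after fitting, and the EM
    log-likelihood trace is checked to be non-decreasing.
    """
    velocities = list(velocities)
    if not velocities:
        raise ValueError("need at least one velocity profile to fit")
    if K < 1:
        raise ValueError("K must be at least 1")
    if any(len(v) < 2 for v in velocities):
        raise ValueError("each velocity profile must have at least 2 samples")
    X, lengths = _stack(velocities)
    pooled = X.ravel()
    n_distinct = np.unique(pooled).size
    degenerate = n_distinct <= K
    if n_distinct == 1:
        warnings.warn(
            "all velocity samples are identical; regime means will coincide",
            RuntimeWarning,
        )
    elif n_distinct < K:
        warnings.warn(
            f"only {n_distinct} distinct velocity values for K={K} regimes",
            RuntimeWarning,
        )

    hmm = GaussianHMM(
        n_components=K,
        covariance_type="diag",
        n_iter=max_iter,
        tol=tol,
        min_covar=var_floor,
        init_params="",
        params="stmc",
        random_state=seed,
    )
    hmm.monitor_ = _HistoryMonitor(hmm.tol, hmm.n_iter, hmm.verbose)
    # deterministic quantile-bin initialization of the emission means
    edges = np.quantile(pooled, np.linspace(0, 1, K + 1))
    srt = np.sort(pooled)
    means0 = np.empty(K)
    for k in range(K):
        lo = np.searchsorted(srt, edges[k], side="left")
        hi = np.searchsorted(srt, edges[k + 1], side="right")
        chunk = srt[lo:hi] if hi > lo else srt
        means0[k] = chunk.mean()
    var0 = max(pooled.var(), var_floor)
    hmm.startprob_ = np.full(K, 1.0 / K)
    if K > 1:
        # sticky-diagonal start: regimes persist ~10 samples a priori
        hmm.transmat_ = np.full((K, K), 0.1 / (K - 1))
        np.fill_diagonal(hmm.transmat_, 0.9)
    else:
        hmm.transmat_ = np.ones((1, 1))
    hmm.means_ = means0.reshape(-1, 1)
    hmm.covars_ = np.full((K, 1), var0)

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="hmmlearn")
        hmm.fit(X, lengths)

    history = list(hmm.monitor_.full_history)
    decreased = any(
        b - a < -1e-6 * max(1.0, abs(a)) for a, b in zip(history, history[1:])
    )
    if decreased:
        # exact EM is monotone; the variance floor / covariance prior act
        # as post-M-step regularizers and can lower the evaluated
        # likelihood when an emission variance collapses on degenerate,
        # noise-free input -- tolerated there, an error anywhere else
        if degenerate:
            warnings.warn(
                "EM log-likelihood decreased after variance regularization "
                "(degenerate input)",
                RuntimeWarning,
            )
        else:
            raise RuntimeError("EM log-likelihood decreased between iterations")

    model_meta = dict(meta or {})
    model_meta.setdefault("loglik_history", history)
    model_meta.setdefault("converged", bool(hmm.monitor_.converged))
    model = RegimeModel(
        v=hmm.means_.ravel(),
        sigma2=np.maximum(hmm.covars_.reshape(K, -1)[:, 0], var_floor),
        Q=hmm.transmat_,
        pi0=hmm.startprob_,
        meta=model_meta,
    )
    return model.canonicalized()


def decode(model: RegimeModel, v: VelocityProfile) -> StatePath:
    """Viterbi path and forward-backward posteriors for one profile."""
    if len(v) < 1:
        raise ValueError("cannot decode an empty profile")
    hmm = model._to_hmm()
    X = v.samples.reshape(-1, 1)
    _, states = hmm.decode(X, algorithm="viterbi")
    post = hmm.predict_proba(X)
    return StatePath(states=states, posteriors=post)


def sample(
    model: RegimeModel, T: int, seed: int | np.random.Generator = 0
) -> tuple[StatePath, VelocityProfile]:
    """Draw a regime path and velocities of length T from the model.

    States are drawn from pi0 and Q, velocities per-state from
    Normal(v_k, sigma2_k). Reproducible under a fixed integer seed.
    """
    if T < 1:
        raise ValueError("sample length T must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = model.K
    states = np.empty(T, dtype=int)
    cum_pi0 = np.cumsum(model.pi0)
    cum_Q = np.cumsum(model.Q, axis=1)
    u = rng.random(T)
    states[0] = np.searchsorted(cum_pi0, u[0])
    for t in range(1, T):
        states[t] = np.searchsorted(cum_Q[states[t - 1]], u[t])
    states = np.clip(states, 0, K - 1)
    vel = rng.normal(model.v[states], np.sqrt(model.sigma2[states]))
    post = np.eye(K)[states]
    rate = 1.0 / model.meta.get("dt", 1.0 / 30.0)
    return StatePath(states=states, posteriors=post), VelocityProfile(
        samples=vel, rate=rate
    )
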