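r"""Maxwell viscoelastic model of blade-tissue interaction.

A Maxwell body -- a spring (coefficient ``E``, N cm^-1) and a damper
(coefficient ``eta``, N s cm^-1) in series -- relates the cutting force
``f(t)`` to the virtual blade velocity ``xdot(t)``:

    eta * xdot(t) = f(t) + (eta / E) * fdot(t)

Equivalently, in the Laplace domain the force response to a displacement
input is the high-pass transfer function

    G(s) = F(s) / X(s) = eta * s / ((eta / E) * s + 1)

realized as the first-order state-space system

    g' = alpha * g + beta * x,    f = gamma * g + delta * x

with alpha = -E/eta, beta = 1, gamma = -E^2/eta, delta = E. A unit step in
displacement produces a force that decays exponentially with time constant
eta/E; a constant-velocity (ramp) displacement produces a step-like force
settling at eta * v. This module provides the force <-> displacement
transforms in both directions, finite-difference velocity estimation, and
forward simulation of force from a velocity input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .profiles import DisplacementProfile, ForceProfile, VelocityProfile

__all__ = [
    "MaxwellParams",
    "state_space_constants",
    "force_to_displacement",
    "velocity_from_displacement",
    "virtual_velocity",
    "simulate_force",
]


def state_space_constants(E: float, eta: float) -> tuple[float, float, float, float]:
    """State-space realization constants (alpha, beta, gamma, delta) of G(s).

    Derived by transfer-function matching of the first-order realization
    g' = alpha*g + beta*u, y = gamma*g + delta*u (displacement input u)
    against G(s) = eta*s / ((eta/E)*s + 1):

        delta + gamma*beta / (s - alpha) = E*s / (s + E/eta)

    which holds for alpha = -E/eta, beta = 1, gamma = -E^2/eta, delta = E.
    For the study's E = 1 N cm^-1, eta = 0.5 N s cm^-1 this gives
    (-2, 1, -2, 1).
    """
    if not (E > 0 and eta > 0):
        raise ValueError("Maxwell coefficients E and eta must be positive")
    return (-E / eta, 1.0, -(E * E) / eta, E)


@dataclass(frozen=True)
class MaxwellParams:
    """Maxwell body coefficients plus sampling interval.

    Attributes
    ----------
    E : float
        Spring coefficient, N cm^-1 (study default 1).
    eta : float
        Damping coefficient, N s cm^-1 (study default 0.5).
    dt : float
        Sample interval in seconds (study default 1/30 s).
    """

    E: float = 1.0
    eta: float = 0.5
    dt: float = 1.0 / 30.0

    def __post_init__(self):
        if not (self.E > 0 and self.eta > 0 and self.dt > 0):
            raise ValueError("E, eta and dt must all be positive")

    @property
    def tau(self) -> float:
        """Relaxation time constant eta/E, seconds."""
        return self.eta / self.E

    @property
    def constants(self) -> tuple[float, float, float, float]:
        """(alpha, beta, gamma, delta) of the state-space realization."""
        return state_space_constants(self.E, self.eta)

    @property
    def alpha(self) -> float:
        return self.constants[0]

    @property
    def beta(self) -> float:
        return self.constants[1]

    @property
    def gamma(self) -> float:
        return self.constants[2]

    @property
    def delta(self) -> float:
        return self.constants[3]


def force_to_displacement(
    f: ForceProfile, p: MaxwellParams | None = None
) -> DisplacementProfile:
    """Virtual displacement implied by a force profile.

    Solves the Maxwell ODE for x(t) given f(t):

        x(t) = f(t)/E + (1/eta) * integral_0^t f(tau) dtau

    with the running integral evaluated by cumulative trapezoid, so
    x(0) = f(0)/E.
    """
    p = p or MaxwellParams(dt=f.dt)
    integral = cumulative_trapezoid(f.samples, dx=f.dt, initial=0.0)
    x = f.samples / p.E + integral / p.eta
    return DisplacementProfile(samples=x, rate=f.rate, label=f.label)


def velocity_from_displacement(x: DisplacementProfile) -> VelocityProfile:
    """Forward finite-difference velocity, (x[t+1] - x[t]) / dt.

    Output is one sample shorter than the input (no padding); at the
    study's 30 Hz the step size is dt = 0.033 s.
    """
    if len(x) < 2:
        raise ValueError("need at least 2 displacement samples to differentiate")
    v = np.diff(x.samples) * x.rate
    return VelocityProfile(samples=v, rate=x.rate, label=x.label)


def virtual_velocity(f: ForceProfile, p: MaxwellParams | None = None) -> VelocityProfile:
    """Convenience composition: force -> displacement -> velocity."""
    return velocity_from_displacement(force_to_displacement(f, p))


def simulate_force(
    v: VelocityProfile,
    p: MaxwellParams | None = None,
    f0: float = 0.0,
    method: str = "exact",
) -> ForceProfile:
    """Simulate the force response to a virtual-velocity input.

    Integrates df/dt = -(E/eta) * f + E * xdot forward from ``f0``. Output
    sample k is the state after integrating through velocity sample k, so
    the output has the same length as the input.

    Parameters
    ----------
    v : VelocityProfile
        Velocity input (one value per step).
    f0 : float
        Initial force. Use the first measured sample when round-tripping
        a measured profile, 0 when generating from rest.
    method : {"exact", "euler"}
        "exact" (default) is the zero-order-hold discretization
        f[k+1] = phi * f[k] + eta * (1 - phi) * v[k], phi = exp(-dt/tau),
        which preserves the continuous-time decay rate exactly.
        "euler" is the forward-Euler step with local error O(dt^2).
    """
    p = p or MaxwellParams(dt=v.dt)
    if f0 < 0:
        raise ValueError("initial force f0 must be non-negative")
    if method == "exact":
        phi = math.exp(-p.E * p.dt / p.eta)
        b, a = [p.eta * (1.0 - phi)], [1.0, -phi]
    elif method == "euler":
        phi = 1.0 - p.E * p.dt / p.eta
        b, a = [p.E * p.dt], [1.0, -phi]
    else:
        raise ValueError(f"unknown integration method {method!r}")
    # one-pole IIR: f[k] = phi*f[k-1] + b0*v[k], seeded with f[-1] = f0
    f, _ = lfilter(b, a, v.samples, zi=[phi * f0])
    return ForceProfile(samples=f, rate=v.rate, label=v.label)
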