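"""Fit the switching model to simulated force profiles and recover its
parameters.

The fitting direction mirrors the measurement pipeline: force profiles
are inverted through the Maxwell body to virtual displacements, finite
differences give virtual velocities, and a 2-state Gaussian HMM is fit
to the velocities by EM. Ground truth is known by construction, so the
printout shows how well the full pipeline recovers it.
"""

from incise import ArchetypeSpec, MaxwellParams, fit, generate_trial, virtual_velocity

truth = ArchetypeSpec(
    name="truth", v_L=1.0, v_U=6.0, q12=0.05, q21=0.05,
    sigma_L=0.35, sigma_U=0.35, seed=42,
)
maxwell = MaxwellParams()  # E = 1 N/cm, eta = 0.5 N s/cm, 30 Hz

trial = generate_trial(truth)  # 12 profiles x 120 samples
velocities = [virtual_velocity(f, maxwell) for f in trial.profiles]
model = fit(velocities, K=2, seed=0)

print("parameter        truth    estimate")
print(f"v_L            {truth.v_L:7.3f}  {model.v_L:9.3f}")
print(f"v_U            {truth.v_U:7.3f}  {model.v_U:9.3f}")
print(f"q12            {truth.q12:7.3f}  {model.Q[0, 1]:9.3f}")
print(f"q21            {truth.q21:7.3f}  {model.Q[1, 0]:9.3f}")
print(f"sigma2_L       {truth.sigma_L**2:7.3f}  {model.sigma2[0]:9.3f}")
print(f"sigma2_U       {truth.sigma_U**2:7.3f}  {model.sigma2[1]:9.3f}")
print(f"\nstationary P(upper regime) pi_U = {model.pi_U:.3f} "
      "(long-run fraction of time at the upper force level)")
print(f"EM iterations: {len(model.meta['loglik_history'])}, "
      f"converged: {model.meta['converged']}")
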