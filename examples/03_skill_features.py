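"""Extract PCA skill features (Abruptness, Energy, Confidence) from a
synthetic cohort.

Each archetype subject is simulated, fitted back, and compressed to the
six-parameter vector (v_L, v_U, sigma2_L, sigma2_U, q12, q21). A
standardized PCA of these vectors yields three components whose
diagonal combinations name the behaviours: abruptness (discontinuity of
execution), energy (high forces held for long), confidence (steady,
narrow-envelope force application).
"""

import numpy as np
import pandas as pd

from incise import (
    MaxwellParams,
    PARAMETER_NAMES,
    default_archetypes,
    fit,
    fit_feature_space,
    generate_trial,
    parameter_vector,
    skill_axes,
    virtual_velocity,
)

maxwell = MaxwellParams()
vectors, labels = [], []
for arch_idx, spec in enumerate(default_archetypes(seed=3)):
    for trial_idx in range(1, 4):  # three trials per archetype
        ts = generate_trial(spec, trial=trial_idx, seed=1000 * trial_idx + 97 * arch_idx)
        vels = [virtual_velocity(p, maxwell) for p in ts.profiles]
        vectors.append(parameter_vector(fit(vels, K=2, seed=0)))
        labels.append(f"{spec.name}:{trial_idx}")

space = fit_feature_space(np.array(vectors), labels=labels)
axes = skill_axes(space)

print("explained variance ratio:",
      np.round(space.explained_variance_ratio, 3))
print("\nPC loadings (rows = PC1..PC3):")
print(pd.DataFrame(space.loadings,
                   columns=[PARAMETER_NAMES[i] for i in space.kept],
                   index=["PC1", "PC2", "PC3"]).round(2).to_string())
print("\nmean skill-axis scores per archetype "
      "(higher abruptness = more interrupted execution):")
axes["archetype"] = [l.rsplit(":", 1)[0] for l in axes.index]
print(axes.groupby("archetype").mean().round(2).to_string())
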