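"""Climate pruning, climate PCA and PCNM spatial grains.

Generates synthetic sampling locations with two climate variables that
vary at different spatial scales, prunes redundant covariates, and reads
off each variable's spatial grain from the significant PCNM components.
"""

import numpy as np
import pandas as pd

from poolgea import climate_pca, compute_pcnm, pcnm_regression, prune_covariates

rng = np.random.default_rng(21)
xy = rng.uniform(0, 200, size=(80, 2))          # 80 locations, planar km

basis = compute_pcnm(xy)
print(f"{basis.n_components} PCNM components from 80 locations "
      f"(truncation at {basis.truncation_threshold:.1f} km)")

# coarse-grained "temperature": a smooth gradient; fine-grained
# "precipitation": mid-frequency spatial waves; plus a redundant copy
climate = pd.DataFrame(
    {
        "temperature": xy[:, 0] * 0.05 + rng.normal(0, 0.3, 80),
        "temperature_copy": xy[:, 0] * 0.049 + rng.normal(0, 0.3, 80),
        "precipitation": basis.vectors[:, 12] * 5 + rng.normal(0, 0.3, 80),
    }
)
kept = prune_covariates(climate, rho_threshold=0.8)
print(f"covariates kept after Spearman pruning at 0.8: {kept}")

space = climate_pca(climate[kept])
print("climate PCA explained fractions:",
      np.round(100 * space.explained_fraction, 1), "%")

for name in kept:
    rep = pcnm_regression(climate[name].to_numpy(), basis)
    sig = rep.loc[rep["significant"], "component"].tolist()
    grain = "coarse" if sig and min(sig) <= 3 else "fine"
    print(f"{name}: significant components {sig} -> {grain}-grained variation")
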