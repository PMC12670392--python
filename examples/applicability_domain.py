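"""Leverage applicability domain: which predictions can be trusted?

Fits a model on training compounds, then assesses query compounds via the
Williams plot quantities: leverage (distance from the training centroid in
descriptor space) against the warning leverage h* = 3p/n, and standardized
residuals against the +/-2 outlier band.  Queries beyond h* are
extrapolations whose predicted retention indices should not be trusted.
"""

import numpy as np

import qsrrkit as qk
from qsrrkit.synthetic import PlantedSignalSpec, gen_descriptor_dataset

spec = PlantedSignalSpec(n=120, coefficients=(1000.0, 150.0, 80.0),
                         k_decoy=0, noise_sd=40.0, seed=3)
matrix, ri = gen_descriptor_dataset(spec)
X = matrix.values.to_numpy()
model = qk.fit_ols(X, ri, matrix.descriptor_names)

h_star = qk.warning_leverage(model.p_params, model.n_train)
print(f"warning leverage h* = 3*{model.p_params}/{model.n_train} "
      f"= {h_star:.3f}")

# queries: a few interpolations near the centroid, a few extrapolations
centroid = X.mean(axis=0)
queries = np.vstack([
    centroid + [0.2, -0.1],
    centroid + [0.5, 0.5],
    centroid + [4.0, 0.0],   # far outside the training cloud
    centroid + [0.0, 6.0],
])
result = qk.williams(model, X, queries,
                     compound_ids=["near-1", "near-2", "far-1", "far-2"])

print(f"{'query':<8}{'leverage':>10}{'predicted RI':>14}{'in domain':>11}")
for i, cid in enumerate(result.compound_ids):
    print(f"{cid:<8}{result.leverage[i]:>10.3f}"
          f"{result.predicted[i]:>14.0f}"
          f"{str(bool(result.in_domain[i])):>11}")
print(f"\n{result.n_in} reliable (h < h*), {result.n_out} extrapolations.")
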