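"""Build and train a small Sugeno ANFIS from scratch on a toy surface.

Subtractive clustering finds the rule centers, least squares fits the
linear consequents; the fitted surface is compared with the target.
"""

import numpy as np

from spastiq.anfis import init_structure, predict, train_consequents

rng = np.random.default_rng(0)
X = rng.uniform(-1, 1, size=(400, 2))
y = np.sin(2 * X[:, 0]) + 0.5 * X[:, 1] ** 2  # smooth nonlinear target

model = init_structure(X)
train_consequents(model, X, y)

pred = predict(model, X)
resid = float(np.sqrt(np.mean((pred - y) ** 2)))
print(f"rules discovered by subtractive clustering: {len(model.rules)}")
print(f"training RMSE of the rule mixture        : {resid:.4f}")
print(f"target range                             : [{y.min():.2f}, {y.max():.2f}]")

x0 = np.array([0.5, -0.5])
print(f"\nprediction at {x0}: {predict(model, x0):+.3f} "
      f"(target {np.sin(2 * x0[0]) + 0.5 * x0[1] ** 2:+.3f})")
print("\nEach rule blends a local linear map with Gaussian memberships; a handful")
print("of rules already track the curved surface far better than one global line.")
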