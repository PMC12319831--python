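"""The temporal mean of the time-resolved mixing equals the static mixing.

For noise-free model data X = S M B the per-frame estimate
f(t) = N * A X(t) B(t)' Z averages exactly to M over frames — the
closed-form identity that makes f interpretable as fluctuation around the
classical mixing matrix.  Also shown: for z-scored series the elementwise
product underlying f is the instantaneous correlation (its temporal mean
is Pearson r).
"""

import numpy as np

import trifle

rng = np.random.default_rng(0)
d, k, n = 5, 3, 400
S = rng.normal(size=(60, d))
M = rng.normal(size=(d, k))
B = rng.laplace(size=(k, n))
B = (B - B.mean(1, keepdims=True)) / B.std(1, keepdims=True)

trm = trifle.time_resolved_mixing(np.linalg.pinv(S), S @ M @ B, B)
err = np.abs(trm.f.mean(axis=2) - M).max()
print(f"max |mean_t f(t) - M| = {err:.2e}  (machine precision: the "
      "temporal average of the instantaneous mixing is the static mixing)")

x = rng.normal(size=1000)
y = 0.6 * x + rng.normal(size=1000)
zx = (x - x.mean()) / x.std()
zy = (y - y.mean()) / y.std()
print(f"mean(z_x * z_y) = {np.mean(zx * zy):.6f}")
print(f"Pearson r       = {np.corrcoef(x, y)[0, 1]:.6f}")
print("the per-frame product of z-scored series is the instantaneous "
      "correlation; its mean over time is the ordinary correlation.")
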