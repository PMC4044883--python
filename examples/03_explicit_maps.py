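"""Explicit feature maps: degree-2 polynomial expansion and randomized
Fourier features approximating the Gaussian RBF kernel.

Instead of the kernel trick (infeasible for ~10,000-sample kernel
matrices and for criteria like HDA/CDA with no kernelized form), vectors
are mapped explicitly and the linear machinery runs on the mapped data."""

import numpy as np

from hairpinldr import poly_dim, poly_map, rbf_fit, rbf_transform

x = np.array([2.0, 3.0])
print(f"poly_map({x}) = {poly_map(x)}")
print(f"  -> [1, x1, x2, x1^2, x2^2, x1*x2]; dimension C(n+2,2) = {poly_dim(2, 2)}")

# randomized cosine features: z(x).z(y) ~= exp(-gamma ||x-y||^2)
gamma = 1.0
rng = np.random.default_rng(0)
a = rng.standard_normal(3)
b = a + np.array([1.0, 0.0, 0.0])  # ||a-b||^2 = 1
exact = np.exp(-gamma * 1.0)
for m in (50, 500, 5000):
    fmap = rbf_fit(n=3, gamma=gamma, m=m, seed=1)
    approx = rbf_transform(fmap, a) @ rbf_transform(fmap, b)
    print(f"m = {m:5d}: z(a).z(b) = {approx:.4f}   "
          f"(exact kernel exp(-1) = {exact:.4f})")
# the Monte-Carlo kernel estimate tightens as O(1/sqrt(m)); the default
# dimension rule for an n-feature subset is m = n + 15
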