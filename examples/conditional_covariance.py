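"""Why condition on markers: hotspots induce spurious gene-gene correlation.

Two genes regulated by the same marker are marginally correlated even
when they are conditionally independent.  The conditional covariance
(linear kernel, suitable for 0/1 backcross genotypes) removes that
marker-driven component; the kernel formula with a linear Gram matrix
gives the same answer.
"""

import numpy as np

from jcggm import kernel_cond_cov, linear_cond_cov, make_kernel

rng = np.random.default_rng(3)
n = 400
x = rng.integers(0, 2, n).astype(float)  # one backcross marker
# two genes driven by the same marker, independent residuals
Y = np.column_stack([1.5 * x + rng.standard_normal(n) * 0.5,
                     -1.2 * x + rng.standard_normal(n) * 0.5])

marginal = linear_cond_cov(Y, None)
conditional = linear_cond_cov(Y, x[:, None])
via_kernel = kernel_cond_cov(Y, make_kernel(x[:, None], "linear"))

print("marginal covariance of the two genes:")
print(np.round(marginal, 3))
print("conditional covariance given the marker:")
print(np.round(conditional, 3))
print("max |linear formula - kernel formula| =",
      f"{np.abs(conditional - via_kernel).max():.2e}")
print("The marginal off-diagonal is strongly negative (shared marker), "
      "the conditional one is near zero: the genes are not directly "
      "interacting.")
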