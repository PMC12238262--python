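"""Fréchet distance between feature distributions.

The distance d^2 = ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^(1/2))
compares two Gaussian summaries of a feature sample.  Two samples of the
same distribution score near zero (the same-class baseline); separated
distributions score by how far their means and covariances differ.
"""

import numpy as np

from lptraj.evaluate import feature_distribution, frechet_distance

rng = np.random.default_rng(0)

# same distribution: baseline near zero
A = feature_distribution(rng.standard_normal((3000, 128)))
B = feature_distribution(rng.standard_normal((3000, 128)))
print("same-distribution baseline (128-d): d = %.3f" % frechet_distance(A, B))

# shifted mean: d^2 adds the squared mean separation
C = feature_distribution(rng.standard_normal((3000, 128)) + 0.5)
print("mean shifted by 0.5 per axis:       d = %.3f (expect ~ sqrt(128*0.25)"
      " = %.2f)" % (frechet_distance(A, C), np.sqrt(128 * 0.25)))

# inflated covariance: d^2 adds sum of (sqrt(var_a) - sqrt(var_b))^2
D = feature_distribution(2.0 * rng.standard_normal((3000, 128)))
print("SD doubled per axis:                d = %.3f (expect ~ sqrt(128*1)"
      " = %.2f)" % (frechet_distance(A, D), np.sqrt(128.0)))
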