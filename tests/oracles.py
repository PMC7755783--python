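"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the reference-
change-value check is a brute-force Monte-Carlo quantile of the null
difference distribution, not a rearrangement of the closed form.
"""

import numpy as np
from scipy.stats import norm


def two_sided_alpha(k: float) -> float:
    """Two-sided tail mass of a standard normal beyond ±k."""
    return 2.0 * norm.sf(k)


def mc_null_quantile(
    cvi_percent: float,
    cva_percent: float,
    k: float,
    n: int = 400_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo (1 - alpha) quantile of the null percent difference.

    Simulates pairs of results from one stable patient: each result is the
    homeostatic set point perturbed by independent within-subject and
    analytical Gaussian noise.  The percent difference between the two
    results (relative to the set point) is the quantity the reference
    change value bounds; its two-sided (1 - alpha) quantile at
    alpha = 2*(1 - Phi(k)) is returned in percent.
    """
    rng = np.random.default_rng(seed)
    sigma = np.hypot(cvi_percent, cva_percent) / 100.0
    x1 = 1.0 + rng.normal(0.0, sigma, n)
    x2 = 1.0 + rng.normal(0.0, sigma, n)
    d = 100.0 * (x2 - x1)
    return float(np.quantile(np.abs(d), 1.0 - two_sided_alpha(k)))
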