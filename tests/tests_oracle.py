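"""Independent textbook implementation of Efron's BCa interval, used as the
reference oracle in the acceptance checks.  Kept deliberately separate from
the package's implementation."""

import numpy as np
from scipy.stats import norm


def efron_bca(boot, observed, jack, level=0.95):
    boot = np.asarray(boot, dtype=float)
    jack = np.asarray(jack, dtype=float)
    p_less = (np.sum(boot < observed) + 0.5 * np.sum(boot == observed)) / len(boot)
    z0 = norm.ppf(p_less)
    diffs = jack.mean() - jack
    accel = np.sum(diffs**3) / (6.0 * np.sum(diffs**2) ** 1.5)
    z_low = norm.ppf((1.0 - level) / 2.0)
    z_high = -z_low
    alpha1 = norm.cdf(z0 + (z0 + z_low) / (1.0 - accel * (z0 + z_low)))
    alpha2 = norm.cdf(z0 + (z0 + z_high) / (1.0 - accel * (z0 + z_high)))
    return float(np.quantile(boot, alpha1)), float(np.quantile(boot, alpha2))
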