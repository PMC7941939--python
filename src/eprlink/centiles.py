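"""Synthetic birthweight-centile model (stand-in for a customised-centile engine).

Trials of growth surveillance classify a baby as small for gestational age
(SGA) when birthweight falls below a centile threshold for gestational age,
usually computed by an external customised-centile engine. That engine is
pluggable throughout this package; the default here is a synthetic stand-in
derived from the generator's own birthweight model, so that ground truth and
classification agree by construction.

Model: birthweight ~ Normal(mu, sigma) with
    mu = 3400 + 14.5 * (ga_days - 280) + 110 * [male]   (grams)
    sigma = 390 g
The p-th centile cut is mu + z_p * sigma.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

BW_INTERCEPT = 3400.0
BW_GA_SLOPE = 14.5
BW_MALE_SHIFT = 110.0
BW_TWIN_SHIFT = -150.0
BW_SIGMA = 390.0
SGA_CENTILE = 0.10


def birthweight_mean(ga_days, male, twin=False):
    ga_days = np.asarray(ga_days, dtype=float)
    male = np.asarray(male, dtype=float)
    mu = BW_INTERCEPT + BW_GA_SLOPE * (ga_days - 280.0) + BW_MALE_SHIFT * male
    if np.any(twin):
        mu = mu + BW_TWIN_SHIFT * np.asarray(twin, dtype=float)
    return mu


def sga_cut(ga_days, male, centile: float = SGA_CENTILE):
    """Birthweight (g) below which a baby is classified SGA.

    The population cut deliberately ignores twin status, as centile charts do.
    """
    return birthweight_mean(ga_days, male) + norm.ppf(centile) * BW_SIGMA


def is_sga(birthweight_g, ga_days, male, centile: float = SGA_CENTILE):
    return np.asarray(birthweight_g, dtype=float) < sga_cut(ga_days, male, centile)
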