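"""Shared parametric curve models.

The thermal denaturation model is a three-parameter logistic in temperature
with a non-denaturable floor, the standard form used for cellular
thermal-shift / thermal-proteome-profiling melting curves:

    f(T) = p + (1 - p) / (1 + exp(k * (T - Tm)))

where ``Tm`` is the midpoint (the melting temperature), ``k > 0`` the
steepness per degree C, and ``p`` in [0, 1) the soluble plateau remaining at
high temperature.  ``f`` decreases monotonically from ~1 to ~p.

The isothermal dose-response model is the four-parameter logistic (4PL)
in concentration:

    r(c) = bottom + (top - bottom) * c**h / (c**h + ec50**h)
"""

from __future__ import annotations

import numpy as np


def logistic_melt(temperature, tm: float, slope_k: float, plateau_p: float):
    """Soluble fraction at ``temperature`` for a logistic melting curve.

    Vectorized over ``temperature``; returns values in [plateau_p, 1].
    """
    t = np.asarray(temperature, dtype=float)
    # exp argument clipped to avoid overflow far from the midpoint
    z = np.clip(slope_k * (t - tm), -500.0, 500.0)
    out = plateau_p + (1.0 - plateau_p) / (1.0 + np.exp(z))
    if np.isscalar(temperature):
        return float(out)
    return out


def four_pl(dose, ec50: float, hill: float, top: float, bottom: float):
    """Four-parameter logistic dose-response, Hill form.

    ``dose`` must be positive; vectorized.  r(ec50) = (top + bottom) / 2.
    """
    c = np.asarray(dose, dtype=float)
    if np.any(c <= 0):
        raise ValueError("doses must be strictly positive")
    # work in log space for numerical stability at extreme hill slopes
    z = np.clip(hill * (np.log(c) - np.log(ec50)), -500.0, 500.0)
    frac = 1.0 / (1.0 + np.exp(-z))
    out = bottom + (top - bottom) * frac
    if np.isscalar(dose):
        return float(out)
    return out
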