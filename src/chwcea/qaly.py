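"""HbA1c-to-QALY effectiveness model.

A cross-sectional utility decrement ``d`` (utility points lost per
HbA1c percentage point) converts an HbA1c reduction ``r`` achieved
over the follow-up year into QALYs. With only enrollment and 1-year
measurements, HbA1c is assumed to change linearly over the year, so
the incremental utility at time ``t`` (years) is ``d * r * t`` and the
year-1 QALY gain is the triangle area ``d * r / 2``.

For exploratory horizons beyond one year the year-1 utility gain is
held constant (no further HbA1c change is assumed), adding
``d * r * (horizon - 1)``; the base case uses horizon 1 and no
discounting.
"""

from __future__ import annotations

import numpy as np

from .config import EffectEstimate, UtilityModel
from .exceptions import ConfigurationError


def _utility_gain(t: np.ndarray, reduction: float, model: UtilityModel) -> np.ndarray:
    """Incremental utility trajectory u(t) = d * r * min(t, 1)."""
    return model.decrement_per_hba1c_point * reduction * np.minimum(t, 1.0)


def qalys_gained(effect: EffectEstimate | float, model: UtilityModel) -> float:
    """Closed-form QALY gain for an HbA1c reduction under a utility model.

    For horizon ``h`` (years): ``d * r * (1/2 + max(h - 1, 0))``,
    which is ``d * r / 2`` in the base case ``h = 1``.
    """
    r = effect.hba1c_reduction if isinstance(effect, EffectEstimate) else float(effect)
    d = model.decrement_per_hba1c_point
    h = model.horizon_years
    if h <= 1.0:
        # linear ramp integrated over [0, h]: d*r*h^2/2
        return d * r * h * h / 2.0
    return d * r * (0.5 + (h - 1.0))


def qalys_gained_numeric(
    effect: EffectEstimate | float, model: UtilityModel, grid_points: int = 365
) -> float:
    """Trapezoid-rule integration of the utility-gain trajectory.

    Independent numerical check of :func:`qalys_gained`; exact for any
    grid that includes the kink at t = 1 (the trajectory is piecewise
    linear), and within O(1/n) otherwise.
    """
    if grid_points < 2:
        raise ConfigurationError("grid_points must be at least 2")
    r = effect.hba1c_reduction if isinstance(effect, EffectEstimate) else float(effect)
    t = np.linspace(0.0, model.horizon_years, grid_points)
    if model.horizon_years > 1.0:  # keep the kink on the grid
        t = np.unique(np.concatenate([t, [1.0]]))
    u = _utility_gain(t, r, model)
    return float(np.trapezoid(u, t))
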