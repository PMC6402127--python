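"""ICER computation, threshold decisions, one-way sensitivity analysis.

The incremental cost-effectiveness ratio (ICER) is incremental cost
over incremental effect. The ratio is only meaningful in the interior
case (both differences positive, or both negative); a cheaper and more
effective strategy *dominates* (always adopted), a costlier and less
effective one is *dominated* (never adopted), and a zero effect leaves
the ratio undefined. Dominance is reported as an explicit flag, never
as a signed ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from math import isfinite, nan
from typing import Callable, Mapping, Sequence

import pandas as pd

from .config import ThresholdSet
from .exceptions import ConfigurationError


class Dominance(str, Enum):
    INTERIOR = "interior"  # finite, meaningful ratio
    DOMINANT = "dominant"  # cheaper (or free) and more effective
    DOMINATED = "dominated"  # costlier and less (or no more) effective
    UNDEFINED = "undefined"  # zero effect, or both differences <= 0


@dataclass(frozen=True)
class ICER:
    """A classified incremental cost-effectiveness ratio."""

    value: float  # NaN unless interior
    dominance: Dominance
    incremental_cost: float
    incremental_effect: float

    def __float__(self) -> float:
        return self.value


def icer(incremental_cost: float, incremental_effect: float) -> ICER:
    """Classify and (when meaningful) compute cost / effect.

    Homogeneous of degree 1 in cost and −1 in effect on the interior.
    """
    c, e = float(incremental_cost), float(incremental_effect)
    if e > 0 and c > 0:
        dom, value = Dominance.INTERIOR, c / e
    elif e > 0:  # c <= 0: at worst free, strictly better
        dom, value = Dominance.DOMINANT, nan
    elif e < 0 and c > 0:
        dom, value = Dominance.DOMINATED, nan
    else:  # e == 0, or e < 0 with c <= 0 (cheaper but worse: no ratio rule)
        dom, value = Dominance.UNDEFINED, nan
    return ICER(value=value, dominance=dom, incremental_cost=c, incremental_effect=e)


def threshold_decisions(
    result: ICER, thresholds: ThresholdSet | Mapping[str, float]
) -> dict[str, bool]:
    """Cost-effectiveness verdict at each willingness-to-pay threshold.

    Interior: cost-effective iff ICER <= lambda (boundary counts as
    cost-effective). Dominant strategies are cost-effective at every
    threshold, dominated and undefined ones at none. Decisions are
    monotone in lambda.
    """
    entries = thresholds.entries if isinstance(thresholds, ThresholdSet) else dict(thresholds)
    if not entries:
        raise ConfigurationError("threshold set must not be empty")
    if result.dominance is Dominance.DOMINANT:
        return {label: True for label in entries}
    if result.dominance in (Dominance.DOMINATED, Dominance.UNDEFINED):
        return {label: False for label in entries}
    return {label: bool(result.value <= lam) for label, lam in entries.items()}


def gdp_multiple_threshold(gdp_per_capita: float, multiple: int) -> float:
    """WHO-style willingness-to-pay threshold: a multiple of GDP per capita."""
    if gdp_per_capita <= 0:
        raise ConfigurationError("GDP per capita must be positive")
    if multiple < 1:
        raise ConfigurationError("multiple must be at least 1")
    return float(gdp_per_capita) * multiple


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityResult:
    """One-way sensitivity rows and their ICER extremes.

    ``rows`` has columns parameter, value, icer_qaly, dominance,
    incremental_cost, qalys. Extremes are over rows with a finite ICER.
    """

    rows: pd.DataFrame
    base_icer_qaly: float = field(default=nan)

    @property
    def max_icer(self) -> float:
        finite = self.rows["icer_qaly"].dropna()
        return float(finite.max()) if len(finite) else nan

    @property
    def min_icer(self) -> float:
        finite = self.rows["icer_qaly"].dropna()
        return float(finite.min()) if len(finite) else nan

    def plot(self, ax=None):
        """Horizontal bar chart of ICERs by varied parameter value."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.5 * len(self.rows) + 1.5))
        labels = [
            f"{p} = {v:g}" for p, v in zip(self.rows["parameter"], self.rows["value"])
        ]
        ax.barh(labels, self.rows["icer_qaly"], color="#4878a8")
        if isfinite(self.base_icer_qaly):
            ax.axvline(self.base_icer_qaly, color="k", lw=1, ls="--", label="base case")
            ax.legend()
        ax.set_xlabel("ICER (USD per QALY gained)")
        ax.figure.tight_layout()
        return ax


def one_way_sensitivity(
    refit: Callable[[str, float], "object"],
    param_grid: Mapping[str, Sequence[float]],
    base_icer_qaly: float = nan,
) -> SensitivityResult:
    """Re-run the pipeline varying one parameter at a time.

    ``refit(parameter, value)`` must return an object exposing
    ``icer_qaly`` (float or NaN), ``dominance``, ``incremental_cost``
    and ``qalys`` — a full pipeline re-run with that single override.
    """
    if not param_grid or all(len(v) == 0 for v in param_grid.values()):
        raise ConfigurationError("sensitivity grid must not be empty")
    records = []
    for param, values in param_grid.items():
        for value in values:
            res = refit(param, value)
            records.append(
                {
                    "parameter": param,
                    "value": float(value),
                    "icer_qaly": float(res.icer_qaly),
                    "dominance": str(getattr(res.dominance, "value", res.dominance)),
                    "incremental_cost": float(res.incremental_cost),
                    "qalys": float(res.qalys),
                }
            )
    return SensitivityResult(rows=pd.DataFrame(records), base_icer_qaly=base_icer_qaly)
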