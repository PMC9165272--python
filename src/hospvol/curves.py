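"""Volume-outcome association: mortality curve, deviation band, hospital
performance coefficients, and expected-death accounting.

The empirical volume-outcome association says that hospitals performing more
of a procedure achieve lower 30-day risk-adjusted mortality for it.  Here the
association is used as a deterministic relation: a parametric, monotone
decreasing curve ``m(x)`` maps annual procedure volume ``x`` to an adjusted
mortality rate.  Around the curve, a deviation band ``dev(x)`` bounds how far
an individual hospital's outcome may credibly sit from the curve; a hospital's
past position inside that band is summarised by a performance coefficient
``v`` in [-1, +1] (negative = better than the curve predicts).

Expected deaths at volume ``x`` for a hospital with coefficient ``v`` are

    g(x) = x * m(x) + x * v * dev(x)

which is the per-hospital term of the planner's total-mortality objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "InputError",
    "MortalityCurve",
    "mortality_rate",
    "deviation_band",
    "performance_coefficient",
    "expected_deaths",
    "total_mortality",
]


class ConfigurationError(ValueError):
    """Invalid model configuration (curve parameters, flags, thresholds)."""


class InputError(ValueError):
    """Invalid or inconsistent input data."""


_FORMS = ("exponential", "power")


@dataclass(frozen=True)
class MortalityCurve:
    """Parametric decreasing volume -> adjusted-mortality curve.

    Parameters
    ----------
    form:
        ``"exponential"`` gives ``m(x) = m_floor + m_scale * exp(-decay * x)``
        (steep decline to a plateau); ``"power"`` gives
        ``m(x) = m_floor + m_scale * (x + 1) ** -decay`` (heavier tail).
    m_floor:
        Asymptotic mortality rate at very high volume, in [0, 1].
    m_scale:
        Excess mortality at volume 0 (exponential) or the power-law scale.
    decay:
        Positive decay rate (exponential) or exponent (power).
    dev_fraction:
        gamma in [0, 1]; the deviation band is ``dev(x) = gamma * m(x)``,
        so ``m(x) - dev(x) >= 0`` holds for any admissible gamma.
    """

    form: str = "exponential"
    m_floor: float = 0.02
    m_scale: float = 0.08
    decay: float = 0.02
    dev_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ConfigurationError(f"unknown curve form {self.form!r}; expected one of {_FORMS}")
        if not 0.0 <= self.m_floor <= 1.0:
            raise ConfigurationError(f"m_floor must be a rate in [0, 1], got {self.m_floor}")
        if self.m_scale < 0.0:
            raise ConfigurationError(f"m_scale must be >= 0, got {self.m_scale}")
        if self.decay <= 0.0:
            raise ConfigurationError(f"decay must be > 0, got {self.decay}")
        if not 0.0 <= self.dev_fraction <= 1.0:
            raise ConfigurationError(f"dev_fraction must be in [0, 1], got {self.dev_fraction}")

    def rate(self, volume):
        """Adjusted mortality rate m(volume); accepts scalars or arrays.

        Fractional volumes are admitted because operational (patient-model)
        solutions are sums of choice probabilities.
        """
        x = np.asarray(volume, dtype=float)
        if np.any(x < 0):
            raise InputError("volume must be non-negative")
        if self.form == "exponential":
            m = self.m_floor + self.m_scale * np.exp(-self.decay * x)
        else:
            m = self.m_floor + self.m_scale * (x + 1.0) ** (-self.decay)
        m = np.clip(m, 0.0, 1.0)
        return float(m) if np.isscalar(volume) or np.ndim(volume) == 0 else m

    def deviation(self, volume):
        """Deviation band dev(volume) = dev_fraction * m(volume)."""
        m = self.rate(volume)
        return self.dev_fraction * m


def mortality_rate(curve: MortalityCurve, volume) -> float:
    """Adjusted mortality rate at ``volume`` on ``curve``."""
    return curve.rate(volume)


def deviation_band(curve: MortalityCurve, volume) -> float:
    """Average deviation from the curve at ``volume`` (performance headroom)."""
    return curve.deviation(volume)


def performance_coefficient(
    curve: MortalityCurve,
    prev_volume: int,
    prev_observed_rate: float | None,
) -> float:
    """Signed, clamped on-curve residual of last year's observed outcome.

    ``v = clamp((observed - m(prev_volume)) / dev(prev_volume), -1, +1)``.
    A hospital with no recorded history gets ``v = 0`` (assumed to sit exactly
    on the curve).  A degenerate band (``dev = 0``) with a nonzero residual
    saturates to +/-1.
    """
    if prev_volume < 0:
        raise InputError("prev_volume must be non-negative")
    if prev_observed_rate is None or (
        isinstance(prev_observed_rate, float) and np.isnan(prev_observed_rate)
    ):
        return 0.0
    if not 0.0 <= prev_observed_rate <= 1.0:
        raise InputError(f"observed mortality rate must be in [0, 1], got {prev_observed_rate}")
    resid = prev_observed_rate - curve.rate(prev_volume)
    dev = curve.deviation(prev_volume)
    if dev == 0.0:
        if resid == 0.0:
            return 0.0
        return float(np.sign(resid))
    return float(np.clip(resid / dev, -1.0, 1.0))


def expected_deaths(curve: MortalityCurve, volume, v: float = 0.0):
    """Expected deaths ``x*m(x) + x*v*dev(x)`` at volume ``x``; 0 at x = 0."""
    if not -1.0 <= v <= 1.0:
        raise InputError(f"performance coefficient must lie in [-1, 1], got {v}")
    x = np.asarray(volume, dtype=float)
    out = x * curve.rate(volume) + x * v * curve.deviation(volume)
    return float(out) if np.ndim(volume) == 0 else out


def total_mortality(
    volumes: Mapping[str, float] | pd.Series,
    hospitals: pd.DataFrame,
    curve: MortalityCurve,
) -> float:
    """Total expected deaths of a volume allocation.

    ``hospitals`` must be indexed by hospital id and carry a ``v`` column
    (performance coefficients).  Fractional volumes are accepted: operational
    solutions are probability sums.
    """
    if isinstance(volumes, pd.Series):
        volumes = volumes.to_dict()
    if not volumes:
        return 0.0
    ids = list(volumes.keys())
    unknown = [h for h in ids if h not in hospitals.index]
    if unknown:
        raise InputError(f"unknown hospital id(s) in volume map: {unknown}")
    x = np.array([volumes[h] for h in ids], dtype=float)
    if np.any(x < 0):
        raise InputError("volumes must be non-negative")
    v = hospitals.loc[ids, "v"].to_numpy(dtype=float)
    return float(np.sum(x * curve.rate(x) + x * v * curve.deviation(x)))
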