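"""Mediator velocities (rate of change of the group median) and ranked profiles.

For a mediator A in one tissue, the velocity between two arms is

    v_A = (median_to - median_from) / duration

with the 7-day contrast (baseline -> day-7 surgery arm) expressed per day and
the LPS contrast (surgery arm at 7 d / 0 h -> 3 h post LPS) per hour. Each
LPS arm is referenced to its matching surgery-only arm: sham for sham+LPS,
vagotomy for vagotomy+LPS.

Ranking the velocities of one mediator across tissues, ascending, yields the
cross-tissue profile whose shape is typically sigmoidal; the putative
biological threshold is read out two ways, neither privileged: the rank at
which velocity first becomes non-negative (zero crossing) and the midpoint
of a 4-parameter logistic fitted over rank index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .core_data import median_by_group, units_for_tissue


@dataclass
class Velocity:
    """Rate of change of one mediator's median in one tissue."""

    mediator: str
    tissue: str
    from_condition: str
    to_condition: str
    median_from: float
    median_to: float
    duration: float  # in `per` units
    per: str = "day"  # "day" for the 7-day contrast, "hour" for LPS

    @property
    def value(self) -> float:
        return (self.median_to - self.median_from) / self.duration

    @property
    def units(self) -> str:
        return f"{units_for_tissue(self.tissue)}/{self.per}"


def compute_velocity(
    df: pd.DataFrame,
    tissue: str,
    mediator: str,
    from_condition: str,
    to_condition: str,
    duration: float,
    per: str = "day",
) -> Velocity:
    """Velocity of the group median between two arms (outlier-filtered input).

    Raises :class:`~cytodyn.core_data.MissingGroupError` if either group is
    empty; ValueError if duration is not positive.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    m_from = median_by_group(df, tissue, mediator, from_condition)
    m_to = median_by_group(df, tissue, mediator, to_condition)
    return Velocity(
        mediator=mediator,
        tissue=tissue,
        from_condition=from_condition,
        to_condition=to_condition,
        median_from=m_from,
        median_to=m_to,
        duration=duration,
        per=per,
    )


@dataclass
class RankedProfile:
    """One mediator's velocities across tissues, sorted ascending.

    ``zero_crossing_index`` is the position of the first non-negative
    velocity (0 if all are non-negative, None if all are negative).
    ``logistic_fit`` is filled by :func:`fit_logistic`.
    """

    mediator: str
    condition: str
    tissues: list[str]
    velocities: list[float]
    zero_crossing_index: int | None
    logistic_fit: dict | None = None


def rank_tissue_velocities(velocities) -> RankedProfile:
    """Sort one mediator's per-tissue velocities ascending (ties alphabetical).

    ``velocities`` is an iterable of :class:`Velocity` for a single mediator
    and condition pair; duplicate tissues are an error.
    """
    velocities = list(velocities)
    if not velocities:
        raise ValueError("need at least one velocity")
    mediators = {v.mediator for v in velocities}
    pairs = {(v.from_condition, v.to_condition) for v in velocities}
    if len(mediators) > 1 or len(pairs) > 1:
        raise ValueError(
            f"profile mixes mediators {mediators} / condition pairs {pairs}"
        )
    tissues = [v.tissue for v in velocities]
    if len(set(tissues)) != len(tissues):
        dup = {t for t in tissues if tissues.count(t) > 1}
        raise ValueError(f"duplicate tissue(s) in profile: {sorted(dup)}")

    ordered = sorted(velocities, key=lambda v: (v.value, v.tissue))
    vals = [v.value for v in ordered]
    zero_idx = next((i for i, x in enumerate(vals) if x >= 0), None)
    return RankedProfile(
        mediator=mediators.pop(),
        condition="->".join(pairs.pop()),
        tissues=[v.tissue for v in ordered],
        velocities=vals,
        zero_crossing_index=zero_idx,
    )


def _logistic4(x, lower, upper, midpoint, slope):
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (x - midpoint)))


def fit_logistic(profile: RankedProfile) -> dict | None:
    """Least-squares 4-parameter logistic over rank index -> velocity.

    Returns {"lower", "upper", "midpoint", "slope"} (midpoint in rank units
    is the inferred threshold position) or None when there are fewer than 4
    tissues, the profile is flat, or the fit does not converge. The result is
    also stored on ``profile.logistic_fit``.
    """
    y = np.asarray(profile.velocities, dtype=float)
    if len(y) < 4:
        return None
    if np.ptp(y) == 0:
        return None
    x = np.arange(len(y), dtype=float)
    p0 = [y.min(), y.max(), float(len(y) - 1) / 2.0, 1.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_logistic4, x, y, p0=p0, maxfev=10000)
    except (RuntimeError, ValueError):
        return None
    fit = dict(zip(("lower", "upper", "midpoint", "slope"), map(float, popt)))
    profile.logistic_fit = fit
    return fit


def velocity_table(velocities) -> pd.DataFrame:
    """Tidy frame of velocities for CSV export."""
    return pd.DataFrame(
        [
            {
                "mediator": v.mediator,
                "tissue": v.tissue,
                "from_condition": v.from_condition,
                "to_condition": v.to_condition,
                "median_from": v.median_from,
                "median_to": v.median_to,
                "duration": v.duration,
                "value": v.value,
                "units": v.units,
            }
            for v in velocities
        ]
    )
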