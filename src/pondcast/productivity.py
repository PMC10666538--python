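"""Areal productivity from ash-free dry weight (AFDW) change.

Areal productivity (g/m2/d) of an open raceway pond over an interval of
``t`` days is

    P = (AFDW_end - AFDW_start) * V_ORP / (t * A_ORP)

with AFDW in g/L, pond volume ``V_ORP`` in litres and pond area ``A_ORP``
in m2.  The defaults correspond to the 1,025 L / 4.2 m2 experimental ponds
of the ATP3 unified field studies.
"""

from __future__ import annotations

from .types import PondGeometry

DEFAULT_GEOMETRY = PondGeometry()


def areal_productivity(
    afdw_start: float,
    afdw_end: float,
    duration_days: float,
    geometry: PondGeometry = DEFAULT_GEOMETRY,
) -> float:
    """Areal productivity in g/m2/d.

    Negative results (net biomass loss) are returned unclamped; callers decide
    whether to keep them.

    Parameters
    ----------
    afdw_start, afdw_end : float
        Ash-free dry weight (g/L) at the interval start and end.
    duration_days : float
        Interval length in days; must be positive.
    geometry : PondGeometry
        Pond volume (L) and area (m2).
    """
    if duration_days <= 0:
        raise ValueError("duration_days must be positive")
    return (afdw_end - afdw_start) * geometry.volume_l / (duration_days * geometry.area_m2)
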