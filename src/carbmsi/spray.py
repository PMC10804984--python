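"""Areal deposition arithmetic for pneumatic sprayer application.

The sprayer lays down solution at ``concentration × flow`` µg/min while the
head sweeps ``velocity × track_spacing`` mm²/min of surface; one cycle's
coverage is the ratio, and cycles add linearly.  With mg/mL × µL/min in the
numerator and mm/min × mm in the denominator the unit conversion collapses
to a factor of 100 for µg/cm².
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SprayParameters", "spray_coverage", "DHB_DEFAULTS", "NEDC_DEFAULTS"]


@dataclass(frozen=True)
class SprayParameters:
    concentration_mg_ml: float
    flow_ul_min: float
    n_cycles: int
    velocity_mm_min: float
    track_spacing_mm: float

    def __post_init__(self):
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be non-negative")
        for name in ("concentration_mg_ml", "flow_ul_min",
                     "velocity_mm_min", "track_spacing_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: matrix application parameter sets used in the source protocol
DHB_DEFAULTS = SprayParameters(40.0, 50.0, 12, 1200.0, 3.0)
NEDC_DEFAULTS = SprayParameters(7.0, 120.0, 8, 1200.0, 3.0)


def spray_coverage(p: SprayParameters) -> float:
    """Deposited areal coverage in µg/cm².

    coverage = 100 × concentration × flow × n_cycles / (velocity × spacing).
    """
    return (100.0 * p.concentration_mg_ml * p.flow_ul_min * p.n_cycles
            / (p.velocity_mm_min * p.track_spacing_mm))
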