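"""Physical constants, rasters and unit helpers.

All times are carried internally as integer nanoseconds so that cached
parameter values, streamed blocks and file round-trips compare bit-exact
(float accumulation across >1e4 repetition intervals would not).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gyromagnetic ratio of 1H in Hz/T (CODATA value, gamma-bar).
GAMMA_HZ_PER_T: float = 42.577478518e6

#: RF envelope sampling raster in nanoseconds.
RF_RASTER_NS: int = 1_000
#: Gradient waveform raster in nanoseconds.
GRAD_RASTER_NS: int = 10_000
#: Execution-block duration granularity in nanoseconds.
BLOCK_RASTER_NS: int = 10_000
#: ADC dwell raster in nanoseconds.
ADC_RASTER_NS: int = 100

MS = 1_000_000  # ns per millisecond
US = 1_000  # ns per microsecond
S = 1_000_000_000  # ns per second


def ms_to_ns(t_ms: float) -> int:
    return int(round(t_ms * MS))


def ns_to_ms(t_ns: int) -> float:
    return t_ns / MS


def ns_to_s(t_ns: int) -> float:
    return t_ns / S


def ceil_to_raster(t_ns: int, raster_ns: int) -> int:
    """Round a duration up to the next raster multiple."""
    return -(-int(t_ns) // raster_ns) * raster_ns


@dataclass(frozen=True)
class HardwareLimits:
    """Scanner hardware envelope the compiler designs against.

    Attributes
    ----------
    gmax : float
        Maximum gradient amplitude in mT/m.
    slew : float
        Maximum slew rate in mT/m/ms.
    b1_max : float
        Peak RF amplitude ceiling in microtesla.
    """

    gmax: float = 40.0
    slew: float = 150.0
    b1_max: float = 25.0
    rf_raster_ns: int = RF_RASTER_NS
    grad_raster_ns: int = GRAD_RASTER_NS
    block_raster_ns: int = BLOCK_RASTER_NS

    def __post_init__(self) -> None:
        if self.gmax <= 0 or self.slew <= 0 or self.b1_max <= 0:
            raise ValueError("hardware limits must be positive")


DEFAULT_LIMITS = HardwareLimits()
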