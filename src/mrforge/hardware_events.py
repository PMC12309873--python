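"""Generalized raw representation of hardware execution blocks.

One atomic sequence element translates into one :class:`ExecutionBlock`
holding at most one RF event, up to three gradient events (logical axes
READ/PHASE/SLICE), and at most one ADC event with its acquisition header.
Event times are block-relative integer nanoseconds; the stream assigns
absolute block start times.  Events are frozen dataclasses with tuple-typed
shapes so that equality (and therefore cache/stream/round-trip checks) is
bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from ._units import (
    BLOCK_RASTER_NS,
    GAMMA_HZ_PER_T,
    GRAD_RASTER_NS,
    DEFAULT_LIMITS,
    HardwareLimits,
    ceil_to_raster,
)
from .sequence_model import Element, ParameterGraph, Violation

__all__ = [
    "ADCEvent",
    "AcquisitionHeader",
    "ExecutionBlock",
    "GradientEvent",
    "RFEvent",
    "build_block",
    "dump_blocks",
    "logical_to_physical",
    "validate_block",
]

LOGICAL_AXES = ("READ", "PHASE", "SLICE")
PHYSICAL_AXES = ("X", "Y", "Z")


@dataclass(frozen=True)
class RFEvent:
    """A shaped RF pulse.

    ``envelope`` is the complex envelope sampled on the RF raster with
    ``max |envelope| <= 1``; ``peak_amplitude`` scales it to microtesla.
    ``center_fraction`` locates the isodelay point (0.5 for symmetric
    pulses).  ``use`` tags the pulse role for k-space bookkeeping.
    """

    start: int  # ns, block-relative
    envelope: tuple[complex, ...]
    peak_amplitude: float  # µT
    raster: int = 1_000  # ns
    frequency_offset: float = 0.0  # Hz
    phase_offset: float = 0.0  # rad
    center_fraction: float = 0.5
    bandwidth: float = 0.0  # Hz (design bandwidth; 0 if unspecified)
    use: str = "excite"  # excite | refocus | inversion | saturation

    @property
    def duration(self) -> int:
        return len(self.envelope) * self.raster

    @property
    def end(self) -> int:
        return self.start + self.duration

    @property
    def center(self) -> int:
        return self.start + int(round(self.center_fraction * self.duration))

    def flip_angle_deg(self) -> float:
        """On-resonance small-tip flip angle implied by the scaled envelope."""
        integral = sum(abs(e) for e in self.envelope) * (self.raster * 1e-9)
        return math.degrees(2 * math.pi * GAMMA_HZ_PER_T * self.peak_amplitude * 1e-6 * integral)


@dataclass(frozen=True)
class GradientEvent:
    """A gradient on one axis: a trapezoid or an arbitrary sampled waveform.

    Trapezoid: ``amplitude`` mT/m with ``rise``/``flat``/``fall`` ns.
    Arbitrary: ``waveform`` in mT/m sampled on the gradient raster with
    linear interpolation between samples (first sample at ``start``).
    """

    axis: str
    start: int  # ns
    amplitude: float = 0.0  # mT/m
    rise: int = 0
    flat: int = 0
    fall: int = 0
    waveform: tuple[float, ...] | None = None
    raster: int = 10_000  # ns

    @property
    def is_arbitrary(self) -> bool:
        return self.waveform is not None

    @property
    def duration(self) -> int:
        if self.is_arbitrary:
            return max(len(self.waveform) - 1, 0) * self.raster
        return self.rise + self.flat + self.fall

    @property
    def end(self) -> int:
        return self.start + self.duration

    def amplitude_at(self, t_ns: float) -> float:
        """Waveform value in mT/m at block-relative time ``t_ns``."""
        t = t_ns - self.start
        if t < 0 or t > self.duration:
            return 0.0
        if self.is_arbitrary:
            x = t / self.raster
            i = min(int(x), len(self.waveform) - 2) if len(self.waveform) > 1 else 0
            if len(self.waveform) == 1:
                return self.waveform[0]
            frac = x - i
            return self.waveform[i] * (1 - frac) + self.waveform[i + 1] * frac
        if t < self.rise:
            return self.amplitude * t / self.rise if self.rise else self.amplitude
        if t < self.rise + self.flat:
            return self.amplitude
        if self.fall:
            return self.amplitude * (self.duration - t) / self.fall
        return 0.0

    def integral_to(self, t_ns: float) -> float:
        """∫G dt from event start to ``t_ns`` in mT/m·ms."""
        t = min(max(t_ns - self.start, 0.0), float(self.duration))
        if self.is_arbitrary:
            if len(self.waveform) < 2:
                return 0.0
            n_full = int(t // self.raster)
            acc = 0.0
            for i in range(min(n_full, len(self.waveform) - 1)):
                acc += 0.5 * (self.waveform[i] + self.waveform[i + 1]) * self.raster
            if n_full < len(self.waveform) - 1:
                dt = t - n_full * self.raster
                g0 = self.waveform[n_full]
                g1 = self.amplitude_at(self.start + t)
                acc += 0.5 * (g0 + g1) * dt
            return acc * 1e-6  # ns → ms
        a = self.amplitude
        acc = 0.0
        seg = min(t, self.rise)
        if self.rise:
            acc += 0.5 * a * seg * seg / self.rise
        if t > self.rise:
            acc += a * (min(t, self.rise + self.flat) - self.rise)
        if t > self.rise + self.flat and self.fall:
            td = t - self.rise - self.flat
            acc += a * td - 0.5 * a * td * td / self.fall
        return acc * 1e-6

    @property
    def area(self) -> float:
        """Total area in mT/m·ms."""
        return self.integral_to(self.start + self.duration)

    def slew_mT_m_ms(self) -> float:
        """Peak slew rate of the event in mT/m/ms."""
        if self.is_arbitrary:
            if len(self.waveform) < 2:
                return 0.0
            diffs = np.abs(np.diff(np.asarray(self.waveform)))
            return float(diffs.max()) / (self.raster * 1e-6)
        s = 0.0
        if self.rise:
            s = max(s, abs(self.amplitude) / (self.rise * 1e-6))
        if self.fall:
            s = max(s, abs(self.amplitude) / (self.fall * 1e-6))
        return s


@dataclass(frozen=True)
class AcquisitionHeader:
    """Counters and flags attached to one readout, using the ISMRMRD
    counter vocabulary so third-party reconstruction can consume them."""

    line: int = 0
    partition: int = 0
    slice: int = 0
    average: int = 0
    set: int = 0
    repetition: int = 0
    contrast: int = 0
    segment: int = 0
    flags: tuple[str, ...] = ()
    trajectory_id: int = 0

    COUNTERS = ("line", "partition", "slice", "average", "set", "repetition", "contrast", "segment")

    def counters(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in self.COUNTERS}


@dataclass(frozen=True)
class ADCEvent:
    start: int  # ns
    samples: int
    dwell: int  # ns
    header: AcquisitionHeader = field(default_factory=AcquisitionHeader)
    frequency_offset: float = 0.0  # Hz (receiver demodulation)
    phase_offset: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.samples < 1:
            raise ValueError("ADC needs at least one sample")

    @property
    def duration(self) -> int:
        return self.samples * self.dwell

    @property
    def end(self) -> int:
        return self.start + self.duration

    @property
    def center(self) -> int:
        return self.start + self.duration // 2

    def sample_times(self) -> np.ndarray:
        """Block-relative sample times (ns), sample centered in its dwell."""
        return self.start + (np.arange(self.samples) + 0.5) * self.dwell


@dataclass(frozen=True)
class ExecutionBlock:
    """One atomic's hardware events on a common block-relative clock."""

    duration: int  # ns
    start: int = 0  # ns, absolute within stream (assigned by the streamer)
    rf: RFEvent | None = None
    gradients: tuple[GradientEvent, ...] = ()
    adc: ADCEvent | None = None
    sync: bool = False
    label: str = ""

    @property
    def end(self) -> int:
        return self.start + self.duration

    def events_end(self) -> int:
        ends = [0]
        if self.rf:
            ends.append(self.rf.end)
        ends.extend(g.end for g in self.gradients)
        if self.adc:
            ends.append(self.adc.end)
        return max(ends)

    def gradient_on(self, axis: str) -> GradientEvent | None:
        for g in self.gradients:
            if g.axis == axis:
                return g
        return None


# --------------------------------------------------------------------------


def build_block(atomic: Element, graph: ParameterGraph) -> ExecutionBlock:
    """Translate an atomic element into one execution block.

    The atomic's ``raw`` rule produces the events (an :class:`ExecutionBlock`
    with block-relative times).  The block duration is the maximum event end
    rounded up to the block raster unless the rule declared a longer one;
    acquisition-header counters are merged in from every enclosing loop that
    declares a ``counter`` rule naming a header field.
    """
    raw = graph.evaluate(atomic.node_id("raw"))
    if not isinstance(raw, ExecutionBlock):
        raise TypeError(f"{atomic.path}: raw rule must return an ExecutionBlock")
    ev_end = raw.events_end()
    duration = max(raw.duration, 0)
    if duration and ev_end > duration:
        raise ValueError(
            f"{atomic.path}: event ends at {ev_end} ns, beyond declared "
            f"block duration {duration} ns"
        )
    duration = max(duration, ceil_to_raster(ev_end, BLOCK_RASTER_NS))
    for ev in (raw.rf, raw.adc, *raw.gradients):
        if ev is not None and ev.start < 0:
            raise ValueError(f"{atomic.path}: negative event start {ev.start} ns")

    counters: dict[str, int] = {}
    anc = atomic.parent
    while anc is not None:
        if anc.kind == "loop" and "counter" in anc.nodes:
            name = graph.evaluate(anc.node_id("counter"))
            if name in AcquisitionHeader.COUNTERS and name not in counters:
                counters[name] = graph.evaluate(anc.index_node)
        anc = anc.parent

    adc = raw.adc
    if adc is not None and counters:
        adc = replace(adc, header=replace(adc.header, **counters))
    return replace(raw, duration=duration, adc=adc, label=raw.label or atomic.path)


def validate_block(block: ExecutionBlock, limits: HardwareLimits = DEFAULT_LIMITS) -> list[Violation]:
    """Check one block against its invariants and the hardware envelope."""
    out: list[Violation] = []
    if block.events_end() > block.duration:
        out.append(Violation("containment", "event extends beyond block duration"))
    for g in block.gradients:
        peak = max(abs(v) for v in g.waveform) if g.is_arbitrary else abs(g.amplitude)
        if peak > limits.gmax * (1 + 1e-9):
            out.append(
                Violation(
                    "gradient_amplitude",
                    f"gradient amplitude {peak:.3f} mT/m exceeds Gmax {limits.gmax} mT/m",
                    where=f"gradient[{g.axis}]",
                    value=peak,
                )
            )
        slew = g.slew_mT_m_ms()
        if slew > limits.slew * (1 + 1e-9):
            out.append(
                Violation(
                    "gradient_slew",
                    f"slew {slew:.1f} mT/m/ms exceeds limit {limits.slew} mT/m/ms",
                    where=f"gradient[{g.axis}]",
                    value=slew,
                )
            )
        if not g.is_arbitrary:
            for t in (g.start, g.rise, g.flat, g.fall):
                if t % GRAD_RASTER_NS:
                    out.append(
                        Violation(
                            "raster",
                            f"gradient timing {t} ns not on {GRAD_RASTER_NS} ns raster",
                            where=f"gradient[{g.axis}]",
                        )
                    )
                    break
    if block.rf is not None and abs(block.rf.peak_amplitude) > limits.b1_max * (1 + 1e-9):
        out.append(
            Violation(
                "rf_amplitude",
                f"peak B1 {block.rf.peak_amplitude:.2f} µT exceeds {limits.b1_max} µT",
                where="rf",
                value=block.rf.peak_amplitude,
            )
        )
    if block.rf is not None and block.adc is not None:
        if block.rf.start < block.adc.end and block.adc.start < block.rf.end:
            out.append(Violation("overlap", "RF and ADC events overlap", where="rf/adc"))
    return out


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------


def _is_signed_permutation(r: np.ndarray) -> bool:
    return all(
        sorted(np.abs(row)) == [0.0, 0.0, 1.0] and set(np.abs(row)) <= {0.0, 1.0}
        for row in np.round(r, 12)
    )


def _gradient_vector_at(block: ExecutionBlock, t_ns: float) -> np.ndarray:
    vec = np.zeros(3)
    for g in block.gradients:
        if g.axis in LOGICAL_AXES:
            vec[LOGICAL_AXES.index(g.axis)] = g.amplitude_at(t_ns)
    return vec


def logical_to_physical(
    block: ExecutionBlock,
    orientation: np.ndarray,
    offset_mm: Iterable[float] = (0.0, 0.0, 0.0),
) -> ExecutionBlock:
    """Rotate a block's logical-axis gradients into physical axes.

    ``orientation`` maps logical (READ, PHASE, SLICE) to physical (X, Y, Z)
    and must be a proper rotation.  The RF frequency offset picks up
    γ·(G_slice·offset) so a slice at ``offset_mm`` stays on resonance; the
    ADC receives the corresponding demodulation frequency from the gradient
    vector at its center (off-isocenter phase handled at the receiver, not
    baked into samples).  Signed-permutation rotations keep trapezoids
    intact; general rotations produce sampled physical waveforms.
    """
    r = np.asarray(orientation, dtype=float)
    if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-10):
        raise ValueError("orientation must be an orthonormal 3x3 matrix")
    if np.linalg.det(r) < 0:
        raise ValueError("orientation must be proper (det = +1)")
    offset = np.asarray(tuple(offset_mm), dtype=float) * 1e-3  # m

    identity = np.allclose(r, np.eye(3), atol=1e-12)

    if identity:
        new_grads = block.gradients
    elif _is_signed_permutation(r) and all(g.axis in LOGICAL_AXES for g in block.gradients):
        rr = np.round(r, 12)
        new_grads = []
        for g in block.gradients:
            col = LOGICAL_AXES.index(g.axis)
            row = int(np.argmax(np.abs(rr[:, col])))
            sign = float(np.sign(rr[row, col]))
            if g.is_arbitrary:
                ng = replace(g, axis=PHYSICAL_AXES[row], waveform=tuple(sign * v for v in g.waveform))
            else:
                ng = replace(g, axis=PHYSICAL_AXES[row], amplitude=sign * g.amplitude)
            new_grads.append(ng)
        new_grads = tuple(new_grads)
    else:
        # sample the logical vector waveform on the gradient raster and rotate
        t_end = max((g.end for g in block.gradients), default=0)
        t0 = min((g.start for g in block.gradients), default=0)
        t0 = (t0 // GRAD_RASTER_NS) * GRAD_RASTER_NS
        n = (ceil_to_raster(t_end - t0, GRAD_RASTER_NS)) // GRAD_RASTER_NS + 1
        times = t0 + np.arange(n) * GRAD_RASTER_NS
        logical = np.stack([_gradient_vector_at(block, t) for t in times], axis=1)
        physical = r @ logical
        new_grads = tuple(
            GradientEvent(axis=PHYSICAL_AXES[i], start=int(t0), waveform=tuple(physical[i]))
            for i in range(3)
            if np.any(physical[i] != 0)
        )

    rf = block.rf
    if rf is not None and np.any(offset):
        g_log = _gradient_vector_at(block, rf.center)
        g_phys = r @ g_log  # mT/m
        df = GAMMA_HZ_PER_T * float(g_phys @ offset) * 1e-3
        rf = replace(rf, frequency_offset=rf.frequency_offset + df)

    adc = block.adc
    if adc is not None and np.any(offset):
        g_log = _gradient_vector_at(block, adc.center)
        g_phys = r @ g_log
        df = GAMMA_HZ_PER_T * float(g_phys @ offset) * 1e-3
        adc = replace(adc, frequency_offset=adc.frequency_offset + df)

    return replace(block, gradients=new_grads, rf=rf, adc=adc)


# --------------------------------------------------------------------------


def dump_blocks(blocks: Iterable[ExecutionBlock]) -> str:
    """Line-oriented text dump of a block stream for debugging/diffing."""
    lines = []
    for i, b in enumerate(blocks):
        parts = [f"block {i} start={b.start} dur={b.duration} sync={int(b.sync)} label={b.label}"]
        if b.rf:
            parts.append(
                f"  rf start={b.rf.start} dur={b.rf.duration} peak={b.rf.peak_amplitude:.4f}uT "
                f"freq={b.rf.frequency_offset:.2f}Hz use={b.rf.use}"
            )
        for g in b.gradients:
            if g.is_arbitrary:
                parts.append(f"  grad {g.axis} start={g.start} arbitrary n={len(g.waveform)}")
            else:
                parts.append(
                    f"  grad {g.axis} start={g.start} amp={g.amplitude:.4f} "
                    f"rise={g.rise} flat={g.flat} fall={g.fall}"
                )
        if b.adc:
            h = b.adc.header
            parts.append(
                f"  adc start={b.adc.start} n={b.adc.samples} dwell={b.adc.dwell} "
                f"lin={h.line} par={h.partition} slc={h.slice} avg={h.average} set={h.set}"
            )
        lines.append("\n".join(parts))
    return "\n".join(lines) + ("\n" if lines else "")
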