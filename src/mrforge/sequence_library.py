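"""Blueprint implementations of the demonstrated sequence families.

Families are composed from shared blueprints (slice-selective excitation,
refocusing with crushers, Cartesian encode/readout/rewind, EPI echo trains,
spoilers, inversion, fat saturation, pCASL labeling) wired together by
parameter rules, so every derived quantity (fill times, encode schedules,
label timing) flows through the parameter graph and reacts to protocol or
feedback updates.

All times inside rules are integer nanoseconds; protocol times are
milliseconds.  Fill-time rules are named ``*_fill`` so the protocol checker
can flag infeasible TE/TR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
from scipy.linalg import hadamard
from scipy.optimize import least_squares

from ._units import (
    BLOCK_RASTER_NS,
    GAMMA_HZ_PER_T,
    GRAD_RASTER_NS,
    MS,
    S,
    DEFAULT_LIMITS,
    HardwareLimits,
    ceil_to_raster,
)
from .hardware_events import (
    ADCEvent,
    AcquisitionHeader,
    ExecutionBlock,
    GradientEvent,
    RFEvent,
    build_block,
)
from .sequence_model import (
    Blueprint,
    BlueprintRegistry,
    ElementTree,
    ParameterGraph,
    Protocol,
    Rule,
    assemble,
    const,
    rule_function,
)
from .waveforms import (
    EncodingTable,
    bipolar_diffusion,
    encoding_table,
    make_rf,
    make_slice_select,
    make_trapezoid,
    radial_directions,
)

__all__ = [
    "ASLSpec",
    "FAMILIES",
    "SpectroscopySpec",
    "asl_inflow_times",
    "build_sequence",
    "hadamard_label_train",
    "realized_te",
    "scan_duration",
    "sequence_definition",
    "stream_eager",
    "table1_protocol",
    "walsh_hadamard_8",
]

FAMILIES = (
    "flash",
    "bssfp",
    "mprage",
    "rare",
    "flair",
    "se_epi_diffusion",
    "grase_pcasl",
    "radial_ute",
    "steam",
    "press",
)


# ==========================================================================
# ASL specifications and Hadamard time encoding
# ==========================================================================


def walsh_hadamard_8() -> np.ndarray:
    """The 8×8 Hadamard matrix in Walsh (sequency) order: rows sorted by
    sign-change count, first row all +1, H·Hᵀ = 8·I."""
    h = hadamard(8)
    changes = (np.diff(h, axis=1) != 0).sum(axis=1)
    return h[np.argsort(changes, kind="stable")]


@dataclass(frozen=True)
class ASLSpec:
    """Hadamard time-encoded pCASL labeling parameters."""

    subbolus_duration_s: float = 0.4
    post_labeling_delay_s: float = 0.6
    background_suppression_t1s_ms: tuple[float, ...] = (700.0, 1400.0)

    @property
    def n_subboli(self) -> int:
        return 7

    @property
    def encoding(self) -> np.ndarray:
        return walsh_hadamard_8()


@dataclass(frozen=True)
class SpectroscopySpec:
    """Single-voxel spectroscopy acquisition parameters."""

    sequence: str = "steam"  # steam | press
    data_points: int = 2048
    spectral_bandwidth_hz: float = 2000.0
    mixing_time_ms: float = 10.0
    voxel_mm: tuple[float, float, float] = (25.0, 25.0, 25.0)
    water_suppression: bool = True

    @property
    def readout_duration_s(self) -> float:
        return self.data_points / self.spectral_bandwidth_hz


@dataclass(frozen=True)
class LabelSegment:
    start_s: float
    duration_s: float
    kind: str  # label | control


def hadamard_label_train(spec: ASLSpec, encode_index: int) -> list[LabelSegment]:
    """Label/control segment schedule for one Hadamard encode (1-based row).

    Columns 2..8 of the Walsh-ordered row map onto the 7 subboli (+1 →
    label, −1 → control), each of the subbolus duration, played
    back-to-back and followed by the post-labeling delay.
    """
    if not 1 <= encode_index <= 8:
        raise ValueError("encode_index must be in 1..8")
    row = spec.encoding[encode_index - 1]
    segs = []
    for k in range(spec.n_subboli):
        sign = row[k + 1]
        segs.append(
            LabelSegment(
                start_s=k * spec.subbolus_duration_s,
                duration_s=spec.subbolus_duration_s,
                kind="label" if sign > 0 else "control",
            )
        )
    return segs


def asl_inflow_times(spec: ASLSpec) -> list[float]:
    """Inflow time of each subbolus (k = 1 earliest-labeled):
    ``PLD + (N − k + 1)·subbolus_duration`` seconds."""
    n = spec.n_subboli
    return [
        spec.post_labeling_delay_s + (n - k + 1) * spec.subbolus_duration_s
        for k in range(1, n + 1)
    ]


def background_suppression_times(
    t1s_ms: tuple[float, ...], window_ms: float
) -> tuple[float, float]:
    """Two-inversion placement nulling the given T1 species at readout.

    Returns times (ms) of the two inversions *before the readout*, both
    constrained to the available window (bounded least squares on the
    longitudinal recovery residuals ``1 − 2e^{−t_b/T1} + 2e^{−t_a/T1}``).
    """

    def resid(x):
        a, b = x
        return [1 - 2 * math.exp(-b / t1) + 2 * math.exp(-a / t1) for t1 in t1s_ms]

    sol = least_squares(
        resid,
        x0=(0.8 * window_ms, 0.25 * window_ms),
        bounds=([1.0, 0.5], [window_ms, window_ms]),
    )
    a, b = sorted(sol.x, reverse=True)
    return float(a), float(b)


# ==========================================================================
# Rule functions shared by the family blueprints
# ==========================================================================


@rule_function("lib.ms_ns")
def _r_ms_ns(ms: float) -> int:
    return int(round(ms * MS))


@rule_function("lib.fill")
def _r_fill(total_ns: int, *parts: int) -> int:
    return int(total_ns) - int(sum(parts))


@rule_function("lib.linfill")
def _r_linfill(total_ns: int, count: int, unit_ns: int, *extra: int) -> int:
    return int(total_ns) - int(count) * int(unit_ns) - int(sum(extra))


@rule_function("lib.sum")
def _r_sum(*parts: int) -> int:
    return int(sum(parts))


@rule_function("lib.mul")
def _r_mul(a, b):
    return a * b


@rule_function("lib.item0")
def _r_item0(t):
    return t[0]


@rule_function("lib.item1")
def _r_item1(t):
    return t[1]


@rule_function("lib.item2")
def _r_item2(t):
    return t[2]


@rule_function("lib.item3")
def _r_item3(t):
    return t[3]


@rule_function("lib.matrix_dim")
def _r_matrix_dim(matrix, which: int) -> int:
    return int(matrix[int(which)])


@rule_function("lib.fov_dim")
def _r_fov_dim(fov, which: int) -> float:
    return float(fov[int(which)])


@rule_function("lib.delay_raw")
def _r_delay_raw(dur_ns: int) -> ExecutionBlock:
    dur = max(int(dur_ns), 0)
    dur = int(round(dur / BLOCK_RASTER_NS)) * BLOCK_RASTER_NS
    return ExecutionBlock(duration=dur)


@rule_function("lib.block_dur")
def _r_block_dur(raw: ExecutionBlock) -> int:
    return max(raw.duration, ceil_to_raster(raw.events_end(), BLOCK_RASTER_NS))


@rule_function("lib.enc_table")
def _r_enc_table(matrix_dim, pf, accel, ref_lines, ordering) -> EncodingTable:
    return encoding_table(int(matrix_dim), float(pf), int(accel), int(ref_lines), ordering)


@rule_function("lib.table_len")
def _r_table_len(table: EncodingTable) -> int:
    return len(table)


@rule_function("lib.table_entry")
def _r_table_entry(table: EncodingTable, i: int):
    return table.entries[int(i)]


@rule_function("lib.entry_index")
def _r_entry_index(entry) -> int:
    return entry.index


@rule_function("lib.center_echo")
def _r_center_echo(table: EncodingTable) -> int:
    """Train position of the line closest to the k-space center."""
    center = table.matrix_dim // 2
    best = min(range(len(table.entries)), key=lambda j: abs(table.entries[j].index - center))
    return best


@rule_function("lib.rare_line")
def _r_rare_line(table: EncodingTable, n_shots: int, echo: int, shot: int):
    return table.entries[int(echo) * int(n_shots) + int(shot)]


@rule_function("lib.n_shots")
def _r_n_shots(table: EncodingTable, etl: int) -> int:
    n = len(table)
    etl = int(etl)
    if n % etl:
        raise ValueError(f"{n} encodes not divisible by train length {etl}")
    return n // etl


# -- RF / excitation -------------------------------------------------------


@rule_function("lib.rf_pulse")
def _r_rf_pulse(shape, dur_ms, flip_deg, tbw, limits, phase_rad, use) -> RFEvent:
    return make_rf(shape, float(dur_ms), float(flip_deg), tbw, limits,
                   phase_offset=float(phase_rad), use=use)


def _slice_layout(rf: RFEvent, thickness_mm: float, limits: HardwareLimits):
    """Slice-select plateau geometry for a pulse: (grad, rf_start_ns)."""
    grad, _ = make_slice_select(rf, thickness_mm, limits)
    rf_start = grad.rise + (grad.flat - rf.duration) // 2
    return grad, rf_start


@rule_function("lib.excite_assembly")
def _r_excite_assembly(pulse: RFEvent, thickness_mm, limits, z_off_mm, extra_freq_hz):
    """Selective excitation block: (block, center_ns, tail_ns, dur_ns)."""
    grad, rf_start = _slice_layout(pulse, float(thickness_mm), limits)
    freq = GAMMA_HZ_PER_T * grad.amplitude * 1e-3 * float(z_off_mm) * 1e-3
    rf = replace(pulse, start=rf_start,
                 frequency_offset=pulse.frequency_offset + freq + float(extra_freq_hz))
    block = ExecutionBlock(duration=0, rf=rf, gradients=(grad,))
    dur = ceil_to_raster(block.events_end(), BLOCK_RASTER_NS)
    block = replace(block, duration=dur)
    center = rf.center
    return (block, center, dur - center, dur)


@rule_function("lib.hard_assembly")
def _r_hard_assembly(pulse: RFEvent):
    block = ExecutionBlock(duration=0, rf=pulse)
    dur = ceil_to_raster(block.events_end(), BLOCK_RASTER_NS)
    block = replace(block, duration=dur)
    return (block, pulse.center, dur - pulse.center, dur)


@rule_function("lib.refocus_assembly")
def _r_refocus_assembly(pulse: RFEvent, thickness_mm, limits, crusher_area):
    """Refocusing block with symmetric slice-axis crushers."""
    grad, rf_start = _slice_layout(pulse, float(thickness_mm), limits)
    crusher_area = float(crusher_area)
    if crusher_area:
        cr = make_trapezoid("SLICE", limits, area=crusher_area)
        shift = cr.duration
        grad = replace(grad, start=shift)
        rf = replace(pulse, start=rf_start + shift)
        cr2 = replace(cr, start=shift + grad.duration)
        grads = (cr, grad, cr2)
    else:
        rf = replace(pulse, start=rf_start)
        grads = (grad,)
    block = ExecutionBlock(duration=0, rf=rf, gradients=grads)
    dur = ceil_to_raster(block.events_end(), BLOCK_RASTER_NS)
    block = replace(block, duration=dur)
    return (block, rf.center, dur - rf.center, dur)


@rule_function("lib.voxel_pulse_assembly")
def _r_voxel_pulse_assembly(pulse: RFEvent, voxel_mm, limits, axis_idx):
    """Voxel-selective spectroscopy pulse on one logical axis."""
    axis = ("READ", "PHASE", "SLICE")[int(axis_idx)]
    thickness = float(voxel_mm[int(axis_idx)])
    grad, rf_start = _slice_layout(pulse, thickness, limits)
    grad = replace(grad, axis=axis)
    rf = replace(pulse, start=rf_start)
    block = ExecutionBlock(duration=0, rf=rf, gradients=(grad,))
    dur = ceil_to_raster(block.events_end(), BLOCK_RASTER_NS)
    return (replace(block, duration=dur), rf.center, dur - rf.center, dur)


@rule_function("lib.slice_reph_area")
def _r_slice_reph_area(pulse: RFEvent, thickness_mm, limits) -> float:
    grad, _ = _slice_layout(pulse, float(thickness_mm), limits)
    tail_ms = (1.0 - pulse.center_fraction) * pulse.duration / MS
    return -(grad.amplitude * tail_ms + grad.amplitude * (grad.fall / MS) / 2)


@rule_function("lib.fatsat_raw")
def _r_fatsat_raw(limits, b0_t) -> ExecutionBlock:
    """Spectrally selective fat saturation: Gaussian at −3.35 ppm + spoiler."""
    offset = -3.35e-6 * GAMMA_HZ_PER_T * float(b0_t)
    rf = make_rf("gauss", 10.24, 90.0, limits=limits, frequency_offset=offset,
                 use="saturation")
    spoil = make_trapezoid("SLICE", limits, area=20.0)
    spoil = replace(spoil, start=ceil_to_raster(rf.duration, GRAD_RASTER_NS))
    block = ExecutionBlock(duration=0, rf=rf, gradients=(spoil,))
    return replace(block, duration=ceil_to_raster(block.events_end(), BLOCK_RASTER_NS))


@rule_function("lib.inversion_assembly")
def _r_inversion_assembly(limits):
    """Nonselective adiabatic-style inversion placeholder (hard 180)."""
    rf = make_rf("hard", 1.0, 180.0, limits=limits, use="inversion")
    block = ExecutionBlock(duration=0, rf=rf)
    dur = ceil_to_raster(block.events_end(), BLOCK_RASTER_NS)
    return (replace(block, duration=dur), rf.center, dur - rf.center, dur)


# -- Cartesian encode / readout -------------------------------------------


def _pe_area(index: int, n: int, fov_mm: float) -> float:
    """Phase-encode area (mT/m·ms) for k-index ``index`` of ``n``."""
    k = (index - n // 2) / (fov_mm * 1e-3)  # 1/m
    return k / GAMMA_HZ_PER_T * 1e6


@rule_function("lib.readout_geom")
def _r_readout_geom(n, fov_mm, dwell_ns, limits) -> dict[str, Any]:
    """Frequency-encode geometry shared by dephaser/readout/timing rules."""
    n = int(n)
    dwell_s = int(dwell_ns) * 1e-9
    g_mt_m = 1.0 / (GAMMA_HZ_PER_T * dwell_s * float(fov_mm) * 1e-3) * 1e3
    if g_mt_m > limits.gmax:
        raise ValueError(f"readout gradient {g_mt_m:.2f} mT/m exceeds Gmax")
    rise = ceil_to_raster(int(math.ceil(g_mt_m / limits.slew * MS)), GRAD_RASTER_NS)
    adc_dur = n * int(dwell_ns)
    flat = ceil_to_raster(adc_dur, GRAD_RASTER_NS)
    adc_start = rise + (flat - adc_dur) // 2
    return {
        "n": n,
        "g": g_mt_m,
        "rise": rise,
        "flat": flat,
        "dwell": int(dwell_ns),
        "adc_start": adc_start,
        "adc_center": adc_start + adc_dur // 2,
        "dur": rise + flat + rise,
    }


@rule_function("lib.read_deph_area")
def _r_read_deph_area(geom) -> float:
    """Prephaser area putting k=0 at the ADC center (−A/2-style)."""
    g = geom["g"]
    rise_ms = geom["rise"] / MS
    to_center_ms = (geom["adc_center"] - geom["rise"]) / MS
    return -(g * rise_ms / 2 + g * to_center_ms)


@rule_function("lib.encode_raw")
def _r_encode_raw(entry_phase, entry_part, matrix, fov, limits,
                  read_deph_area, slice_extra_area, enc_dur_ms) -> ExecutionBlock:
    """Combined read-dephase + phase/partition encode (+slice rephaser)."""
    n1, n2 = int(matrix[1]), int(matrix[2])
    area_p = _pe_area(entry_phase.index, n1, float(fov[1])) if entry_phase is not None else 0.0
    area_s = _pe_area(entry_part.index, n2, float(fov[2])) if entry_part is not None else 0.0
    area_s += float(slice_extra_area)
    grads = []
    for axis, area in (("READ", float(read_deph_area)), ("PHASE", area_p), ("SLICE", area_s)):
        if area:
            grads.append(make_trapezoid(axis, limits, area=area, duration_ms=float(enc_dur_ms)))
    dur = ceil_to_raster(int(round(float(enc_dur_ms) * MS)), BLOCK_RASTER_NS)
    return ExecutionBlock(duration=dur, gradients=tuple(grads))


@rule_function("lib.rewind_raw")
def _r_rewind_raw(entry_phase, entry_part, matrix, fov, limits,
                  read_extra_area, enc_dur_ms, balanced) -> ExecutionBlock:
    """Rewinder (negated encodes) and spoiler/balancing on READ."""
    n1, n2 = int(matrix[1]), int(matrix[2])
    area_p = -_pe_area(entry_phase.index, n1, float(fov[1])) if entry_phase is not None else 0.0
    area_s = -_pe_area(entry_part.index, n2, float(fov[2])) if entry_part is not None else 0.0
    grads = []
    for axis, area in (("READ", float(read_extra_area)), ("PHASE", area_p), ("SLICE", area_s)):
        if area and (balanced or axis == "READ"):
            grads.append(make_trapezoid(axis, limits, area=area, duration_ms=float(enc_dur_ms)))
    dur = ceil_to_raster(int(round(float(enc_dur_ms) * MS)), BLOCK_RASTER_NS)
    return ExecutionBlock(duration=dur, gradients=tuple(grads))


@rule_function("lib.readout_raw")
def _r_readout_raw(geom, limits, entry_phase, entry_part, slice_idx,
                   contrast_idx, prescan_flagged) -> ExecutionBlock:
    g = GradientEvent(axis="READ", start=0, amplitude=geom["g"],
                      rise=geom["rise"], flat=geom["flat"], fall=geom["rise"])
    flags = []
    if entry_phase is not None and entry_phase.is_reference:
        flags.append("is_reference")
    if entry_part is not None and entry_part.is_reference and "is_reference" not in flags:
        flags.append("is_reference")
    if prescan_flagged:
        flags.append("is_prescan")
    header = AcquisitionHeader(
        line=entry_phase.index if entry_phase is not None else 0,
        partition=entry_part.index if entry_part is not None else 0,
        slice=int(slice_idx),
        contrast=int(contrast_idx),
        flags=tuple(flags),
    )
    adc = ADCEvent(start=geom["adc_start"], samples=geom["n"], dwell=geom["dwell"], header=header)
    block = ExecutionBlock(duration=0, gradients=(g,), adc=adc)
    return replace(block, duration=ceil_to_raster(block.events_end(), BLOCK_RASTER_NS))


@rule_function("lib.blip_step")
def _r_blip_step(table: EncodingTable) -> int:
    p = table.pattern()
    return (p[1] - p[0]) if len(p) > 1 else 1


@rule_function("lib.epi_echo_raw")
def _r_epi_echo_raw(geom, limits, matrix, fov, echo_idx, entry_phase, entry_part,
                    slice_idx, contrast_idx, etl, blip_step) -> ExecutionBlock:
    """One EPI gradient echo: alternating readout + phase blip (uniform
    stride of the accelerated pattern; the headers define the recon order)."""
    echo = int(echo_idx)
    sign = 1.0 if echo % 2 == 0 else -1.0
    g = GradientEvent(axis="READ", start=0, amplitude=sign * geom["g"],
                      rise=geom["rise"], flat=geom["flat"], fall=geom["rise"])
    flags = ["reverse"] if sign < 0 else []
    if entry_phase is not None and entry_phase.is_reference:
        flags.append("is_reference")
    header = AcquisitionHeader(
        line=entry_phase.index if entry_phase is not None else 0,
        partition=entry_part.index if entry_part is not None else 0,
        slice=int(slice_idx),
        contrast=int(contrast_idx),
        segment=echo,
        flags=tuple(flags),
    )
    adc = ADCEvent(start=geom["adc_start"], samples=geom["n"], dwell=geom["dwell"], header=header)
    grads = [g]
    if echo < int(etl) - 1:
        n1 = int(matrix[1])
        stride_area = int(blip_step) * (_pe_area(1, n1, float(fov[1])) - _pe_area(0, n1, float(fov[1])))
        blip = make_trapezoid("PHASE", limits, area=stride_area)
        grads.append(replace(blip, start=geom["dur"] - blip.duration))
    block = ExecutionBlock(duration=0, gradients=tuple(grads), adc=adc)
    return replace(block, duration=ceil_to_raster(block.events_end(), BLOCK_RASTER_NS))


@rule_function("lib.epi_esp")
def _r_epi_esp(geom) -> int:
    return ceil_to_raster(geom["dur"], BLOCK_RASTER_NS)


@rule_function("lib.spoiler_raw")
def _r_spoiler_raw(limits, area, dur_ms) -> ExecutionBlock:
    g = make_trapezoid("SLICE", limits, area=float(area), duration_ms=float(dur_ms))
    dur = ceil_to_raster(int(round(float(dur_ms) * MS)), BLOCK_RASTER_NS)
    return ExecutionBlock(duration=dur, gradients=(g,))


# -- bSSFP / MPRAGE / diffusion / ASL / radial / spectroscopy helpers ------


@rule_function("lib.bssfp_phase")
def _r_bssfp_phase(prescans, part_idx, line_idx, n_lines) -> float:
    k = int(prescans) + int(part_idx) * int(n_lines) + int(line_idx)
    return math.pi * (k % 2)


@rule_function("lib.ramp_phase")
def _r_ramp_phase(i) -> float:
    return math.pi * (int(i) % 2)


@rule_function("lib.ramp_flip")
def _r_ramp_flip(flip, i, n) -> float:
    return float(flip) * (int(i) + 1) / (int(n) + 1)


@rule_function("lib.diffusion_volume")
def _r_diffusion_volume(b_values, vol_idx) -> tuple[float, int]:
    """Volume schedule: one b=0 plus each nonzero b on each of 3 axes."""
    v = int(vol_idx)
    nonzero = [b for b in b_values if b > 0]
    if v == 0:
        return (0.0, 0)
    v -= 1
    return (float(nonzero[v // 3]), v % 3)


@rule_function("lib.lobe_ns")
def _r_lobe_ns(lobe_ms) -> int:
    return ceil_to_raster(int(round(float(lobe_ms) * MS)), BLOCK_RASTER_NS)


@rule_function("lib.diffusion_lobe_raw")
def _r_diffusion_lobe_raw(volume, lobe_ms, gap_ns, limits) -> ExecutionBlock:
    """One diffusion lobe of the pair straddling the refocusing pulse.

    Both lobes share the same physical polarity; the 180° between them
    makes the pair an effective bipolar waveform.  The amplitude is solved
    for the target b of the volume schedule at the realized inter-lobe gap
    (fill delay + refocusing block), so the nominal b is met by the pair.
    """
    b, axis_idx = volume
    axis = ("READ", "PHASE", "SLICE")[axis_idx]
    if b == 0:
        dur = ceil_to_raster(int(round(float(lobe_ms) * MS)), BLOCK_RASTER_NS)
        return ExecutionBlock(duration=dur)
    spec = bipolar_diffusion(b, float(lobe_ms), limits, gap_ms=int(gap_ns) / MS)
    rise = ceil_to_raster(int(math.ceil(spec.amplitude / limits.slew * MS)), GRAD_RASTER_NS)
    total = ceil_to_raster(int(round(float(lobe_ms) * MS)), GRAD_RASTER_NS)
    flat = max(total - 2 * rise, 0)
    lobe = GradientEvent(axis=axis, start=0, amplitude=spec.amplitude,
                         rise=rise, flat=flat, fall=rise)
    block = ExecutionBlock(duration=0, gradients=(lobe,))
    return replace(block, duration=ceil_to_raster(block.events_end(), BLOCK_RASTER_NS))


@rule_function("lib.label_segment_raw")
def _r_label_segment_raw(spec_sub_s, encoding_row, seg_idx, limits) -> ExecutionBlock:
    """One pCASL subbolus segment (label or control by Hadamard sign).

    The continuous labeling RF train is abstracted to its average gradient
    (label) or zero net gradient (control) over the segment.
    """
    sign = int(encoding_row[int(seg_idx) + 1])
    dur = ceil_to_raster(int(round(float(spec_sub_s) * S)), BLOCK_RASTER_NS)
    amp = 1.0 if sign > 0 else -1.0
    g = GradientEvent(axis="SLICE", start=0, amplitude=amp,
                      rise=GRAD_RASTER_NS, flat=dur - 2 * GRAD_RASTER_NS, fall=GRAD_RASTER_NS)
    return ExecutionBlock(duration=dur, gradients=(g,))


@rule_function("lib.hadamard_row")
def _r_hadamard_row(encode_idx) -> tuple[int, ...]:
    return tuple(int(v) for v in walsh_hadamard_8()[int(encode_idx)])


@rule_function("lib.bs_times")
def _r_bs_times(t1s_ms, pld_ms) -> tuple[float, float]:
    return background_suppression_times(tuple(t1s_ms), float(pld_ms))


@rule_function("lib.bs_delays")
def _r_bs_delays(bs_times, pld_ms, inv_dur_ns) -> tuple[int, int, int]:
    """Split the PLD into [d1, inv, d2, inv, d3] with the inversions at the
    solved times-before-readout (centers aligned as closely as rasters allow)."""
    a, b = bs_times
    pld = int(round(float(pld_ms) * MS))
    inv = int(inv_dur_ns)
    t_a = pld - int(round(a * MS))  # inversion-center targets from PLD start
    t_b = pld - int(round(b * MS))
    d1 = max(t_a - inv // 2, 0)
    d2 = max(t_b - inv // 2 - (d1 + inv), 0)
    d3 = max(pld - (d1 + inv + d2 + inv), 0)
    return (d1, d2, d3)


@rule_function("lib.spoke_dir")
def _r_spoke_dir(mode, i, n_angles) -> tuple[float, float, float]:
    """O(1) per-spoke direction (same conventions as ``radial_directions``)."""
    i = int(i)
    if mode == "calibration_planes":
        n = int(n_angles)
        plane, j = divmod(i, n)
        a = 2 * math.pi * j / n
        c, s = math.cos(a), math.sin(a)
        return ((c, s, 0.0), (c, 0.0, s), (0.0, c, s))[plane]
    from .waveforms import GOLDEN_MEANS

    z = 1.0 - 2.0 * math.fmod(i * GOLDEN_MEANS[0], 1.0)
    phi = 2 * math.pi * math.fmod(i * GOLDEN_MEANS[1], 1.0)
    rho = math.sqrt(max(1.0 - z * z, 0.0))
    return (rho * math.cos(phi), rho * math.sin(phi), z)


@rule_function("lib.ute_spoke_raw")
def _r_ute_spoke_raw(direction, matrix, fov, limits, te_ms, flip, dwell_ns,
                     spoke_idx, is_prescan, dephase_area) -> ExecutionBlock:
    """Center-out radial spoke: short hard pulse, then ramp-sampled readout
    along ``direction`` (calibration spokes add a small dephaser first)."""
    rf = make_rf("hard", 0.1, float(flip), limits=limits, use="excite")
    n = int(matrix[0]) // 2  # center-out: half diameter of samples
    dwell = int(dwell_ns)
    kmax = n / (float(fov[0]) * 1e-3)  # 1/m (center-out radius)
    g = kmax / (GAMMA_HZ_PER_T * n * dwell * 1e-9) * 1e3  # mT/m
    rise = ceil_to_raster(int(math.ceil(g / limits.slew * MS)), GRAD_RASTER_NS)
    te_fill = int(round(float(te_ms) * MS)) - (rf.duration - rf.center)
    if te_fill < 0:
        raise ValueError("UTE echo time shorter than RF tail")
    g_start = rf.duration + te_fill
    deph_dur = 0
    grads = []
    if float(dephase_area):
        deph = make_trapezoid("READ", limits, area=float(dephase_area))
        deph_dur = deph.duration
        g_start += deph_dur
    adc_dur = n * dwell
    flat = ceil_to_raster(max(adc_dur - rise, 0), GRAD_RASTER_NS)
    for axis, comp in zip(("X", "Y", "Z"), direction):
        if abs(comp) > 1e-12:
            grads.append(GradientEvent(axis=axis, start=g_start, amplitude=g * comp,
                                       rise=rise, flat=flat, fall=rise))
            if float(dephase_area):
                d = make_trapezoid(axis, limits, area=float(dephase_area) * comp)
                grads.insert(-1, replace(d, start=g_start - deph_dur))
    header = AcquisitionHeader(
        line=int(spoke_idx),
        flags=("is_prescan",) if is_prescan else (),
        trajectory_id=2 if is_prescan else 1,
    )
    adc = ADCEvent(start=g_start, samples=n, dwell=dwell, header=header)
    block = ExecutionBlock(duration=0, rf=rf, gradients=tuple(grads), adc=adc)
    return replace(block, duration=ceil_to_raster(block.events_end(), BLOCK_RASTER_NS))


@rule_function("lib.svs_acquire_raw")
def _r_svs_acquire_raw(data_points, bandwidth_hz, rep_idx, prescans) -> ExecutionBlock:
    dwell = int(round(1e9 / float(bandwidth_hz)))
    rep = int(rep_idx)
    pre = int(prescans)
    header = AcquisitionHeader(
        average=max(rep - pre, 0),
        flags=("is_prescan",) if rep < pre else (),
    )
    adc = ADCEvent(start=0, samples=int(data_points), dwell=dwell, header=header)
    block = ExecutionBlock(duration=0, adc=adc)
    return replace(block, duration=ceil_to_raster(block.events_end(), BLOCK_RASTER_NS))


@rule_function("lib.water_sup_raw")
def _r_water_sup_raw(limits, enabled) -> ExecutionBlock:
    """Water-suppression placeholder (single suppression pulse + spoiler)."""
    if not enabled:
        return ExecutionBlock(duration=0)
    rf = make_rf("gauss", 20.0, 90.0, limits=limits, use="saturation")
    spoil = make_trapezoid("SLICE", limits, area=20.0)
    spoil = replace(spoil, start=ceil_to_raster(rf.duration, GRAD_RASTER_NS))
    block = ExecutionBlock(duration=0, rf=rf, gradients=(spoil,))
    return replace(block, duration=ceil_to_raster(block.events_end(), BLOCK_RASTER_NS))


@rule_function("lib.half_ns")
def _r_half_ns(total_ms) -> int:
    return int(round(float(total_ms) * MS / 2))


@rule_function("lib.quarter_ns")
def _r_quarter_ns(total_ms) -> int:
    return int(round(float(total_ms) * MS / 4))


@rule_function("lib.epi_center_offset")
def _r_epi_center_offset(center_echo, esp, geom) -> int:
    return int(center_echo) * int(esp) + geom["adc_center"]


@rule_function("lib.epi_tail_offset")
def _r_epi_tail_offset(etl, center_echo, esp, geom) -> int:
    return int(etl) * int(esp) - (int(center_echo) * int(esp) + geom["adc_center"])


@rule_function("lib.flair_slice")
def _r_flair_slice(concat_idx, slice_idx, n_concat) -> int:
    return int(concat_idx) + int(n_concat) * int(slice_idx)


@rule_function("lib.geom_adc_center")
def _r_geom_adc_center(geom) -> int:
    return int(geom["adc_center"])


@rule_function("lib.geom_dur")
def _r_geom_dur(geom) -> int:
    return int(geom["dur"])


@rule_function("lib.ref_lines")
def _r_ref_lines(accel, requested, matrix_dim) -> int:
    """Reference-band width: requested, else 24 for accelerated scans,
    clamped to the matrix."""
    if requested is None:
        requested = 24 if int(accel) > 1 else 0
    return min(int(requested), int(matrix_dim))


@rule_function("lib.balance_read_area")
def _r_balance_read_area(geom, deph_area) -> float:
    total = geom["g"] * (geom["rise"] + geom["flat"]) / MS
    return -(float(deph_area) + total)


@rule_function("lib.rare_echo_raw")
def _r_rare_echo_raw(geom, limits, matrix, fov, entry, slice_idx,
                     enc_dur_ms, read_deph) -> ExecutionBlock:
    """One CPMG echo: encode, read out, rewind — read and phase axes are
    balanced across the block so every echo sees the same net gradient."""
    enc = ceil_to_raster(int(round(float(enc_dur_ms) * MS)), BLOCK_RASTER_NS)
    n1 = int(matrix[1])
    pe = _pe_area(entry.index, n1, float(fov[1]))
    grads = []
    for axis, area, start in (
        ("READ", float(read_deph), 0),
        ("PHASE", pe, 0),
        ("READ", float(read_deph), enc + geom["dur"]),
        ("PHASE", -pe, enc + geom["dur"]),
    ):
        if area:
            t = make_trapezoid(axis, limits, area=area, duration_ms=float(enc_dur_ms))
            grads.append(replace(t, start=start))
    grads.append(GradientEvent(axis="READ", start=enc, amplitude=geom["g"],
                               rise=geom["rise"], flat=geom["flat"], fall=geom["rise"]))
    flags = ("is_reference",) if entry.is_reference else ()
    header = AcquisitionHeader(line=entry.index, slice=int(slice_idx), flags=flags)
    adc = ADCEvent(start=enc + geom["adc_start"], samples=geom["n"],
                   dwell=geom["dwell"], header=header)
    block = ExecutionBlock(duration=0, gradients=tuple(grads), adc=adc)
    return replace(block, duration=ceil_to_raster(block.events_end(), BLOCK_RASTER_NS))


@rule_function("lib.n_diff_vols")
def _r_n_diff_vols(b_values) -> int:
    return 1 + 3 * sum(1 for b in b_values if b > 0)


@rule_function("lib.calib_count")
def _r_calib_count(n_angles) -> int:
    return 3 * int(n_angles)


@rule_function("lib.int")
def _r_int(x) -> int:
    return int(x)


@rule_function("lib.s_to_ms")
def _r_s_to_ms(x_s) -> float:
    return float(x_s) * 1e3


@rule_function("lib.group_size")
def _r_group_size(total, n_groups) -> int:
    total, n_groups = int(total), int(n_groups)
    if total % n_groups:
        raise ValueError(f"{total} slices not divisible into {n_groups} concatenations")
    return total // n_groups


# ==========================================================================
# Family builders
# ==========================================================================
#
# Each builder registers the family's blueprints (prefix "<family>.") into a
# fresh registry and returns the root blueprint name.  Shared structures are
# produced by the helper factories below; family differences enter through
# const rules and rule overrides.


def _atomic(name: str, rules: dict[str, Rule]) -> Blueprint:
    rules = dict(rules)
    if "dur" not in rules:
        rules["dur"] = Rule("lib.block_dur", ("raw",))
    return Blueprint(name, rules=rules, is_atomic=True)


def _delay_bp(name: str, fill_dep: str) -> Blueprint:
    return _atomic(name, {"raw": Rule("lib.delay_raw", (fill_dep,))})


def _excite_bp(name: str, flip_dep: str = "protocol.flip",
               phase_rule: Rule | None = None, shape: str = "hann_sinc",
               dur_ms: float = 2.56, use: str = "excite") -> Blueprint:
    return _atomic(name, {
        "rf_shape": const(shape),
        "rf_dur_ms": const(dur_ms),
        "rf_tbw": const(4.0),
        "rf_use": const(use),
        "rf_phase": phase_rule if phase_rule is not None else const(0.0),
        "extra_freq": const(0.0),
        "pulse": Rule("lib.rf_pulse", ("rf_shape", "rf_dur_ms", flip_dep,
                                       "rf_tbw", "limits.all", "rf_phase", "rf_use")),
        "assembly": Rule("lib.excite_assembly",
                         ("pulse", "protocol.slice_thickness", "limits.all",
                          "protocol.slice_offset_z", "extra_freq")),
        "raw": Rule("lib.item0", ("assembly",)),
        "center": Rule("lib.item1", ("assembly",)),
        "tail": Rule("lib.item2", ("assembly",)),
        "dur": Rule("lib.item3", ("assembly",)),
    })


def _refocus_bp(name: str, crusher_area: float = 8.0) -> Blueprint:
    return _atomic(name, {
        "rf_shape": const("hann_sinc"),
        "rf_dur_ms": const(2.56),
        "rf_tbw": const(4.0),
        "rf_use": const("refocus"),
        "rf_phase": const(math.pi / 2),  # CPMG phase
        "crusher_area": const(crusher_area),
        "pulse": Rule("lib.rf_pulse", ("rf_shape", "rf_dur_ms", "protocol.refocus_flip",
                                       "rf_tbw", "limits.all", "rf_phase", "rf_use")),
        "assembly": Rule("lib.refocus_assembly",
                         ("pulse", "protocol.slice_thickness", "limits.all", "crusher_area")),
        "raw": Rule("lib.item0", ("assembly",)),
        "center": Rule("lib.item1", ("assembly",)),
        "tail": Rule("lib.item2", ("assembly",)),
        "dur": Rule("lib.item3", ("assembly",)),
    })


def _inversion_bp(name: str) -> Blueprint:
    return _atomic(name, {
        "assembly": Rule("lib.inversion_assembly", ("limits.all",)),
        "raw": Rule("lib.item0", ("assembly",)),
        "center": Rule("lib.item1", ("assembly",)),
        "tail": Rule("lib.item2", ("assembly",)),
        "dur": Rule("lib.item3", ("assembly",)),
    })


def _root_rules_cartesian() -> dict[str, Rule]:
    """Timing/encoding rules shared by the Cartesian family roots."""
    return {
        "te_ns": Rule("lib.ms_ns", ("protocol.te",)),
        "tr_ns": Rule("lib.ms_ns", ("protocol.tr",)),
        "dim1": const(1),
        "dim2": const(2),
        "dim0": const(0),
        "m0": Rule("lib.matrix_dim", ("protocol.matrix", "dim0")),
        "m1": Rule("lib.matrix_dim", ("protocol.matrix", "dim1")),
        "m2": Rule("lib.matrix_dim", ("protocol.matrix", "dim2")),
        "fov0": Rule("lib.fov_dim", ("protocol.fov", "dim0")),
        "ordering": const("linear"),
        "ref_phase": Rule("lib.ref_lines",
                          ("protocol.accel_phase", "protocol.ref_lines", "m1")),
        "ref_slice": Rule("lib.ref_lines",
                          ("protocol.accel_slice", "protocol.ref_lines", "m2")),
        "table_phase": Rule("lib.enc_table", ("m1", "protocol.pf_phase",
                                              "protocol.accel_phase", "ref_phase", "ordering")),
        "table_part": Rule("lib.enc_table", ("m2", "protocol.pf_slice",
                                             "protocol.accel_slice", "ref_slice", "ordering")),
        "n_lines": Rule("lib.table_len", ("table_phase",)),
        "n_parts": Rule("lib.table_len", ("table_part",)),
        "geom": Rule("lib.readout_geom", ("m0", "fov0", "protocol.dwell_ns", "limits.all")),
        "read_deph": Rule("lib.read_deph_area", ("geom",)),
        "enc_dur_ms": const(0.8),
    }


_COMMON_EXTRAS: dict[str, Any] = {
    "dwell_ns": 10_000,
    "ref_lines": None,
    "slice_offset_z": 0.0,
    "b0_t": 3.0,
}


def _with_extras(protocol: Protocol, defaults: dict[str, Any]) -> Protocol:
    extras = dict(_COMMON_EXTRAS)
    extras.update(defaults)
    extras.update(protocol.extras)
    return replace(protocol, extras=extras)


# -- FLASH / bSSFP ---------------------------------------------------------


def _encode_bp(name: str, balanced: bool) -> Blueprint:
    return _atomic(name, {
        "entry_phase": Rule("lib.table_entry", ("table_phase", "line_loop.index")),
        "entry_part": Rule("lib.table_entry", ("table_part", "part_loop.index")),
        "sreph": Rule("lib.slice_reph_area",
                      ("exc.pulse", "protocol.slice_thickness", "limits.all")),
        "raw": Rule("lib.encode_raw", ("entry_phase", "entry_part", "protocol.matrix",
                                       "protocol.fov", "limits.all", "read_deph",
                                       "sreph", "enc_dur_ms")),
    })


def _readout_bp(name: str) -> Blueprint:
    return _atomic(name, {
        "slice_idx": const(0),
        "contrast_idx": const(0),
        "prescan_flag": const(False),
        "raw": Rule("lib.readout_raw", ("geom", "limits.all", "enc.entry_phase",
                                        "enc.entry_part", "slice_idx", "contrast_idx",
                                        "prescan_flag")),
        "pre_center": Rule("lib.geom_adc_center", ("geom",)),
    })


def _gre_family(family: str, balanced: bool) -> tuple[str, BlueprintRegistry]:
    p = family
    reg = BlueprintRegistry()
    if balanced:
        phase = Rule("lib.bssfp_phase", ("protocol.prescans", "part_loop.index",
                                         "line_loop.index", "n_lines"))
    else:
        phase = None
    reg.add(_excite_bp(f"{p}.exc", phase_rule=phase))
    reg.add(_encode_bp(f"{p}.enc", balanced))
    reg.add(_delay_bp(f"{p}.dte", "te_fill"))
    reg.add(_readout_bp(f"{p}.ro"))
    if balanced:
        reg.add(_atomic(f"{p}.spl", {
            "balance_read": Rule("lib.balance_read_area", ("geom", "read_deph")),
            "balanced": const(True),
            "raw": Rule("lib.rewind_raw", ("enc.entry_phase", "enc.entry_part",
                                           "protocol.matrix", "protocol.fov", "limits.all",
                                           "balance_read", "enc_dur_ms", "balanced")),
        }))
    else:
        reg.add(_atomic(f"{p}.spl", {
            "spoil_area": const(20.0),
            "spoil_dur_ms": const(1.0),
            "raw": Rule("lib.spoiler_raw", ("limits.all", "spoil_area", "spoil_dur_ms")),
        }))
    reg.add(_delay_bp(f"{p}.dtr", "tr_fill"))
    reg.add(Blueprint(f"{p}.tr", rules={
        "te_fill": Rule("lib.fill", ("te_ns", "exc.tail", "enc.dur", "ro.pre_center")),
        "tr_fill": Rule("lib.fill", ("tr_ns", "exc.dur", "enc.dur", "dte.dur",
                                     "ro.dur", "spl.dur")),
    }, children=(
        ("exc", f"{p}.exc"), ("enc", f"{p}.enc"), ("dte", f"{p}.dte"),
        ("ro", f"{p}.ro"), ("spl", f"{p}.spl"), ("dtr", f"{p}.dtr"),
    )))
    reg.add(Blueprint(f"{p}.line_loop", rules={
        "count": Rule("lib.table_len", ("table_phase",)),
    }, children=(("tr", f"{p}.tr"),), is_loop=True))
    reg.add(Blueprint(f"{p}.part_loop", rules={
        "count": Rule("lib.table_len", ("table_part",)),
    }, children=(("line_loop", f"{p}.line_loop"),), is_loop=True))
    children = [("part_loop", f"{p}.part_loop")]
    root_rules = _root_rules_cartesian()
    if balanced:
        reg.add(_atomic(f"{p}.ramp_exc", {
            "rf_shape": const("hann_sinc"),
            "rf_dur_ms": const(2.56),
            "rf_tbw": const(4.0),
            "rf_use": const("excite"),
            "ramp_flip": Rule("lib.ramp_flip", ("protocol.flip", "ramp_loop.index",
                                                "protocol.prescans")),
            "rf_phase": Rule("lib.ramp_phase", ("ramp_loop.index",)),
            "extra_freq": const(0.0),
            "pulse": Rule("lib.rf_pulse", ("rf_shape", "rf_dur_ms", "ramp_flip",
                                           "rf_tbw", "limits.all", "rf_phase", "rf_use")),
            "assembly": Rule("lib.excite_assembly",
                             ("pulse", "protocol.slice_thickness", "limits.all",
                              "protocol.slice_offset_z", "extra_freq")),
            "raw": Rule("lib.item0", ("assembly",)),
            "dur": Rule("lib.item3", ("assembly",)),
        }))
        reg.add(_delay_bp(f"{p}.ramp_fill", "ramp_tr_fill"))
        reg.add(Blueprint(f"{p}.ramp_tr", rules={
            "ramp_tr_fill": Rule("lib.fill", ("tr_ns", "rexc.dur")),
        }, children=(("rexc", f"{p}.ramp_exc"), ("rfill", f"{p}.ramp_fill"))))
        reg.add(Blueprint(f"{p}.ramp_loop", rules={
            "count": Rule("lib.int", ("protocol.prescans",)),
        }, children=(("ramp_tr", f"{p}.ramp_tr"),), is_loop=True))
        children.insert(0, ("ramp_loop", f"{p}.ramp_loop"))
    reg.add(Blueprint(f"{p}.avg_loop", rules={
        "count": Rule("lib.int", ("protocol.averages",)),
        "counter": const("average"),
    }, children=tuple(children), is_loop=True))
    reg.add(Blueprint(f"{p}.seq", rules=root_rules,
                      children=(("avg_loop", f"{p}.avg_loop"),)))
    return f"{p}.seq", reg


# -- MPRAGE ----------------------------------------------------------------


def _mprage_family() -> tuple[str, BlueprintRegistry]:
    p = "mprage"
    reg = BlueprintRegistry()
    reg.add(_excite_bp(f"{p}.exc"))
    reg.add(Blueprint(f"{p}.enc", rules={
        "entry_phase": Rule("lib.table_entry", ("table_phase", "line_loop.index")),
        "entry_part": Rule("lib.table_entry", ("table_part", "part_loop.index")),
        "sreph": Rule("lib.slice_reph_area",
                      ("exc.pulse", "protocol.slice_thickness", "limits.all")),
        "raw": Rule("lib.encode_raw", ("entry_phase", "entry_part", "protocol.matrix",
                                       "protocol.fov", "limits.all", "read_deph",
                                       "sreph", "enc_dur_ms")),
        "dur": Rule("lib.block_dur", ("raw",)),
    }, is_atomic=True))
    reg.add(_delay_bp(f"{p}.dte", "te_fill"))
    reg.add(_readout_bp(f"{p}.ro"))
    reg.add(_atomic(f"{p}.spl", {
        "spoil_area": const(20.0),
        "spoil_dur_ms": const(1.0),
        "raw": Rule("lib.spoiler_raw", ("limits.all", "spoil_area", "spoil_dur_ms")),
    }))
    reg.add(_delay_bp(f"{p}.dtr", "inner_tr_fill"))
    reg.add(Blueprint(f"{p}.tr", rules={
        "inner_tr_ns": Rule("lib.ms_ns", ("protocol.readout_tr_ms",)),
        "te_fill": Rule("lib.fill", ("te_ns", "exc.tail", "enc.dur", "ro.pre_center")),
        "inner_tr_fill": Rule("lib.fill", ("inner_tr_ns", "exc.dur", "enc.dur",
                                           "dte.dur", "ro.dur", "spl.dur")),
    }, children=(
        ("exc", f"{p}.exc"), ("enc", f"{p}.enc"), ("dte", f"{p}.dte"),
        ("ro", f"{p}.ro"), ("spl", f"{p}.spl"), ("dtr", f"{p}.dtr"),
    )))
    reg.add(Blueprint(f"{p}.line_loop", rules={
        "count": Rule("lib.table_len", ("table_phase",)),
    }, children=(("tr", f"{p}.tr"),), is_loop=True))
    reg.add(_inversion_bp(f"{p}.inv"))
    reg.add(_delay_bp(f"{p}.dti", "ti_fill"))
    reg.add(_delay_bp(f"{p}.dshot", "shot_fill"))
    reg.add(Blueprint(f"{p}.part_loop", rules={
        "count": Rule("lib.table_len", ("table_part",)),
        "ti_ns": Rule("lib.ms_ns", ("protocol.ti",)),
        "inner_tr_unit": Rule("lib.ms_ns", ("protocol.readout_tr_ms",)),
        "ti_fill": Rule("lib.fill", ("ti_ns", "inv.tail", "line_loop.tr.exc.center")),
        "shot_fill": Rule("lib.linfill", ("tr_ns", "n_lines", "inner_tr_unit",
                                          "inv.dur", "dti.dur")),
    }, children=(
        ("inv", f"{p}.inv"), ("dti", f"{p}.dti"),
        ("line_loop", f"{p}.line_loop"), ("dshot", f"{p}.dshot"),
    ), is_loop=True))
    reg.add(Blueprint(f"{p}.seq", rules=_root_rules_cartesian(),
                      children=(("part_loop", f"{p}.part_loop"),)))
    return f"{p}.seq", reg


# -- RARE / FLAIR ----------------------------------------------------------


def _rare_echo_bp(name: str, slice_rule: Rule) -> Blueprint:
    return _atomic(name, {
        "slice_idx": slice_rule,
        "entry": Rule("lib.rare_line", ("table_phase", "n_shots",
                                        "echo_loop.index", "shot_loop.index")),
        "raw": Rule("lib.rare_echo_raw", ("geom", "limits.all", "protocol.matrix",
                                          "protocol.fov", "entry", "slice_idx",
                                          "enc_dur_ms", "read_deph")),
        "ce": Rule("lib.sum", ("enc_ns", "pre_center")),
        "post_ce": Rule("lib.fill", ("dur", "ce")),
        "pre_center": Rule("lib.geom_adc_center", ("geom",)),
        "enc_ns": Rule("lib.ms_ns", ("enc_dur_ms",)),
    })


def _rare_like(p: str, with_inversion: bool, n_concat: int) -> tuple[str, BlueprintRegistry]:
    reg = BlueprintRegistry()
    reg.add(_excite_bp(f"{p}.exc", shape="hann_sinc"))
    reg.add(_refocus_bp(f"{p}.rfc"))
    if n_concat > 1:
        slice_rule = Rule("lib.flair_slice",
                          ("concat_loop.index", "slice_loop.index", "n_concat"))
    else:
        slice_rule = const(0)
    reg.add(_rare_echo_bp(f"{p}.ech", slice_rule))
    reg.add(_delay_bp(f"{p}.d1", "d1_fill"))
    reg.add(_delay_bp(f"{p}.d2", "d2_fill"))
    reg.add(_delay_bp(f"{p}.d3", "d3_fill"))
    reg.add(Blueprint(f"{p}.echo_loop", rules={
        "count": Rule("lib.int", ("protocol.train_phase",)),
        "d2_fill": Rule("lib.fill", ("esp_half", "rfc.tail", "ech.ce")),
        "d3_fill": Rule("lib.fill", ("esp_half", "ech.post_ce", "rfc.center")),
    }, children=(
        ("rfc", f"{p}.rfc"), ("d2", f"{p}.d2"), ("ech", f"{p}.ech"), ("d3", f"{p}.d3"),
    ), is_loop=True))
    reg.add(Blueprint(f"{p}.shot", rules={
        "esp_half": Rule("lib.half_ns", ("protocol.te",)),
        "d1_fill": Rule("lib.fill", ("esp_half", "exc.tail", "echo_loop.rfc.center")),
        "etl": Rule("lib.int", ("protocol.train_phase",)),
        "body_dur": Rule("lib.sum", ("echo_loop.rfc.dur", "echo_loop.d2.dur",
                                     "echo_loop.ech.dur", "echo_loop.d3.dur")),
        "train_dur": Rule("lib.mul", ("etl", "body_dur")),
        "shot_dur": Rule("lib.sum", ("exc.dur", "d1.dur", "train_dur")),
    }, children=(("exc", f"{p}.exc"), ("d1", f"{p}.d1"), ("echo_loop", f"{p}.echo_loop"))))
    reg.add(Blueprint(f"{p}.slice_loop", rules={
        "count": Rule("lib.int", ("n_group",)),
        **({} if n_concat > 1 else {"counter": const("slice")}),
    }, children=(("shot", f"{p}.shot"),), is_loop=True))
    reg.add(_delay_bp(f"{p}.dtr", "tr_fill"))
    root_rules = _root_rules_cartesian()
    root_rules["n_shots"] = Rule("lib.n_shots", ("table_phase", "protocol.train_phase"))
    root_rules["n_concat"] = const(n_concat)
    shot_children: list[tuple[str, str]] = []
    if with_inversion:
        reg.add(_inversion_bp(f"{p}.inv"))
        reg.add(_delay_bp(f"{p}.dti", "ti_fill"))
        shot_children += [("inv", f"{p}.inv"), ("dti", f"{p}.dti")]
    shot_children += [("slice_loop", f"{p}.slice_loop"), ("dtr", f"{p}.dtr")]
    loop_rules: dict[str, Rule] = {
        "count": Rule("lib.int", ("n_shots",)),
        "n_group": Rule("lib.int", ("n_group_f",)),
        "tr_fill": Rule("lib.linfill", ("tr_ns", "n_group", "slice_loop.shot.shot_dur")
                        + (("inv.dur", "dti.dur") if with_inversion else ())),
    }
    if with_inversion:
        loop_rules["ti_ns"] = Rule("lib.ms_ns", ("protocol.ti",))
        loop_rules["ti_fill"] = Rule("lib.fill",
                                     ("ti_ns", "inv.tail", "slice_loop.shot.exc.center"))
    reg.add(Blueprint(f"{p}.shot_loop", rules=loop_rules,
                      children=tuple(shot_children), is_loop=True))
    root_rules["n_group_f"] = Rule("lib.group_size", ("m2", "n_concat"))
    if n_concat > 1:
        reg.add(Blueprint(f"{p}.concat_loop", rules={
            "count": const(n_concat),
        }, children=(("shot_loop", f"{p}.shot_loop"),), is_loop=True))
        top = ("concat_loop", f"{p}.concat_loop")
    else:
        top = ("shot_loop", f"{p}.shot_loop")
    reg.add(Blueprint(f"{p}.seq", rules=root_rules, children=(top,)))
    return f"{p}.seq", reg


# -- SE-EPI diffusion ------------------------------------------------------


def _epi_family() -> tuple[str, BlueprintRegistry]:
    p = "epi"
    reg = BlueprintRegistry()
    reg.add(_atomic(f"{p}.fatsat", {
        "raw": Rule("lib.fatsat_raw", ("limits.all", "protocol.b0_t")),
    }))
    reg.add(_excite_bp(f"{p}.exc"))
    reg.add(_refocus_bp(f"{p}.rfc"))
    for inst in ("diff1", "diff2"):
        reg.add(_atomic(f"{p}.{inst}", {
            "volume": Rule("lib.diffusion_volume", ("protocol.b_values", "vol_loop.index")),
            "gap_ns": Rule("lib.sum", ("d1.dur", "rfc.dur")),
            "raw": Rule("lib.diffusion_lobe_raw", ("volume", "protocol.diffusion_lobe_ms",
                                                   "gap_ns", "limits.all")),
        }))
    reg.add(_delay_bp(f"{p}.d1", "d1_fill"))
    reg.add(_delay_bp(f"{p}.d2", "d2_fill"))
    reg.add(_atomic(f"{p}.echo", {
        "slice_idx": const(0),
        "contrast_idx": const(0),
        "entry": Rule("lib.table_entry", ("table_phase", "epi_loop.index")),
        "entry_part": const(None),
        "raw": Rule("lib.epi_echo_raw", ("geom", "limits.all", "protocol.matrix",
                                         "protocol.fov", "epi_loop.index", "entry",
                                         "entry_part", "slice_idx", "contrast_idx",
                                         "etl", "blip")),
    }))
    reg.add(Blueprint(f"{p}.epi_loop", rules={
        "count": Rule("lib.int", ("etl",)),
    }, children=(("echo", f"{p}.echo"),), is_loop=True))
    reg.add(Blueprint(f"{p}.shot", rules={
        "te_half": Rule("lib.half_ns", ("protocol.te",)),
        "lobe_ns": Rule("lib.lobe_ns", ("protocol.diffusion_lobe_ms",)),
        "d1_fill": Rule("lib.fill", ("te_half", "exc.tail", "lobe_ns", "rfc.center")),
        "d2_fill": Rule("lib.fill", ("te_half", "rfc.tail", "lobe_ns", "center_off")),
        "center_off": Rule("lib.epi_center_offset", ("center_echo", "esp", "geom")),
        "train_dur": Rule("lib.mul", ("etl", "esp")),
        "shot_dur": Rule("lib.sum", ("fatsat.dur", "exc.dur", "lobe_ns", "d1.dur",
                                     "rfc.dur", "lobe_ns", "d2.dur", "train_dur")),
    }, children=(
        ("fatsat", f"{p}.fatsat"), ("exc", f"{p}.exc"), ("diff1", f"{p}.diff1"),
        ("d1", f"{p}.d1"), ("rfc", f"{p}.rfc"), ("diff2", f"{p}.diff2"),
        ("d2", f"{p}.d2"), ("epi_loop", f"{p}.epi_loop"),
    )))
    reg.add(Blueprint(f"{p}.slice_loop", rules={
        "count": Rule("lib.int", ("m2",)),
        "counter": const("slice"),
    }, children=(("shot", f"{p}.shot"),), is_loop=True))
    reg.add(_delay_bp(f"{p}.dtr", "tr_fill"))
    reg.add(Blueprint(f"{p}.vol_loop", rules={
        "count": Rule("lib.n_diff_vols", ("protocol.b_values",)),
        "counter": const("contrast"),
        "tr_fill": Rule("lib.linfill", ("tr_ns", "m2", "slice_loop.shot.shot_dur")),
    }, children=(("slice_loop", f"{p}.slice_loop"), ("dtr", f"{p}.dtr")), is_loop=True))
    root_rules = _root_rules_cartesian()
    root_rules["etl"] = Rule("lib.table_len", ("table_phase",))
    root_rules["center_echo"] = Rule("lib.center_echo", ("table_phase",))
    root_rules["esp"] = Rule("lib.epi_esp", ("geom",))
    root_rules["blip"] = Rule("lib.blip_step", ("table_phase",))
    reg.add(Blueprint(f"{p}.seq", rules=root_rules,
                      children=(("vol_loop", f"{p}.vol_loop"),)))
    return f"{p}.seq", reg


# -- GRASE pCASL -----------------------------------------------------------


def _grase_family() -> tuple[str, BlueprintRegistry]:
    p = "grase"
    reg = BlueprintRegistry()
    reg.add(_atomic(f"{p}.seg", {
        "row": Rule("lib.hadamard_row", ("set_loop.index",)),
        "raw": Rule("lib.label_segment_raw", ("protocol.subbolus_s", "row",
                                              "label_loop.index", "limits.all")),
    }))
    reg.add(Blueprint(f"{p}.label_loop", rules={
        "count": const(7),
    }, children=(("seg", f"{p}.seg"),), is_loop=True))
    reg.add(_inversion_bp(f"{p}.inv1"))
    reg.add(_inversion_bp(f"{p}.inv2"))
    reg.add(_delay_bp(f"{p}.db1", "bs_d1"))
    reg.add(_delay_bp(f"{p}.db2", "bs_d2"))
    reg.add(_delay_bp(f"{p}.db3", "bs_d3"))
    reg.add(_atomic(f"{p}.fatsat", {
        "raw": Rule("lib.fatsat_raw", ("limits.all", "protocol.b0_t")),
    }))
    reg.add(_excite_bp(f"{p}.exc"))
    reg.add(_refocus_bp(f"{p}.rfc"))
    reg.add(_delay_bp(f"{p}.d1", "d1_fill"))
    reg.add(_delay_bp(f"{p}.d2", "d2_fill"))
    reg.add(_delay_bp(f"{p}.d3", "d3_fill"))
    reg.add(_atomic(f"{p}.echo", {
        "slice_idx": const(0),
        "contrast_idx": const(0),
        "entry": Rule("lib.table_entry", ("table_phase", "epi_loop.index")),
        "entry_part": Rule("lib.table_entry", ("table_part", "rfc_loop.index")),
        "raw": Rule("lib.epi_echo_raw", ("geom", "limits.all", "protocol.matrix",
                                         "protocol.fov", "epi_loop.index", "entry",
                                         "entry_part", "slice_idx", "contrast_idx",
                                         "etl_g", "blip")),
    }))
    reg.add(Blueprint(f"{p}.epi_loop", rules={
        "count": Rule("lib.int", ("etl_g",)),
    }, children=(("echo", f"{p}.echo"),), is_loop=True))
    reg.add(Blueprint(f"{p}.rfc_loop", rules={
        "count": Rule("lib.int", ("n_rfc",)),
        "esp_half": Rule("lib.half_ns", ("protocol.te",)),
        "d2_fill": Rule("lib.fill", ("esp_half", "rfc.tail", "center_off")),
        "d3_fill": Rule("lib.fill", ("esp_half", "tail_off", "rfc.center")),
        "center_off": Rule("lib.epi_center_offset", ("center_echo", "esp_g", "geom")),
        "tail_off": Rule("lib.epi_tail_offset", ("etl_g", "center_echo", "esp_g", "geom")),
    }, children=(
        ("rfc", f"{p}.rfc"), ("d2", f"{p}.d2"), ("epi_loop", f"{p}.epi_loop"),
        ("d3", f"{p}.d3"),
    ), is_loop=True))
    reg.add(_delay_bp(f"{p}.dtr", "tr_fill"))
    reg.add(Blueprint(f"{p}.set_loop", rules={
        "count": const(8),
        "counter": const("set"),
        "pld_ns": Rule("lib.ms_ns", ("pld_ms",)),
        "pld_ms": Rule("lib.s_to_ms", ("protocol.pld_s",)),
        "bs_times": Rule("lib.bs_times", ("protocol.bs_t1s", "pld_ms")),
        "bs_delays": Rule("lib.bs_delays", ("bs_times", "pld_ms", "inv1.dur")),
        "bs_d1": Rule("lib.item0", ("bs_delays",)),
        "bs_d2": Rule("lib.item1", ("bs_delays",)),
        "bs_d3": Rule("lib.item2", ("bs_delays",)),
        "n7": const(7),
        "label_total": Rule("lib.mul", ("n7", "label_loop.seg.dur")),
        "d1_fill": Rule("lib.fill", ("rfc_loop.esp_half", "exc.tail",
                                     "rfc_loop.rfc.center")),
        "train_total": Rule("lib.mul", ("n_rfc", "te_ns")),
        "tr_fill": Rule("lib.fill", ("tr_ns", "label_total", "db1.dur", "inv1.dur",
                                     "db2.dur", "inv2.dur", "db3.dur", "fatsat.dur",
                                     "exc.dur", "d1.dur", "train_total")),
    }, children=(
        ("label_loop", f"{p}.label_loop"),
        ("db1", f"{p}.db1"), ("inv1", f"{p}.inv1"), ("db2", f"{p}.db2"),
        ("inv2", f"{p}.inv2"), ("db3", f"{p}.db3"),
        ("fatsat", f"{p}.fatsat"), ("exc", f"{p}.exc"), ("d1", f"{p}.d1"),
        ("rfc_loop", f"{p}.rfc_loop"), ("dtr", f"{p}.dtr"),
    ), is_loop=True))
    reg.add(Blueprint(f"{p}.avg_loop", rules={
        "count": Rule("lib.int", ("protocol.averages",)),
        "counter": const("average"),
    }, children=(("set_loop", f"{p}.set_loop"),), is_loop=True))
    root_rules = _root_rules_cartesian()
    root_rules["etl_g"] = Rule("lib.table_len", ("table_phase",))
    root_rules["n_rfc"] = Rule("lib.table_len", ("table_part",))
    root_rules["center_echo"] = Rule("lib.center_echo", ("table_phase",))
    root_rules["esp_g"] = Rule("lib.epi_esp", ("geom",))
    root_rules["blip"] = Rule("lib.blip_step", ("table_phase",))
    reg.add(Blueprint(f"{p}.seq", rules=root_rules,
                      children=(("avg_loop", f"{p}.avg_loop"),)))
    return f"{p}.seq", reg


# -- 3D radial UTE ---------------------------------------------------------


def _ute_family() -> tuple[str, BlueprintRegistry]:
    p = "ute"
    reg = BlueprintRegistry()
    for kind, mode, prescan, deph in (
        ("calib", "calibration_planes", True, "protocol.calib_dephase_area"),
        ("img", "golden_3d", False, "zero_area"),
    ):
        loop = f"{kind}_loop"
        reg.add(_atomic(f"{p}.{kind}_spoke", {
            "mode": const(mode),
            "zero_area": const(0.0),
            "is_prescan": const(prescan),
            "dir": Rule("lib.spoke_dir", ("mode", f"{loop}.index", "protocol.calib_angles")),
            "raw": Rule("lib.ute_spoke_raw", ("dir", "protocol.matrix", "protocol.fov",
                                              "limits.all", "protocol.ute_te_ms",
                                              "protocol.flip", "protocol.radial_dwell_ns",
                                              f"{loop}.index", "is_prescan", deph)),
        }))
        reg.add(_delay_bp(f"{p}.{kind}_dtr", f"{kind}_tr_fill"))
        reg.add(Blueprint(f"{p}.{kind}_tr", rules={
            f"{kind}_tr_fill": Rule("lib.fill", ("tr_ns", "spoke.dur")),
        }, children=(("spoke", f"{p}.{kind}_spoke"), ("dtr", f"{p}.{kind}_dtr"))))
    reg.add(Blueprint(f"{p}.calib_loop", rules={
        "count": Rule("lib.calib_count", ("protocol.calib_angles",)),
    }, children=(("tr", f"{p}.calib_tr"),), is_loop=True))
    reg.add(Blueprint(f"{p}.img_loop", rules={
        "count": Rule("lib.int", ("protocol.spokes",)),
    }, children=(("tr", f"{p}.img_tr"),), is_loop=True))
    reg.add(Blueprint(f"{p}.seq", rules={
        "tr_ns": Rule("lib.ms_ns", ("protocol.tr",)),
    }, children=(("calib_loop", f"{p}.calib_loop"), ("img_loop", f"{p}.img_loop"))))
    return f"{p}.seq", reg


# -- STEAM / PRESS ---------------------------------------------------------


def _svs_family(kind: str) -> tuple[str, BlueprintRegistry]:
    p = kind
    reg = BlueprintRegistry()
    steam = kind == "steam"
    reg.add(_atomic(f"{p}.ws", {
        "raw": Rule("lib.water_sup_raw", ("limits.all", "protocol.water_suppression")),
    }))
    for i, (inst, flip_dep, use) in enumerate((
        ("p1", "protocol.flip", "excite"),
        ("p2", "protocol.refocus_flip", "excite" if steam else "refocus"),
        ("p3", "protocol.refocus_flip", "excite" if steam else "refocus"),
    )):
        reg.add(_atomic(f"{p}.{inst}", {
            "rf_shape": const("hann_sinc"),
            "rf_dur_ms": const(2.56),
            "rf_tbw": const(4.0),
            "rf_use": const(use),
            "rf_phase": const(0.0),
            "axis_idx": const(i),
            "pulse": Rule("lib.rf_pulse", ("rf_shape", "rf_dur_ms", flip_dep,
                                           "rf_tbw", "limits.all", "rf_phase", "rf_use")),
            "assembly": Rule("lib.voxel_pulse_assembly",
                             ("pulse", "protocol.voxel_mm", "limits.all", "axis_idx")),
            "raw": Rule("lib.item0", ("assembly",)),
            "center": Rule("lib.item1", ("assembly",)),
            "tail": Rule("lib.item2", ("assembly",)),
            "dur": Rule("lib.item3", ("assembly",)),
        }))
    reg.add(_delay_bp(f"{p}.da", "da_fill"))
    reg.add(_delay_bp(f"{p}.db", "db_fill"))
    reg.add(_delay_bp(f"{p}.dc", "dc_fill"))
    reg.add(_atomic(f"{p}.acq", {
        "raw": Rule("lib.svs_acquire_raw", ("protocol.svs_points", "protocol.svs_bw_hz",
                                            "rep_loop.index", "protocol.prescans")),
    }))
    reg.add(_delay_bp(f"{p}.dtr", "tr_fill"))
    rules: dict[str, Rule] = {
        "te_ns": Rule("lib.ms_ns", ("protocol.te",)),
        "tr_ns": Rule("lib.ms_ns", ("protocol.tr",)),
        "te_half": Rule("lib.half_ns", ("protocol.te",)),
        "tr_fill": Rule("lib.fill", ("tr_ns", "ws.dur", "p1.dur", "da.dur", "p2.dur",
                                     "db.dur", "p3.dur", "dc.dur", "acq.dur")),
    }
    if steam:
        rules["tm_ns"] = Rule("lib.ms_ns", ("protocol.mixing_time_ms",))
        rules["da_fill"] = Rule("lib.fill", ("te_half", "p1.tail", "p2.center"))
        rules["db_fill"] = Rule("lib.fill", ("tm_ns", "p2.tail", "p3.center"))
        rules["dc_fill"] = Rule("lib.fill", ("te_half", "p3.tail"))
    else:
        rules["te_quarter"] = Rule("lib.quarter_ns", ("protocol.te",))
        rules["da_fill"] = Rule("lib.fill", ("te_quarter", "p1.tail", "p2.center"))
        rules["db_fill"] = Rule("lib.fill", ("te_half", "p2.tail", "p3.center"))
        rules["dc_fill"] = Rule("lib.fill", ("te_quarter", "p3.tail"))
    reg.add(Blueprint(f"{p}.svs", rules=rules, children=(
        ("ws", f"{p}.ws"), ("p1", f"{p}.p1"), ("da", f"{p}.da"), ("p2", f"{p}.p2"),
        ("db", f"{p}.db"), ("p3", f"{p}.p3"), ("dc", f"{p}.dc"),
        ("acq", f"{p}.acq"), ("dtr", f"{p}.dtr"),
    )))
    reg.add(Blueprint(f"{p}.rep_loop", rules={
        "count": Rule("lib.sum", ("protocol.prescans", "protocol.averages")),
        "counter": const("repetition"),
    }, children=(("svs", f"{p}.svs"),), is_loop=True))
    reg.add(Blueprint(f"{p}.seq", children=(("rep_loop", f"{p}.rep_loop"),)))
    return f"{p}.seq", reg


# ==========================================================================
# Public API
# ==========================================================================

_FAMILY_EXTRAS: dict[str, dict[str, Any]] = {
    "flash": {},
    "bssfp": {},
    "mprage": {"readout_tr_ms": 10.0},
    "rare": {},
    "flair": {},
    "se_epi_diffusion": {"b_values": (0.0, 300.0, 600.0), "diffusion_lobe_ms": 18.0},
    "grase_pcasl": {"subbolus_s": 0.4, "pld_s": 0.6, "bs_t1s": (700.0, 1400.0)},
    "radial_ute": {"spokes": 20000, "calib_angles": 180, "ute_te_ms": 0.1,
                   "radial_dwell_ns": 5_000, "calib_dephase_area": 2.0},
    "steam": {"svs_points": 2048, "svs_bw_hz": 2000.0, "mixing_time_ms": 10.0,
              "voxel_mm": (25.0, 25.0, 25.0), "water_suppression": True},
    "press": {"svs_points": 2048, "svs_bw_hz": 2000.0,
              "voxel_mm": (25.0, 25.0, 25.0), "water_suppression": True},
}


def sequence_definition(family: str) -> tuple[str, BlueprintRegistry]:
    """Blueprint registry + root name for a sequence family."""
    if family == "flash":
        return _gre_family("flash", balanced=False)
    if family == "bssfp":
        return _gre_family("bssfp", balanced=True)
    if family == "mprage":
        return _mprage_family()
    if family == "rare":
        return _rare_like("rare", with_inversion=False, n_concat=1)
    if family == "flair":
        return _rare_like("flair", with_inversion=True, n_concat=2)
    if family == "se_epi_diffusion":
        return _epi_family()
    if family == "grase_pcasl":
        return _grase_family()
    if family == "radial_ute":
        return _ute_family()
    if family in ("steam", "press"):
        return _svs_family(family)
    raise ValueError(f"unknown sequence family {family!r}; choose from {FAMILIES}")


def build_sequence(
    family: str,
    protocol: Protocol,
    limits: HardwareLimits = DEFAULT_LIMITS,
) -> tuple[ElementTree, ParameterGraph]:
    """Assemble one of the library families for the given protocol."""
    root, reg = sequence_definition(family)
    proto = _with_extras(protocol, _FAMILY_EXTRAS[family])
    return assemble(root, proto, reg, limits)


def stream_eager(tree: ElementTree, graph: ParameterGraph) -> list[ExecutionBlock]:
    """Full eager traversal: built blocks with absolute start times."""
    out: list[ExecutionBlock] = []
    cursor = 0

    def on_atomic(el):
        nonlocal cursor
        blk = build_block(el, graph)
        out.append(replace(blk, start=cursor))
        cursor += blk.duration

    tree.traverse(graph, on_atomic)
    return out


def scan_duration(tree: ElementTree, graph: ParameterGraph) -> float:
    """Total sequence duration in seconds (sum of all block durations)."""
    total = 0

    def on_atomic(el):
        nonlocal total
        total += build_block(el, graph).duration

    tree.traverse(graph, on_atomic)
    return total / S


def realized_te(blocks: list[ExecutionBlock], mode: str = "first_adc",
                center_line: int | None = None) -> list[int]:
    """Realized echo times (ns) per excitation.

    ``first_adc``: RF center → first following ADC center (FLASH, RARE first
    echo).  ``center_line``: RF center → the ADC sampling the line closest
    to ``center_line`` (EPI, GRASE; pass the matrix center, default the
    midpoint of the observed line range).
    """
    tes = []
    current_exc: int | None = None
    candidates: list[tuple[int, int]] = []  # (adc_center_abs, line)
    if center_line is None:
        all_lines = [b.adc.header.line for b in blocks if b.adc is not None]
        if all_lines:
            center_line = (max(all_lines) + min(all_lines) + 1) // 2

    def flush():
        if current_exc is None or not candidates:
            return
        if mode == "first_adc":
            tes.append(candidates[0][0] - current_exc)
        else:
            best = min(candidates, key=lambda c: abs(c[1] - center_line))
            tes.append(best[0] - current_exc)

    for b in blocks:
        if b.rf is not None and b.rf.use == "excite" and b.rf.flip_angle_deg() > 1e-6:
            flush()
            current_exc = b.start + b.rf.center
            candidates = []
        if b.adc is not None and current_exc is not None:
            candidates.append((b.start + b.adc.center, b.adc.header.line))
    flush()
    return tes


def table1_protocol(family: str) -> Protocol:
    """Acquisition protocols of the in vivo comparison study, as packaged
    fixtures (times ms, FOV mm)."""
    if family == "flash":
        return Protocol(tr=10, te=5, flip=10, fov=(256, 192, 160),
                        matrix=(256, 192, 160), partial_fourier=(1.0, 0.75),
                        acceleration=(2, 1), slice_thickness=160.0)
    if family == "bssfp":
        return Protocol(tr=5, te=2.5, flip=10, fov=(256, 192, 160),
                        matrix=(256, 192, 160), partial_fourier=(1.0, 0.75),
                        acceleration=(2, 1), prescans=10, slice_thickness=160.0)
    if family == "mprage":
        return Protocol(tr=2200, te=2.9, ti=900, flip=8, fov=(256, 192, 160),
                        matrix=(256, 192, 160), partial_fourier=(1.0, 0.75),
                        acceleration=(2, 1), slice_thickness=160.0)
    if family == "rare":
        return Protocol(tr=6000, te=48, flip=90, refocus_flip=150,
                        fov=(256, 192, 160), matrix=(256, 192, 32),
                        acceleration=(2, 1), train_length=(8, 1),
                        slice_thickness=4.0)
    if family == "flair":
        return Protocol(tr=9000, te=84, ti=2600, flip=90, refocus_flip=150,
                        fov=(256, 192, 160), matrix=(256, 192, 32),
                        acceleration=(2, 1), train_length=(12, 1),
                        slice_thickness=4.0)
    if family == "se_epi_diffusion":
        return Protocol(tr=8000, te=66.6, flip=90, refocus_flip=180,
                        fov=(240, 180, 162), matrix=(80, 60, 54),
                        acceleration=(2, 1), train_length=(30, 1),
                        slice_thickness=3.0,
                        extras={"ref_lines": 0, "dwell_ns": 5_000})
    if family == "grase_pcasl":
        return Protocol(tr=4000, te=17.9, flip=90, refocus_flip=120,
                        fov=(256, 192, 160), matrix=(64, 48, 32),
                        partial_fourier=(1.0, 0.75), acceleration=(2, 2),
                        train_length=(24, 12), averages=4, prescans=1,
                        slice_thickness=160.0, extras={"ref_lines": 0})
    if family == "radial_ute":
        return Protocol(tr=6, te=0.1, flip=10, fov=(256, 256, 256),
                        matrix=(192, 192, 192), slice_thickness=256.0,
                        extras={"spokes": 20000, "calib_angles": 180})
    if family == "steam":
        return Protocol(tr=2000, te=20, flip=90, refocus_flip=90,
                        fov=(25, 25, 25), matrix=(1, 1, 1), averages=96,
                        prescans=2, slice_thickness=25.0)
    if family == "press":
        return Protocol(tr=2000, te=32, flip=90, refocus_flip=180,
                        fov=(25, 25, 25), matrix=(1, 1, 1), averages=96,
                        prescans=2, slice_thickness=25.0)
    raise ValueError(f"unknown family {family!r}")
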