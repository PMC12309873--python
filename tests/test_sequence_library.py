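"""Sequence families: durations, encoding coverage, timing, ASL math."""

import numpy as np
import pytest

from mrforge._units import GRAD_RASTER_NS
from mrforge.sequence_library import (
    ASLSpec,
    FAMILIES,
    asl_inflow_times,
    build_sequence,
    hadamard_label_train,
    realized_te,
    scan_duration,
    stream_eager,
    table1_protocol,
    walsh_hadamard_8,
)
from mrforge.sequence_model import check_protocol

from conftest import TOY_PROTOCOLS

IMAGING = [f for f in FAMILIES if f not in ("steam", "press", "radial_ute")]


class TestWalshHadamard:
    def test_orthogonality(self):
        h = walsh_hadamard_8()
        assert np.array_equal(h @ h.T, 8 * np.eye(8))

    def test_first_row_all_plus_one(self):
        assert (walsh_hadamard_8()[0] == 1).all()

    def test_sequency_order_strictly_increasing(self):
        h = walsh_hadamard_8()
        changes = [(np.diff(row) != 0).sum() for row in h]
        assert changes == sorted(changes) and len(set(changes)) == 8

    def test_balanced_label_control_counts(self):
        h = walsh_hadamard_8()
        for row in h[1:]:
            segs = row[1:]
            assert (segs == 1).sum() in (3, 4)  # near-balanced among 7 subboli


class TestLabelTrain:
    def test_row_one_all_label_total_duration(self):
        spec = ASLSpec()
        segs = hadamard_label_train(spec, 1)
        assert len(segs) == 7
        assert all(s.kind == "label" for s in segs)
        assert segs[-1].start_s + segs[-1].duration_s == pytest.approx(2.8)

    def test_segment_start_times(self):
        segs = hadamard_label_train(ASLSpec(), 5)
        for k, s in enumerate(segs):
            assert s.start_s == pytest.approx(k * 0.4)

    def test_signs_follow_matrix_row(self):
        spec = ASLSpec()
        h = spec.encoding
        for i in range(1, 9):
            segs = hadamard_label_train(spec, i)
            kinds = ["label" if v > 0 else "control" for v in h[i - 1, 1:]]
            assert [s.kind for s in segs] == kinds


class TestInflowTimes:
    def test_study_values(self):
        times = asl_inflow_times(ASLSpec())
        assert sorted(times) == pytest.approx([1.0, 1.4, 1.8, 2.2, 2.6, 3.0, 3.4])

    def test_single_subbolus_equivalent(self):
        spec = ASLSpec(subbolus_duration_s=0.5, post_labeling_delay_s=1.0)
        # earliest subbolus of 7 has the longest inflow
        assert asl_inflow_times(spec)[0] == pytest.approx(1.0 + 7 * 0.5)

    def test_consecutive_spacing_is_subbolus_duration(self):
        times = asl_inflow_times(ASLSpec())
        diffs = np.diff(sorted(times))
        assert np.allclose(diffs, 0.4)


class TestScanDuration:
    def test_steam_matches_printed_scan_time(self):
        tree, graph = build_sequence("steam", table1_protocol("steam"))
        assert scan_duration(tree, graph) == pytest.approx(196.0)  # 3:16

    def test_press_matches_printed_scan_time(self):
        tree, graph = build_sequence("press", table1_protocol("press"))
        assert scan_duration(tree, graph) == pytest.approx(196.0)

    def test_zero_repetitions_zero_duration(self):
        proto = table1_protocol("steam")
        proto.averages = 0
        proto.prescans = 0
        tree, graph = build_sequence("steam", proto)
        assert scan_duration(tree, graph) == 0.0


class TestTraversalCensus:
    def test_ute_excitation_count(self):
        proto = TOY_PROTOCOLS["radial_ute"]
        tree, graph = build_sequence("radial_ute", proto)
        # one spoke atomic per excitation: 3*6 calibration + 50 imaging
        spokes = []
        tree.traverse(graph, lambda el: spokes.append(el.path)
                      if "spoke" in el.path else None)
        assert len(spokes) == 3 * 6 + 50

    def test_svs_repetition_count(self):
        proto = table1_protocol("steam")
        tree, graph = build_sequence("steam", proto)
        acqs = []
        tree.traverse(graph, lambda el: acqs.append(el.path)
                      if el.path.endswith("acq") else None)
        assert len(acqs) == 96 + 2  # averages + prescans

    def test_flash_toy_readout_headers_distinct(self):
        from mrforge.sequence_model import Protocol

        proto = Protocol(tr=10, te=5, matrix=(8, 8, 8), fov=(256, 256, 64),
                         slice_thickness=64.0)
        blocks = stream_eager(*build_sequence("flash", proto))
        adcs = [b.adc.header for b in blocks if b.adc is not None]
        assert len(adcs) == 64
        assert len({(h.line, h.partition) for h in adcs}) == 64


@pytest.mark.parametrize("family", IMAGING)
def test_kspace_coverage_complete(family):
    """Every (line, partition/slice, average, set, contrast) combination
    demanded by the encoding tables appears exactly once among ADC headers."""
    blocks = stream_eager(*build_sequence(family, TOY_PROTOCOLS[family]))
    keys = [(b.adc.header.line, b.adc.header.partition, b.adc.header.slice,
             b.adc.header.average, b.adc.header.set, b.adc.header.contrast)
            for b in blocks if b.adc is not None]
    assert keys, family
    assert len(keys) == len(set(keys))


@pytest.mark.parametrize("family", IMAGING)
def test_toy_protocols_pass_validity_check(family):
    tree, graph = build_sequence(family, TOY_PROTOCOLS[family])
    report = check_protocol(tree, graph)
    assert report.ok, [v.message for v in report]


@pytest.mark.parametrize("family,mode", [
    ("flash", "first_adc"),
    ("rare", "first_adc"),
    ("se_epi_diffusion", "center_line"),
    ("grase_pcasl", "center_line"),
])
def test_realized_te_matches_protocol(family, mode):
    """RF center to echo center equals the protocol TE within one gradient
    raster."""
    proto = TOY_PROTOCOLS[family]
    blocks = stream_eager(*build_sequence(family, proto))
    center = proto.matrix[1] // 2
    tes = realized_te(blocks, mode, center_line=center)
    te_ns = int(proto.te * 1e6)
    assert tes
    assert all(abs(t - te_ns) <= GRAD_RASTER_NS for t in tes)


def test_bssfp_phase_alternation():
    blocks = stream_eager(*build_sequence("bssfp", TOY_PROTOCOLS["bssfp"]))
    phases = [b.rf.phase_offset for b in blocks
              if b.rf is not None and b.rf.use == "excite"]
    diffs = np.abs(np.diff(phases))
    assert np.allclose(diffs, np.pi)


def test_bssfp_ramp_preparation_flips_increase():
    blocks = stream_eager(*build_sequence("bssfp", TOY_PROTOCOLS["bssfp"]))
    prep = [b.rf.flip_angle_deg() for b in blocks[:20]
            if b.rf is not None and b.adc is None][:10]
    assert len(prep) == 10
    assert all(a < b for a, b in zip(prep, prep[1:]))
    assert prep[-1] < TOY_PROTOCOLS["bssfp"].flip


def test_diffusion_volume_schedule():
    blocks = stream_eager(*build_sequence("se_epi_diffusion",
                                          TOY_PROTOCOLS["se_epi_diffusion"]))
    contrasts = sorted({b.adc.header.contrast for b in blocks if b.adc})
    assert contrasts == list(range(7))  # b=0 plus 2 b-values x 3 axes


def test_grase_interleaves_refocusing_with_gradient_echoes():
    proto = TOY_PROTOCOLS["grase_pcasl"]
    blocks = stream_eager(*build_sequence("grase_pcasl", proto))
    # between two refocusing pulses there are exactly train_phase readouts
    per_set = []
    count = None
    for b in blocks:
        if b.rf is not None and b.rf.use == "refocus":
            if count is not None:
                per_set.append(count)
            count = 0
        elif b.adc is not None and count is not None:
            count += 1
    assert set(per_set) == {proto.matrix[1]}  # full toy table per refocus


def test_ute_adc_starts_on_gradient_ramp():
    blocks = stream_eager(*build_sequence("radial_ute", TOY_PROTOCOLS["radial_ute"]))
    imaging = [b for b in blocks if b.adc is not None
               and "is_prescan" not in b.adc.header.flags]
    b = imaging[0]
    ro = [g for g in b.gradients if g.rise > 0][0]
    assert b.adc.start == ro.start  # ramp sampling from the very first sample


def test_missing_family_extras_raise():
    from mrforge.sequence_model import Protocol

    proto = Protocol(tr=6, te=0.1, extras={"spokes": "not_an_int"})
    with pytest.raises(Exception):
        tree, graph = build_sequence("radial_ute", proto)
        tree.count_atomic_visits(graph)
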