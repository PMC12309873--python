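# mrforge

A framework for building real-time-capable MR pulse sequences as
declarative, reusable modules — and for validating them end to end on a
virtual scanner, without touching vendor hardware.

MR sequence development is usually locked to one manufacturer's toolchain:
pulse definitions, timing conventions and reconstruction hooks all differ
between scanners, which makes sequences hard to share and multicenter
studies hard to reproduce. `mrforge` targets the sequence *logic* instead
of a frozen event list. A sequence is declared as **blueprints** — modules
carrying physics rules as pure functions — and assembled into an element
hierarchy (modules / loops / atomics) plus a **parameter graph**: a DAG of
lazily evaluated, cached parameter rules,

```
value(p) = rule_p(value(dep_1), …, value(dep_k)),   cache valid until an input changes
```

so only essential calculations ever run, and a protocol or real-time
feedback change invalidates exactly the affected closure. Atomics compile
to a generalized hardware representation (RF, gradient and ADC events
with ISMRMRD-style acquisition headers), streamed chronologically in
bounded time buffers (30–300 ms windows) with sync points where pending
feedback — e.g. an updated imaging-plane position from prospective motion
correction — is applied atomically. Sequences interchange with the open
Pulseq text format in both directions, and a virtual scanner (isochromat
Bloch simulation, k-space trajectories, Kaiser–Bessel gridding
reconstruction, gradient-delay calibration, ADC fitting, Hadamard-encoded
ASL decoding, closed-loop motion correction) closes the loop where a
physical scanner would sit.

Who it is for: sequence developers who want hardware-agnostic, testable
sequence logic; methods researchers who need a deterministic virtual
scanner to validate acquisition/reconstruction chains; anyone needing
Pulseq import/export with acquisition-header sidecars.

## Worked example

Build the single-voxel STEAM spectroscopy protocol (TR 2 s, 96 averages,
2 prescans, 2048 points at 2 kHz bandwidth) and inspect it:

```
$ mrforge describe steam
family:       steam
atomics:      9 kinds, 882 visits
scan time:    3:16.0 (196.000 s)
protocol:     valid (streamable)
```

The scan time is derived, not configured: (2 prescans + 96 averages) ×
TR 2.0 s = 196 s, printed as 3:16. The same derivations are available as
library calls:

```python
>>> from mrforge import build_sequence, table1_protocol, scan_duration
>>> tree, graph = build_sequence("steam", table1_protocol("steam"))
>>> scan_duration(tree, graph)
196.0
```

Hadamard-8 time-encoded pCASL: the Walsh-ordered encoding matrix and the
seven subbolus inflow times that a 0.4 s subbolus / 0.6 s post-labeling
delay protocol produces (earliest-labeled subbolus first):

```python
>>> from mrforge import walsh_hadamard_8, asl_inflow_times
>>> from mrforge.sequence_library import ASLSpec
>>> walsh_hadamard_8()[:2]
array([[ 1,  1,  1,  1,  1,  1,  1,  1],
       [ 1,  1,  1,  1, -1, -1, -1, -1]])
>>> [round(t, 1) for t in asl_inflow_times(ASLSpec())]
[3.4, 3.0, 2.6, 2.2, 1.8, 1.4, 1.0]
```

Seven inflow times spanning 1.0–3.4 s: decoding eight encoded volumes
with the matrix above yields one perfusion-weighted image per inflow
time.

The closed-loop motion-correction demonstration acquires volumes of a
phantom under a scripted drift, registers each to the first, and sends
the geometry update through the feedback endpoint so subsequent volumes
are acquired in the corrected frame:

```
$ mrforge demo-moco --volumes 6
volume  uncorrected-MVD  corrected-MVD  [mm]
     0            0.000          0.000
     1            0.507          0.507
     2            1.013          0.507
     3            1.520          0.507
     4            2.027          0.507
     5            2.534          0.507
mean              1.267          0.422
```

Uncorrected, the mean voxel displacement (MVD) grows with the drift;
corrected, it plateaus at the one-volume feedback latency.

Other entry points: `mrforge build` (sequence bundle JSON),
`mrforge stream` (buffered block dump), `mrforge export-pulseq` /
`import-pulseq`, `mrforge simulate` / `recon` (Bloch simulation to raw
HDF5, FFT reconstruction to NIfTI).

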