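"""Time-buffered block streaming with feedback sync points.

Hardware events are computed in strict chronological order and delivered
buffer by buffer (default window 100 ms of sequence time, valid 30–300 ms).
At each sync point — every buffer boundary, plus optionally right before
each slice-excitation atomic — pending feedback parameter updates are
applied atomically to the parameter graph, so every block generated after
the sync point reflects them while blocks already delivered are never
mutated (append-only contract; an in-flight buffer is never cancelled).

The runtime is clocked by sequence time, keeping tests deterministic; a
wall-clock governor for live demos is deliberately out of scope of the
streaming contract.  The feedback service speaks a line-delimited JSON
message protocol ``{"op": ..., "name": ..., "value": ...}``; an in-process
endpoint object is the reference implementation and a stdlib TCP server
exposes the same handler on a socket for external feedback sources.
"""

from __future__ import annotations

import json
import socket
import socketserver
import threading
import time as _time
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterator

from ._units import MS
from .hardware_events import ExecutionBlock, build_block
from .sequence_model import Element, ElementTree, ParameterGraph

__all__ = [
    "FeedbackService",
    "FeedbackState",
    "RuntimeConfig",
    "TCPFeedbackServer",
    "apply_feedback",
    "send_message",
    "stream_blocks",
    "stream_buffers",
]


@dataclass(frozen=True)
class RuntimeConfig:
    """Streaming configuration.

    ``buffer_window_ms`` is the execution-window length; values outside the
    30–300 ms range require ``allow_any_window`` (toy sequences in tests
    stay inside it).  ``sync_policy``: ``every_buffer`` or
    ``at_marked_atomics`` (buffer boundaries plus before every excitation
    atomic).
    """

    buffer_window_ms: float = 100.0
    sync_policy: str = "every_buffer"
    seed: int = 0
    allow_any_window: bool = False

    def __post_init__(self) -> None:
        if not self.allow_any_window and not 30.0 <= self.buffer_window_ms <= 300.0:
            raise ValueError("buffer window must be within 30-300 ms")
        if self.sync_policy not in ("every_buffer", "at_marked_atomics"):
            raise ValueError(f"unknown sync policy {self.sync_policy!r}")

    @property
    def window_ns(self) -> int:
        return int(round(self.buffer_window_ms * MS))


@dataclass
class FeedbackState:
    """Named parameters exposed for real-time update.

    ``exposed`` maps a public name to the graph node it drives.  ``set``
    stores a pending value immediately (acknowledged, versioned); the value
    is applied to the graph only at the next sync point.  Applied versions
    never decrease and updates are atomic per sync point (last writer wins
    between sync points).
    """

    exposed: dict[str, str] = field(default_factory=dict)  # name -> graph node id
    values: dict[str, Any] = field(default_factory=dict)
    versions: dict[str, int] = field(default_factory=dict)
    applied_versions: dict[str, int] = field(default_factory=dict)
    pending: dict[str, Any] = field(default_factory=dict)
    log: list[tuple[float, str, Any]] = field(default_factory=list)
    _lock: threading.Lock = field(default_factory=threading.Lock, repr=False)

    def expose(self, name: str, node_id: str, initial: Any = None) -> None:
        self.exposed[name] = node_id
        self.values.setdefault(name, initial)
        self.versions.setdefault(name, 0)
        self.applied_versions.setdefault(name, 0)

    def set(self, name: str, value: Any, timestamp: float | None = None) -> int:
        """Record a pending update; returns the new version."""
        with self._lock:
            if name not in self.exposed:
                self.log.append((timestamp or 0.0, name, "rejected: unknown parameter"))
                raise KeyError(f"unknown exposed parameter {name!r}")
            self.versions[name] += 1
            self.pending[name] = value
            self.log.append((timestamp or 0.0, name, value))
            return self.versions[name]

    def get(self, name: str) -> dict[str, Any]:
        if name not in self.exposed:
            raise KeyError(f"unknown exposed parameter {name!r}")
        return {
            "name": name,
            "value": self.values[name],
            "version": self.versions[name],
            "applied_version": self.applied_versions[name],
            "pending": self.pending.get(name, None),
        }

    def list(self) -> list[str]:
        return sorted(self.exposed)


def apply_feedback(state: FeedbackState, graph: ParameterGraph) -> set[str]:
    """Apply all pending feedback values at a sync point.

    Returns the set of updated parameter names.  With no pending values the
    graph is untouched (zero invalidations), so a silent feedback source
    leaves the sequence execution bit-identical.
    """
    with state._lock:
        pending = dict(state.pending)
        state.pending.clear()
    updated: set[str] = set()
    for name, value in pending.items():
        graph.update(state.exposed[name], value)
        state.values[name] = value
        assert state.versions[name] >= state.applied_versions[name]
        state.applied_versions[name] = state.versions[name]
        updated.add(name)
    return updated


# --------------------------------------------------------------------------
# Streaming
# --------------------------------------------------------------------------


def _iter_atomics(tree: ElementTree, graph: ParameterGraph) -> Iterator[Element]:
    """Lazy chronological traversal (generator form of ``ElementTree.traverse``)."""

    def walk(el: Element) -> Iterator[Element]:
        if el.kind == "loop":
            count = graph.evaluate(el.count_node)
            for i in range(int(count)):
                graph.update(el.index_node, i)
                for child in el.children:
                    yield from walk(child)
        else:
            if el.kind == "atomic":
                yield el
            for child in el.children:
                yield from walk(child)

    yield from walk(tree.root)


def stream_buffers(
    tree: ElementTree,
    graph: ParameterGraph,
    config: RuntimeConfig = RuntimeConfig(),
    feedback: FeedbackState | None = None,
    on_sync: Callable[[int], None] | None = None,
) -> Iterator[list[ExecutionBlock]]:
    """Stream execution blocks buffer by buffer in chronological order.

    Each yielded buffer covers one execution window of sequence time; a
    block longer than the window is delivered whole in one buffer (never
    split).  Pending feedback is applied at every buffer boundary (and,
    under ``at_marked_atomics``, additionally right before excitation
    atomics).  Only the current buffer plus one look-ahead block are ever
    materialized, so memory stays bounded by ~2 windows regardless of
    sequence length.
    """
    window = config.window_ns
    cursor = 0  # absolute sequence time of the next block
    buffer_end = window
    buf: list[ExecutionBlock] = []
    sync_count = 0

    def sync() -> None:
        nonlocal sync_count
        if feedback is not None:
            apply_feedback(feedback, graph)
        if on_sync is not None:
            on_sync(sync_count)
        sync_count += 1

    sync()  # initial sync before the first buffer is computed
    mark = config.sync_policy == "at_marked_atomics"
    for el in _iter_atomics(tree, graph):
        while cursor >= buffer_end:
            yield buf
            buf = []
            buffer_end += window
            sync()
        if mark and feedback is not None and _is_excitation(el, graph):
            # extra sync point right before a slice excitation
            sync()
        block = build_block(el, graph)
        buf.append(replace(block, start=cursor))
        cursor += block.duration
    if buf:
        yield buf


def _is_excitation(el: Element, graph: ParameterGraph) -> bool:
    if "rf_use" not in el.nodes:
        return False
    try:
        return graph.evaluate(el.nodes["rf_use"]) == "excite"
    except Exception:  # noqa: BLE001
        return False


def stream_blocks(
    tree: ElementTree,
    graph: ParameterGraph,
    config: RuntimeConfig = RuntimeConfig(),
    feedback: FeedbackState | None = None,
) -> list[ExecutionBlock]:
    """Concatenated buffered stream (equals the eager traversal when no
    feedback arrives)."""
    out: list[ExecutionBlock] = []
    for buf in stream_buffers(tree, graph, config, feedback):
        out.extend(buf)
    return out


# --------------------------------------------------------------------------
# Feedback service
# --------------------------------------------------------------------------


class FeedbackService:
    """JSON message endpoint over a :class:`FeedbackState`.

    Messages are JSON objects: ``{"op": "set", "name": ..., "value": ...,
    "timestamp": ...}``, ``{"op": "get", "name": ...}``, ``{"op": "list"}``.
    ``set`` is acknowledged immediately and applied at the next sync point;
    malformed messages get an error reply and change no state.
    """

    def __init__(self, state: FeedbackState):
        self.state = state

    def handle_message(self, text: str) -> str:
        try:
            msg = json.loads(text)
            op = msg["op"]
            if op == "set":
                version = self.state.set(msg["name"], msg["value"], msg.get("timestamp"))
                reply = {"ok": True, "op": "set", "name": msg["name"], "version": version}
            elif op == "get":
                reply = {"ok": True, "op": "get", **self.state.get(msg["name"])}
            elif op == "list":
                reply = {"ok": True, "op": "list", "names": self.state.list()}
            else:
                reply = {"ok": False, "error": f"unknown op {op!r}"}
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
            reply = {"ok": False, "error": str(exc)}
        return json.dumps(reply)


class TCPFeedbackServer:
    """Line-delimited JSON feedback endpoint on a TCP socket.

    The reference transport in the deployed system is a WebSocket; the
    message protocol here is transport-agnostic and this stdlib server
    provides the same contract for external devices on the network.
    """

    def __init__(self, state: FeedbackState, host: str = "127.0.0.1", port: int = 0):
        service = FeedbackService(state)

        class Handler(socketserver.StreamRequestHandler):
            def handle(self) -> None:
                for line in self.rfile:
                    line = line.strip()
                    if not line:
                        continue
                    self.wfile.write(service.handle_message(line.decode()).encode() + b"\n")
                    self.wfile.flush()

        self._server = socketserver.ThreadingTCPServer((host, port), Handler)
        self._server.daemon_threads = True
        self.address = self._server.server_address
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)

    def start(self) -> None:
        self._thread.start()

    def stop(self) -> None:
        self._server.shutdown()
        self._server.server_close()

    def __enter__(self) -> "TCPFeedbackServer":
        self.start()
        return self

    def __exit__(self, *exc) -> None:
        self.stop()


def send_message(address: tuple[str, int], message: dict[str, Any], timeout: float = 5.0) -> dict[str, Any]:
    """One-shot client: send one JSON message, return the parsed reply."""
    with socket.create_connection(address, timeout=timeout) as sock:
        sock.sendall((json.dumps(message) + "\n").encode())
        data = b""
        while not data.endswith(b"\n"):
            chunk = sock.recv(4096)
            if not chunk:
                break
            data += chunk
    return json.loads(data.decode())
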