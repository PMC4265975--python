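"""JSON-over-TCP session interface to a :class:`TreatmentEngine`.

The device is controlled through a client-server model: the server owns
the engine, each client session is handled by its own thread, and requests
are newline-delimited JSON objects::

    {"op": "execute"|"modify"|"query"|"advance"|"ping", "payload": ...}

answered with ``{"ok": bool, "result": ..., "error": str|null}``.  Engine
access is serialized by a lock, so one session's request never corrupts
another's; a status query is answered between requests and never blocks on
a long-running operation (all engine calls return immediately — time only
advances through the ``advance`` op or an in-process driver).

Malformed messages yield an error response and leave the session open.
"""

from __future__ import annotations

import json
import socket
import socketserver
import threading
from typing import Any, Optional

from .engine import TreatmentEngine
from .protocols import (
    Modification,
    ProtocolError,
    TreatmentProtocol,
    deserialize,
    serialize,
)


class _Handler(socketserver.StreamRequestHandler):
    def handle(self) -> None:
        while True:
            line = self.rfile.readline()
            if not line:
                break
            try:
                response = self.server.dispatch(line.decode("utf-8"))
            except Exception as exc:  # pragma: no cover - defensive
                response = {"ok": False, "result": None, "error": str(exc)}
            self.wfile.write((json.dumps(response) + "\n").encode("utf-8"))
            self.wfile.flush()


class EngineServer(socketserver.ThreadingTCPServer):
    """Serves one engine to any number of concurrent client sessions."""

    allow_reuse_address = True
    daemon_threads = True

    def __init__(self, address: tuple[str, int] = ("127.0.0.1", 0),
                 engine: Optional[TreatmentEngine] = None) -> None:
        super().__init__(address, _Handler)
        self.engine = engine if engine is not None else TreatmentEngine()
        self._lock = threading.Lock()
        self._thread: Optional[threading.Thread] = None

    @property
    def endpoint(self) -> tuple[str, int]:
        return self.server_address[:2]

    def start(self) -> "EngineServer":
        self._thread = threading.Thread(target=self.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self.shutdown()
        self.server_close()

    def dispatch(self, line: str) -> dict[str, Any]:
        try:
            message = json.loads(line)
            op = message["op"]
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            return {"ok": False, "result": None, "error": f"malformed request: {exc}"}
        payload = message.get("payload")
        try:
            with self._lock:
                result = self._apply(op, payload)
        except (ProtocolError, ValueError, RuntimeError) as exc:
            return {"ok": False, "result": None, "error": str(exc)}
        return {"ok": True, "result": result, "error": None}

    def _apply(self, op: str, payload: Any) -> Any:
        if op == "ping":
            return "pong"
        if op == "query":
            return self.engine.query_status().to_json_dict()
        if op == "advance":
            events = self.engine.advance_clock(float(payload["dt_s"]))
            return {"n_events": len(events), "clock_s": self.engine.clock_s}
        if op in ("execute", "load"):
            obj = deserialize(json.dumps(payload) if isinstance(payload, dict)
                              else str(payload))
            if not isinstance(obj, TreatmentProtocol):
                raise ProtocolError("execute expects a protocol document")
            return {"executing": self.engine.execute_protocol(obj)}
        if op == "modify":
            obj = deserialize(json.dumps(payload) if isinstance(payload, dict)
                              else str(payload))
            if not isinstance(obj, Modification):
                raise ProtocolError("modify expects a modification document")
            return self.engine.execute_modification(obj)
        raise ValueError(f"unknown op {op!r}")


def serve(endpoint: tuple[str, int] = ("127.0.0.1", 0),
          engine: Optional[TreatmentEngine] = None) -> EngineServer:
    """Start a server thread bound to ``endpoint``; returns the server
    (its ``endpoint`` property carries the bound port)."""
    return EngineServer(endpoint, engine).start()


class EngineClient:
    """One client session: a socket speaking the newline-JSON protocol."""

    def __init__(self, endpoint: tuple[str, int], timeout_s: float = 10.0) -> None:
        self._sock = socket.create_connection(endpoint, timeout=timeout_s)
        self._file = self._sock.makefile("rwb")

    def request(self, op: str, payload: Any = None) -> dict[str, Any]:
        self._file.write((json.dumps({"op": op, "payload": payload}) + "\n")
                         .encode("utf-8"))
        self._file.flush()
        line = self._file.readline()
        if not line:
            raise ConnectionError("server closed the session")
        return json.loads(line.decode("utf-8"))

    def raw_request(self, text: str) -> dict[str, Any]:
        """Send raw text (for exercising malformed-message handling)."""
        self._file.write((text.rstrip("\n") + "\n").encode("utf-8"))
        self._file.flush()
        return json.loads(self._file.readline().decode("utf-8"))

    def execute(self, protocol: TreatmentProtocol) -> dict[str, Any]:
        return self._checked("execute", json.loads(serialize(protocol)))

    def modify(self, modification: Modification) -> dict[str, Any]:
        return self._checked("modify", json.loads(serialize(modification)))

    def query(self) -> dict[str, Any]:
        return self._checked("query")

    def advance(self, dt_s: float) -> dict[str, Any]:
        return self._checked("advance", {"dt_s": dt_s})

    def _checked(self, op: str, payload: Any = None) -> Any:
        response = self.request(op, payload)
        if not response["ok"]:
            raise RuntimeError(response["error"])
        return response["result"]

    def close(self) -> None:
        try:
            self._file.close()
        finally:
            self._sock.close()

    def __enter__(self) -> "EngineClient":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def connect(endpoint: tuple[str, int], timeout_s: float = 10.0) -> EngineClient:
    """Open a client session to a running server."""
    return EngineClient(endpoint, timeout_s=timeout_s)
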