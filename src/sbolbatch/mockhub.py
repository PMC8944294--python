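"""A local, in-process SynBioHub-compatible server emulator.

Implements just enough of the repository HTTP contract — login, multipart
submit into a collection, member listing, field edits, attachment upload — to
exercise every online operation offline. The emulator records every request,
supports scripted fault injection (dropped connections or 5xx responses) to
test retry behavior, and rejects submissions that still carry repository
bookkeeping properties, mimicking the re-upload failure that the CLEAN
operation exists to fix.

Intended for tests and the end-to-end demo; state lives in memory.
"""

from __future__ import annotations

import json
import re
import threading
import urllib.parse
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .sbolio import SBOL2_NS, SYNBIOHUB_TERMS_NS

__all__ = ["MockSynBioHub", "RecordedRequest"]


@dataclass
class RecordedRequest:
    method: str
    path: str
    fields: dict[str, str] = field(default_factory=dict)
    files: list[tuple[str, str, bytes]] = field(default_factory=list)
    headers: dict[str, str] = field(default_factory=dict)


def _parse_multipart(body: bytes, content_type: str):
    m = re.search(r"boundary=([^;]+)", content_type)
    if not m:
        return {}, []
    boundary = m.group(1).strip('"').encode()
    fields: dict[str, str] = {}
    files: list[tuple[str, str, bytes]] = []
    for part in body.split(b"--" + boundary):
        part = part.strip(b"\r\n")
        if not part or part == b"--":
            continue
        if b"\r\n\r\n" not in part:
            continue
        head, _, content = part.partition(b"\r\n\r\n")
        headers = head.decode("utf-8", errors="replace")
        name_m = re.search(r'name="([^"]*)"', headers)
        file_m = re.search(r'filename="([^"]*)"', headers)
        if not name_m:
            continue
        if file_m:
            files.append((name_m.group(1), file_m.group(1), content))
        else:
            fields[name_m.group(1)] = content.decode("utf-8", errors="replace")
    return fields, files


class MockSynBioHub:
    """Local emulator; ``with MockSynBioHub(...) as hub: ...`` serves on localhost."""

    def __init__(self, users: dict[str, str] | None = None,
                 collection_path: str = "/user/demo/library"):
        self.users = users or {"demo": "secret"}
        self.collection_path = collection_path.rstrip("/")
        self.tokens: set[str] = set()
        self.members: dict[str, dict] = {}  # displayId -> record
        self.attachments: dict[str, list[str]] = {}
        self.requests: list[RecordedRequest] = []
        self.faults: list[dict] = []  # {"path": substr, "kind": "drop"|"503", "times": n}
        self._lock = threading.Lock()
        self._server: ThreadingHTTPServer | None = None
        self._thread: threading.Thread | None = None

    # -- lifecycle ---------------------------------------------------------
    def __enter__(self) -> "MockSynBioHub":
        self.start()
        return self

    def __exit__(self, *exc) -> None:
        self.stop()

    def start(self) -> None:
        hub = self

        class Handler(BaseHTTPRequestHandler):
            def log_message(self, *args):  # quiet
                pass

            def do_GET(self):
                hub._handle(self, "GET")

            def do_POST(self):
                hub._handle(self, "POST")

        class QuietServer(ThreadingHTTPServer):
            def handle_error(self, request, client_address):
                pass  # dropped connections are injected on purpose

        self._server = QuietServer(("127.0.0.1", 0), Handler)
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)
        self._thread.start()

    def stop(self) -> None:
        if self._server:
            self._server.shutdown()
            self._server.server_close()
            self._server = None

    @property
    def base_url(self) -> str:
        host, port = self._server.server_address
        return f"http://{host}:{port}"

    @property
    def collection_url(self) -> str:
        return self.base_url + self.collection_path

    def reset(self) -> None:
        with self._lock:
            self.members.clear()
            self.attachments.clear()
            self.requests.clear()
            self.faults.clear()
            self.tokens.clear()

    # -- fault injection ---------------------------------------------------
    def inject_fault(self, path_contains: str, kind: str = "drop", times: int = 1) -> None:
        """Fail the next ``times`` requests whose path contains the substring."""
        self.faults.append({"path": path_contains, "kind": kind, "times": times})

    def _pop_fault(self, path: str):
        with self._lock:
            for f in self.faults:
                if f["path"] in path and f["times"] > 0:
                    f["times"] -= 1
                    return f["kind"]
        return None

    # -- request handling --------------------------------------------------
    def _handle(self, handler: BaseHTTPRequestHandler, method: str) -> None:
        path = urllib.parse.urlsplit(handler.path).path
        length = int(handler.headers.get("Content-Length") or 0)
        body = handler.rfile.read(length) if length else b""
        ctype = handler.headers.get("Content-Type", "")

        fields: dict[str, str] = {}
        files: list = []
        if ctype.startswith("multipart/form-data"):
            fields, files = _parse_multipart(body, ctype)
        elif ctype.startswith("application/x-www-form-urlencoded"):
            fields = {k: v[0] for k, v in urllib.parse.parse_qs(body.decode()).items()}

        recorded_fields = dict(fields)
        if "password" in recorded_fields:
            recorded_fields["password"] = "***"  # never keep credentials
        with self._lock:
            self.requests.append(RecordedRequest(
                method=method, path=path, fields=recorded_fields,
                files=[(n, fn, c) for n, fn, c in files],
                headers={k: v for k, v in handler.headers.items()
                         if k.lower() in ("x-authorization", "accept")},
            ))

        fault = self._pop_fault(path)
        if fault == "drop":
            handler.connection.close()  # simulate a timed-out/dropped request
            return
        if fault and fault.isdigit():
            self._respond(handler, int(fault), b"injected fault")
            return

        if method == "POST" and path == "/login":
            user, password = fields.get("email"), fields.get("password")
            if self.users.get(user) == password:
                token = f"token-{user}"
                self.tokens.add(token)
                self._respond(handler, 200, token.encode())
            else:
                self._respond(handler, 401, b"wrong credentials")
            return

        if not self._authorized(handler):
            self._respond(handler, 401, b"missing or invalid token")
            return

        if method == "POST" and path == "/submit":
            self._submit(handler, fields, files)
        elif method == "GET" and path == self.collection_path + "/members":
            records = [self._public_record(m) for m in
                       sorted(self.members.values(), key=lambda m: m["displayId"])]
            self._respond(handler, 200, json.dumps(records).encode(),
                          "application/json")
        elif method == "POST" and path.endswith("/edit"):
            self._edit(handler, path, fields)
        elif method == "POST" and path.endswith("/attach"):
            self._attach(handler, path, files)
        else:
            self._respond(handler, 404, b"unknown endpoint")

    def _authorized(self, handler) -> bool:
        return handler.headers.get("X-authorization") in self.tokens

    def _member_for(self, path: str, suffix: str):
        prefix = self.collection_path + "/"
        trimmed = path[: -len(suffix)]
        if not trimmed.startswith(prefix):
            return None
        display_id = trimmed[len(prefix):].split("/")[0]
        return self.members.get(display_id)

    def _submit(self, handler, fields, files) -> None:
        if fields.get("rootCollections", "").rstrip("/") != self.collection_url.rstrip("/"):
            self._respond(handler, 404, b"unknown collection")
            return
        if not files:
            self._respond(handler, 400, b"no file in submission")
            return
        _, filename, content = files[0]
        text = content.decode("utf-8", errors="replace")
        if SYNBIOHUB_TERMS_NS in text:
            self._respond(handler, 400,
                          b"document carries repository-specific annotations; "
                          b"clean it before re-upload")
            return
        display_ids = self._root_display_ids(content)
        if not display_ids:
            self._respond(handler, 400, b"no SBOL2 ComponentDefinition found")
            return
        overwrite = fields.get("overwrite_merge", "0") != "0"
        with self._lock:
            clash = [d for d in display_ids if d in self.members]
            if clash and not overwrite:
                self._respond(handler, 409, b"already in collection")
                return
            for d in display_ids:
                self.members[d] = {
                    "displayId": d,
                    "uri": f"{self.collection_url}/{d}/1",
                    "name": d,
                    "description": "",
                    "notes": "",
                    "source": filename,
                }
        self._respond(handler, 200, b"submitted")

    def _root_display_ids(self, content: bytes) -> list[str]:
        """display_ids of root ComponentDefinitions in a submitted document."""
        import rdflib

        g = rdflib.Graph()
        try:
            g.parse(data=content, format="xml")
        except Exception:
            return []
        SBOL = rdflib.Namespace(SBOL2_NS)
        cds = set(g.subjects(rdflib.RDF.type, SBOL.ComponentDefinition))
        used = {next(iter(g.objects(c, SBOL.definition)), None)
                for c in g.subjects(rdflib.RDF.type, SBOL.Component)}
        out = []
        for cd in sorted(cds - used, key=str):
            display_id = next(iter(g.objects(cd, SBOL.displayId)), None)
            if display_id:
                out.append(str(display_id))
        return out

    def _edit(self, handler, path, fields) -> None:
        member = self._member_for(path, "/edit")
        if member is None:
            self._respond(handler, 404, b"unknown member")
            return
        fieldname, value = fields.get("field"), fields.get("value", "")
        if fieldname not in ("name", "description", "notes"):
            self._respond(handler, 400, b"unsupported field")
            return
        with self._lock:
            if fieldname == "notes" and member["notes"]:
                member["notes"] = member["notes"] + "\n" + value
            else:
                member[fieldname] = value
        self._respond(handler, 200, b"updated")

    def _attach(self, handler, path, files) -> None:
        member = self._member_for(path, "/attach")
        if member is None:
            self._respond(handler, 404, b"unknown member")
            return
        if not files:
            self._respond(handler, 400, b"no file attached")
            return
        with self._lock:
            self.attachments.setdefault(member["displayId"], []).extend(
                fn for _, fn, _ in files)
        self._respond(handler, 200, b"attached")

    @staticmethod
    def _public_record(member: dict) -> dict:
        return {k: member[k] for k in ("uri", "displayId", "name",
                                       "description", "notes")}

    @staticmethod
    def _respond(handler, status: int, body: bytes,
                 content_type: str = "text/plain") -> None:
        handler.send_response(status)
        handler.send_header("Content-Type", content_type)
        handler.send_header("Content-Length", str(len(body)))
        handler.end_headers()
        handler.wfile.write(body)
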