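"""Client for a SynBioHub-compatible repository HTTP API.

All network traffic goes through an injectable :class:`Transport`, so the full
online contract (login, submit-to-collection, field edit, attachment upload,
collection membership) is testable against a local emulator with no live
server. Batch operations retry transient failures (timeouts, dropped
connections, 5xx) with exponential backoff, keep going past per-item failures,
and record every attempt in a :class:`BatchReport`. Credentials never appear
in logs or reports.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.error
import urllib.parse
import urllib.request
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .model import SbolError
from .tableio import MetadataTable, interpolate, write_table

__all__ = [
    "SBOL_EXTENSIONS",
    "HubError",
    "CredentialError",
    "TransportError",
    "HttpResponse",
    "RetryPolicy",
    "HubSession",
    "UrllibTransport",
    "BatchReport",
    "login",
    "deposit_folder",
    "update_records",
    "collection_to_table",
]

log = logging.getLogger(__name__)

SBOL_EXTENSIONS = (".xml", ".sbol", ".rdf")


class HubError(SbolError):
    """A repository operation failed."""


class CredentialError(HubError):
    """Authentication was rejected."""


class TransportError(HubError):
    """The server could not be reached."""


@dataclass
class HttpResponse:
    status: int
    body: bytes = b""
    headers: dict[str, str] = field(default_factory=dict)

    @property
    def text(self) -> str:
        return self.body.decode("utf-8", errors="replace")


class UrllibTransport:
    """Default transport over urllib; raises TransportError on network failure."""

    def __init__(self, timeout: float = 30.0):
        self.timeout = timeout

    def request(self, method: str, url: str, headers=None, data: bytes | None = None
                ) -> HttpResponse:
        req = urllib.request.Request(url, data=data, method=method,
                                     headers=dict(headers or {}))
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return HttpResponse(status=resp.status, body=resp.read(),
                                    headers=dict(resp.headers))
        except urllib.error.HTTPError as exc:
            return HttpResponse(status=exc.code, body=exc.read() or b"",
                                headers=dict(exc.headers or {}))
        except (urllib.error.URLError, ConnectionError, TimeoutError, OSError) as exc:
            host = urllib.parse.urlsplit(url).netloc
            raise TransportError(f"cannot reach {host}: {exc}") from exc


@dataclass
class RetryPolicy:
    """Retry transient failures: timeouts, dropped connections and 5xx."""

    max_attempts: int = 3
    backoff: tuple[float, ...] = (1.0, 4.0)

    def delay(self, attempt: int) -> float:
        if not self.backoff:
            return 0.0
        return self.backoff[min(attempt - 1, len(self.backoff) - 1)]


@dataclass
class HubSession:
    server_url: str
    collection_url: str
    user: str
    token: str
    transport: object = field(default_factory=UrllibTransport)
    retry_policy: RetryPolicy = field(default_factory=RetryPolicy)

    @property
    def auth_headers(self) -> dict[str, str]:
        return {"X-authorization": self.token, "Accept": "text/plain"}


@dataclass
class BatchItem:
    item: str
    action: str
    attempts: int
    outcome: str  # ok | skipped | failed
    message: str = ""


@dataclass
class BatchReport:
    items: list[BatchItem] = field(default_factory=list)

    def add(self, item: str, action: str, attempts: int, outcome: str,
            message: str = "") -> None:
        self.items.append(BatchItem(item, action, attempts, outcome, message))

    @property
    def failed(self) -> list[BatchItem]:
        return [i for i in self.items if i.outcome == "failed"]

    @property
    def all_failed(self) -> bool:
        return bool(self.items) and len(self.failed) == len(self.items)

    def write_csv(self, path) -> Path:
        import csv

        path = Path(path)
        with path.open("w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["item", "action", "attempts", "outcome", "message"])
            for i in self.items:
                writer.writerow([i.item, i.action, i.attempts, i.outcome, i.message])
        return path


# ---------------------------------------------------------------------------
# multipart encoding (form-data bodies for submissions and attachments)
# ---------------------------------------------------------------------------

def encode_multipart(fields: dict[str, str], files=()) -> tuple[bytes, str]:
    """Encode form fields + (name, filename, content, mimetype) files."""
    boundary = uuid.uuid4().hex
    out = bytearray()
    for name, value in fields.items():
        out += (f"--{boundary}\r\nContent-Disposition: form-data; "
                f'name="{name}"\r\n\r\n{value}\r\n').encode()
    for name, filename, content, mimetype in files:
        out += (f"--{boundary}\r\nContent-Disposition: form-data; "
                f'name="{name}"; filename="{filename}"\r\n'
                f"Content-Type: {mimetype}\r\n\r\n").encode()
        out += content if isinstance(content, bytes) else content.encode()
        out += b"\r\n"
    out += f"--{boundary}--\r\n".encode()
    return bytes(out), f"multipart/form-data; boundary={boundary}"


def _with_retries(session: HubSession, describe: str, send) -> tuple[HttpResponse, int]:
    """Run ``send()`` with the session's retry policy; returns (response, attempts)."""
    policy = session.retry_policy
    last_exc: Optional[Exception] = None
    for attempt in range(1, policy.max_attempts + 1):
        try:
            resp = send()
        except TransportError as exc:
            last_exc = exc
            log.warning("%s: transient failure (attempt %d/%d): %s",
                        describe, attempt, policy.max_attempts, exc)
            if attempt < policy.max_attempts:
                time.sleep(policy.delay(attempt))
            continue
        if 500 <= resp.status < 600 and attempt < policy.max_attempts:
            log.warning("%s: server error %d (attempt %d/%d)",
                        describe, resp.status, attempt, policy.max_attempts)
            time.sleep(policy.delay(attempt))
            continue
        return resp, attempt
    raise TransportError(
        f"{describe}: giving up after {policy.max_attempts} attempts"
        + (f" ({last_exc})" if last_exc else "")
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def login(server_url: str, user: str, password: str,
          collection_url: str = "", transport=None,
          retry_policy: Optional[RetryPolicy] = None) -> HubSession:
    """Authenticate and return a session; the password is never logged."""
    transport = transport or UrllibTransport()
    server_url = server_url.rstrip("/")
    body = urllib.parse.urlencode({"email": user, "password": password}).encode()
    log.info("logging in to %s as %s", server_url, user)
    resp = transport.request(
        "POST", f"{server_url}/login",
        headers={"Content-Type": "application/x-www-form-urlencoded",
                 "Accept": "text/plain"},
        data=body,
    )
    if resp.status == 401:
        raise CredentialError(f"login rejected for user {user!r}")
    if resp.status != 200:
        raise HubError(f"login failed with HTTP {resp.status}")
    return HubSession(server_url=server_url, collection_url=collection_url,
                      user=user, token=resp.text.strip(),
                      transport=transport,
                      retry_policy=retry_policy or RetryPolicy())


def deposit_folder(session: HubSession, folders, overwrite: bool = False
                   ) -> BatchReport:
    """Submit every SBOL file in the folders to the session's collection.

    One submission per file; transient failures are retried per the session's
    retry policy, and processing continues past per-file failures.
    """
    report = BatchReport()
    paths: list[Path] = []
    for folder in folders:
        folder = Path(folder)
        if not folder.is_dir():
            raise HubError(f"folder not found: {folder}")
        paths.extend(sorted(p for p in folder.iterdir()
                            if p.suffix.lower() in SBOL_EXTENSIONS))
    for path in paths:
        fields = {
            "rootCollections": session.collection_url,
            "overwrite_merge": "1" if overwrite else "0",
        }
        content = path.read_bytes()
        body, ctype = encode_multipart(
            fields, [("file", path.name, content, "application/rdf+xml")])

        def send():
            return session.transport.request(
                "POST", f"{session.server_url}/submit",
                headers={**session.auth_headers, "Content-Type": ctype},
                data=body,
            )

        try:
            resp, attempts = _with_retries(session, f"deposit {path.name}", send)
        except TransportError as exc:
            report.add(str(path), "deposit", session.retry_policy.max_attempts,
                       "failed", str(exc))
            continue
        if resp.status in (200, 201):
            report.add(str(path), "deposit", attempts, "ok")
        elif resp.status == 409 and not overwrite:
            report.add(str(path), "deposit", attempts, "skipped",
                       "already in collection (no overwrite)")
        else:
            report.add(str(path), "deposit", attempts, "failed",
                       f"HTTP {resp.status}: {resp.text[:200]}")
    return report


def _collection_members(session: HubSession) -> list[dict]:
    def send():
        return session.transport.request(
            "GET", f"{session.collection_url.rstrip('/')}/members",
            headers={**session.auth_headers, "Accept": "application/json"},
        )

    resp, _ = _with_retries(session, "list collection members", send)
    if resp.status == 404:
        raise HubError(f"collection not found: {session.collection_url}")
    if resp.status != 200:
        raise HubError(f"member listing failed with HTTP {resp.status}")
    return json.loads(resp.text)


def update_records(session: HubSession, table: MetadataTable) -> BatchReport:
    """Push each row's field edits (and attachments) to its collection member.

    Rows whose display_id resolves to no member are marked failed; the run
    continues. Field edits cover name, description and notes after
    ``{placeholder}`` interpolation.
    """
    report = BatchReport()
    members = {m["displayId"]: m["uri"] for m in _collection_members(session)}
    for row in table:
        uri = members.get(row.display_id)
        if uri is None:
            report.add(row.display_id, "update", 0, "failed",
                       "not a member of the collection")
            continue
        attempts_total = 0
        failures: list[str] = []
        for fieldname in ("name", "description", "notes"):
            raw = row.get(fieldname)
            if raw is None:
                continue
            value = interpolate(raw, row)
            body, ctype = encode_multipart({"field": fieldname, "value": value})

            def send():
                return session.transport.request(
                    "POST", f"{uri.rstrip('/')}/edit",
                    headers={**session.auth_headers, "Content-Type": ctype},
                    data=body,
                )

            try:
                resp, attempts = _with_retries(
                    session, f"edit {fieldname} of {row.display_id}", send)
                attempts_total += attempts
                if resp.status != 200:
                    failures.append(f"{fieldname}: HTTP {resp.status}")
            except TransportError as exc:
                failures.append(f"{fieldname}: {exc}")
        if row.attachment_path:
            attachment = Path(row.attachment_path)
            if not attachment.is_file():
                failures.append(f"attachment not found: {attachment}")
            else:
                body, ctype = encode_multipart(
                    {}, [("file", attachment.name, attachment.read_bytes(),
                          "application/octet-stream")])

                def send_attach():
                    return session.transport.request(
                        "POST", f"{uri.rstrip('/')}/attach",
                        headers={**session.auth_headers, "Content-Type": ctype},
                        data=body,
                    )

                try:
                    resp, attempts = _with_retries(
                        session, f"attach to {row.display_id}", send_attach)
                    attempts_total += attempts
                    if resp.status != 200:
                        failures.append(f"attach: HTTP {resp.status}")
                except TransportError as exc:
                    failures.append(f"attach: {exc}")
        report.add(row.display_id, "update", max(attempts_total, 1),
                   "failed" if failures else "ok", "; ".join(failures))
    return report


def collection_to_table(session: HubSession, out_path) -> Path:
    """Export the collection's member identities to a workbook ready for UPDATE."""
    members = _collection_members(session)
    records = [
        (m["displayId"], {
            "name": m.get("name", ""),
            "description": m.get("description", ""),
            "notes": m.get("notes", ""),
        })
        for m in sorted(members, key=lambda m: m["displayId"])
    ]
    return write_table(records, out_path)
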