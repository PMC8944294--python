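"""Offline batch edits: ANNOTATE (table-driven metadata) and CLEAN (strip
repository-specific properties so a downloaded document can be re-uploaded).

A round-trip through a repository decorates every entity with server-side
bookkeeping properties (ownership, top-level markers, ...) under the
repository's terms namespace and re-roots identities under the server URL —
which is exactly what blocks re-upload. CLEAN removes every property triple
whose predicate falls under the configured namespaces (default: the SynBioHub
terms namespace) and re-mints top-level identities under a target URI prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import SbolDocument
from .sbolio import SYNBIOHUB_TERMS_NS
from .tableio import MetadataTable, interpolate

__all__ = [
    "DEFAULT_STRIP_NAMESPACES",
    "AnnotateReport",
    "annotate_document",
    "clean_document",
]

log = logging.getLogger(__name__)

#: namespaces whose predicates CLEAN removes by default
DEFAULT_STRIP_NAMESPACES = (SYNBIOHUB_TERMS_NS,)


@dataclass
class AnnotateReport:
    matched: list[str] = field(default_factory=list)
    unmatched_rows: list[str] = field(default_factory=list)
    unmatched_components: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"matched {len(self.matched)}, unmatched rows "
            f"{len(self.unmatched_rows)}, untouched components "
            f"{len(self.unmatched_components)}"
        )


class UnmatchedRowsError(Exception):
    """Strict mode: some table rows matched no component."""


def annotate_document(
    doc: SbolDocument,
    table: MetadataTable,
    strict: bool = False,
    append_notes: bool = True,
) -> tuple[SbolDocument, AnnotateReport]:
    """Apply each row's metadata to the component with the same display_id.

    name/description are replaced, notes appended (newline-separated) unless
    ``append_notes`` is false, authors added to creators, version replaced.
    Components not named in the table are untouched.
    """
    report = AnnotateReport()
    matched_ids = set()
    for row in table:
        target = doc.find_component(row.display_id)
        if target is None:
            report.unmatched_rows.append(row.display_id)
            continue
        matched_ids.add(row.display_id)
        report.matched.append(row.display_id)

        def value(column: str):
            raw = row.get(column)
            return interpolate(raw, row) if raw is not None else None

        name = value("name")
        if name is not None:
            target.name = name
        description = value("description")
        if description is not None:
            target.description = description
        notes = value("notes")
        if notes is not None:
            if append_notes and target.notes:
                if notes not in target.notes.split("\n"):
                    target.notes = target.notes + "\n" + notes
            else:
                target.notes = notes
        author = value("author")
        if author is not None:
            for creator in (a.strip() for a in author.split(";")):
                if creator and creator not in target.creators:
                    target.creators.append(creator)
        version = row.get("version")
        if version is not None:
            target.version = version

    report.unmatched_components = [
        c.display_id for c in doc.components if c.display_id not in matched_ids
    ]
    if strict and report.unmatched_rows:
        raise UnmatchedRowsError(
            "rows matched no component: " + ", ".join(report.unmatched_rows)
        )
    return doc, report


def clean_document(
    doc: SbolDocument,
    namespaces=None,
    target_prefix: str | None = None,
) -> SbolDocument:
    """Strip repository-namespace properties and re-root identities.

    Removes every extra/foreign property whose predicate starts with one of
    ``namespaces`` (default :data:`DEFAULT_STRIP_NAMESPACES`), then rewrites
    top-level persistent identities onto ``target_prefix`` (default: the
    document's own ``uri_prefix``), preserving display_id and version. The
    operation is idempotent and returns the same document object.
    """
    namespaces = tuple(namespaces) if namespaces else DEFAULT_STRIP_NAMESPACES
    log.info("CLEAN: stripping predicates under %s", ", ".join(namespaces))

    def keep(pred: str) -> bool:
        return not any(pred.startswith(ns) for ns in namespaces)

    for entity in (*doc.components, *doc.sequences, *doc.collections):
        entity.extra_properties = [
            (p, o) for p, o in entity.extra_properties if keep(p)
        ]
    doc.foreign_properties = {
        (s, p, o) for s, p, o in doc.foreign_properties if keep(str(p))
    }

    prefix = (target_prefix or doc.uri_prefix).rstrip("/")
    rewrites: dict[str, str] = {}
    for entity in (*doc.components, *doc.sequences, *doc.collections):
        old_pid = doc.persistent_identity(entity)
        new_pid = f"{prefix}/{entity.display_id}"
        if old_pid != new_pid:
            rewrites[old_pid] = new_pid
        entity.identity = None  # re-mint from the document prefix
    for c in doc.components:
        for use in c.subcomponents:
            use.identity = use.sa_identity = use.range_identity = None
        c.constraints = [(t[0], t[1]) for t in c.constraints]
    if rewrites:
        def rewrite(u: str) -> str:
            for old, new in rewrites.items():
                if u == old or u.startswith(old + "/"):
                    return new + u[len(old):]
            return u

        doc.foreign_properties = {
            (rewrite(str(s)), p, o) for s, p, o in doc.foreign_properties
        }
    doc.uri_prefix = prefix
    doc.namespaces = {
        pfx: ns for pfx, ns in doc.namespaces.items() if ns not in namespaces
    }
    return doc
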