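"""Lossless read/write of SBOL2 RDF/XML documents, plus GenBank/FASTA export.

Reading maps ComponentDefinitions, Sequences and Collections onto the typed
model; every other triple is preserved verbatim (``extra_properties`` when the
subject is a typed top-level entity, ``foreign_properties`` otherwise) so a
read/write cycle is lossless at the triple level. Writing is deterministic:
identical documents serialize to identical bytes.

Only the RDF/XML serialization dialect is accepted — the format SynBioHub
exchanges. SBOL3 documents are rejected with an explicit error.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional
from xml.sax.saxutils import escape, quoteattr

import rdflib
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import DC, DCTERMS, RDF, RDFS, split_uri

from .model import (
    INLINE,
    REVERSE_COMPLEMENT,
    Annotation,
    CollectionRecord,
    ComponentRecord,
    RangeLocation,
    SbolDocument,
    SbolError,
    SequenceRecord,
    SubcomponentUse,
)

__all__ = [
    "SBOL2_NS",
    "SBOL3_NS",
    "SYNBIOHUB_TERMS_NS",
    "IUPAC_DNA_ENCODING",
    "SbolFormatError",
    "UnsupportedVersionError",
    "read_sbol",
    "write_sbol",
    "to_graph",
    "documents_equal",
    "export_genbank",
    "export_fasta",
]

SBOL2_NS = "http://sbols.org/v2#"
SBOL3_NS = "http://sbols.org/v3#"
SYNBIOHUB_TERMS_NS = "http://wiki.synbiohub.org/wiki/Terms/synbiohub#"
IUPAC_DNA_ENCODING = "http://www.chem.qmul.ac.uk/iubmb/misc/naseq.html"

SBOL = rdflib.Namespace(SBOL2_NS)

_ORIENT_TO_URI = {
    INLINE: SBOL.inline,
    REVERSE_COMPLEMENT: SBOL.reverseComplement,
}
_URI_TO_ORIENT = {str(v): k for k, v in _ORIENT_TO_URI.items()}

# namespace prefixes used when serializing; extras are assigned ns1, ns2, ...
_BASE_PREFIXES = {
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "dcterms": str(DCTERMS),
    "dc": str(DC),
    "sbol": SBOL2_NS,
    "sbh": SYNBIOHUB_TERMS_NS,
    "prov": "http://www.w3.org/ns/prov#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
}


class SbolFormatError(SbolError):
    """Input is not parseable SBOL2 RDF/XML."""


class UnsupportedVersionError(SbolError):
    """Input uses the SBOL3 namespace; only SBOL2 is supported."""


# ---------------------------------------------------------------------------
# document -> graph
# ---------------------------------------------------------------------------

def _term(value) -> object:
    if isinstance(value, (URIRef, Literal, BNode)):
        return value
    return Literal(str(value))


def _child_identity(pid: str, version: str, local: str) -> tuple[str, str]:
    p = f"{pid}/{local}"
    return p, f"{p}/{version}"


def _local_display_id(identity: str, version: str) -> str:
    parts = identity.rstrip("/").split("/")
    if parts and parts[-1] == version and len(parts) >= 2:
        return parts[-2]
    return parts[-1]


def to_graph(doc: SbolDocument) -> Graph:
    """Materialize the document as an rdflib graph (typed + foreign triples)."""
    g = Graph()
    for c in doc.components:
        _component_triples(g, doc, c)
    for s in doc.sequences:
        u = URIRef(doc.identity_of(s))
        g.add((u, RDF.type, SBOL.Sequence))
        g.add((u, SBOL.displayId, Literal(s.display_id)))
        g.add((u, SBOL.persistentIdentity, URIRef(doc.persistent_identity(s))))
        g.add((u, SBOL.version, Literal(s.version)))
        g.add((u, SBOL.elements, Literal(s.elements)))
        g.add((u, SBOL.encoding, URIRef(IUPAC_DNA_ENCODING)))
        for pred, obj in s.extra_properties:
            g.add((u, URIRef(pred), _term(obj)))
    for col in doc.collections:
        u = URIRef(doc.identity_of(col))
        g.add((u, RDF.type, SBOL.Collection))
        g.add((u, SBOL.displayId, Literal(col.display_id)))
        g.add((u, SBOL.persistentIdentity, URIRef(doc.persistent_identity(col))))
        g.add((u, SBOL.version, Literal(col.version)))
        if col.name:
            g.add((u, DCTERMS.title, Literal(col.name)))
        if col.description:
            g.add((u, DCTERMS.description, Literal(col.description)))
        for m in col.member_uris:
            g.add((u, SBOL.member, URIRef(m)))
        for pred, obj in col.extra_properties:
            g.add((u, URIRef(pred), _term(obj)))
    for s, p, o in doc.foreign_properties:
        g.add((URIRef(s) if isinstance(s, str) else s, URIRef(p), _term(o)))
    return g


def _component_triples(g: Graph, doc: SbolDocument, c: ComponentRecord) -> None:
    pid = doc.persistent_identity(c)
    u = URIRef(doc.identity_of(c))
    g.add((u, RDF.type, SBOL.ComponentDefinition))
    g.add((u, SBOL.displayId, Literal(c.display_id)))
    g.add((u, SBOL.persistentIdentity, URIRef(pid)))
    g.add((u, SBOL.version, Literal(c.version)))
    if c.name:
        g.add((u, DCTERMS.title, Literal(c.name)))
    if c.description:
        g.add((u, DCTERMS.description, Literal(c.description)))
    if c.notes:
        g.add((u, RDFS.comment, Literal(c.notes)))
    for creator in c.creators:
        g.add((u, DC.creator, Literal(creator)))
    for role in sorted(c.roles):
        g.add((u, SBOL.role, URIRef(role)))
    for t in sorted(c.types):
        g.add((u, SBOL.type, URIRef(t)))
    if c.sequence_ref:
        seq = doc.find_sequence(c.sequence_ref)
        target = doc.identity_of(seq) if seq else c.sequence_ref
        g.add((u, SBOL.sequence, URIRef(target)))

    for use in c.subcomponents:
        comp_id = use.identity or _child_identity(pid, c.version, use.instance_id)[1]
        comp_pid = comp_id[: -len("/" + c.version)] if comp_id.endswith("/" + c.version) else comp_id
        cu = URIRef(comp_id)
        g.add((u, SBOL.component, cu))
        g.add((cu, RDF.type, SBOL.Component))
        g.add((cu, SBOL.displayId, Literal(use.instance_id)))
        g.add((cu, SBOL.persistentIdentity, URIRef(comp_pid)))
        g.add((cu, SBOL.version, Literal(c.version)))
        g.add((cu, SBOL.access, SBOL.public))
        child = doc.resolve_child(use)
        definition = doc.identity_of(child) if child else use.child_ref
        g.add((cu, SBOL.definition, URIRef(definition)))
        if use.location is not None:
            sa_id = use.sa_identity or _child_identity(pid, c.version, f"annotation_{use.instance_id}")[1]
            sa = URIRef(sa_id)
            sa_pid = sa_id[: -len("/" + c.version)] if sa_id.endswith("/" + c.version) else sa_id
            g.add((u, SBOL.sequenceAnnotation, sa))
            g.add((sa, RDF.type, SBOL.SequenceAnnotation))
            g.add((sa, SBOL.displayId, Literal(_local_display_id(sa_id, c.version))))
            g.add((sa, SBOL.persistentIdentity, URIRef(sa_pid)))
            g.add((sa, SBOL.version, Literal(c.version)))
            g.add((sa, SBOL.component, cu))
            r_id = use.range_identity or f"{sa_pid}/range/{c.version}"
            _range_triples(g, sa, r_id, use.location, c.version)

    for a in c.annotations:
        sa_pid, sa_id = _child_identity(pid, c.version, a.display_id)
        sa = URIRef(sa_id)
        g.add((u, SBOL.sequenceAnnotation, sa))
        g.add((sa, RDF.type, SBOL.SequenceAnnotation))
        g.add((sa, SBOL.displayId, Literal(a.display_id)))
        g.add((sa, SBOL.persistentIdentity, URIRef(sa_pid)))
        g.add((sa, SBOL.version, Literal(c.version)))
        if a.name:
            g.add((sa, DCTERMS.title, Literal(a.name)))
        for role in sorted(a.roles):
            g.add((sa, SBOL.role, URIRef(role)))
        _range_triples(g, sa, f"{sa_pid}/range/{c.version}", a.location, c.version)

    for t in c.constraints:
        subj_id, obj_id = t[0], t[1]
        sc_id = t[2] if len(t) > 2 else _child_identity(pid, c.version, f"constraint_{subj_id}_{obj_id}")[1]
        sc = URIRef(sc_id)
        sc_pid = sc_id[: -len("/" + c.version)] if sc_id.endswith("/" + c.version) else sc_id
        g.add((u, SBOL.sequenceConstraint, sc))
        g.add((sc, RDF.type, SBOL.SequenceConstraint))
        g.add((sc, SBOL.displayId, Literal(_local_display_id(sc_id, c.version))))
        g.add((sc, SBOL.persistentIdentity, URIRef(sc_pid)))
        g.add((sc, SBOL.version, Literal(c.version)))
        g.add((sc, SBOL.restriction, SBOL.precedes))
        for pred, inst in ((SBOL.subject, subj_id), (SBOL.object, obj_id)):
            use = c.find_use(inst)
            target = use.identity if use and use.identity else _child_identity(pid, c.version, inst)[1]
            g.add((sc, pred, URIRef(target)))

    for pred, obj in c.extra_properties:
        g.add((u, URIRef(pred), _term(obj)))


def _range_triples(g: Graph, sa: URIRef, r_id: str, loc: RangeLocation, version: str) -> None:
    r = URIRef(r_id)
    r_pid = r_id[: -len("/" + version)] if r_id.endswith("/" + version) else r_id
    g.add((sa, SBOL.location, r))
    g.add((r, RDF.type, SBOL.Range))
    g.add((r, SBOL.displayId, Literal(_local_display_id(r_id, version))))
    g.add((r, SBOL.persistentIdentity, URIRef(r_pid)))
    g.add((r, SBOL.version, Literal(version)))
    g.add((r, SBOL.start, Literal(str(loc.start))))
    g.add((r, SBOL.end, Literal(str(loc.end))))
    g.add((r, SBOL.orientation, _ORIENT_TO_URI[loc.orientation]))


# ---------------------------------------------------------------------------
# graph -> document
# ---------------------------------------------------------------------------

def read_sbol(path) -> SbolDocument:
    """Parse an SBOL2 RDF/XML file into an :class:`SbolDocument`."""
    path = Path(path)
    g = Graph()
    try:
        g.parse(location=str(path), format="xml")
    except Exception as exc:  # SAXParseException carries line/column info
        raise SbolFormatError(f"{path}: not parseable as RDF/XML: {exc}") from exc

    for s, p, o in g:
        if str(p).startswith(SBOL3_NS) or (p == RDF.type and str(o).startswith(SBOL3_NS)):
            raise UnsupportedVersionError(
                f"{path}: document uses the SBOL3 namespace ({SBOL3_NS}); only SBOL2 is supported"
            )

    doc = SbolDocument()
    used_ns = set()
    for s, p, o in g:
        if _splits(str(p)):
            used_ns.add(split_uri(str(p))[0])
        if p == RDF.type and isinstance(o, URIRef) and _splits(str(o)):
            used_ns.add(split_uri(str(o))[0])
    base_values = set(_BASE_PREFIXES.values())
    doc.namespaces = {
        prefix: str(ns)
        for prefix, ns in g.namespaces()
        if prefix and not prefix.startswith("default")
        and str(ns) in used_ns and str(ns) not in base_values
    }
    consumed: set[tuple] = set()

    def take(s, p) -> Optional[object]:
        for o in g.objects(s, p):
            consumed.add((s, p, o))
            return o
        return None

    def take_all(s, p) -> list:
        out = []
        for o in sorted(g.objects(s, p), key=str):
            consumed.add((s, p, o))
            out.append(o)
        return out

    cd_subjects = sorted(g.subjects(RDF.type, SBOL.ComponentDefinition), key=str)
    seq_subjects = sorted(g.subjects(RDF.type, SBOL.Sequence), key=str)
    col_subjects = sorted(g.subjects(RDF.type, SBOL.Collection), key=str)
    cd_by_uri = {str(s): s for s in cd_subjects}
    seq_display = {}

    for s in seq_subjects:
        consumed.add((s, RDF.type, SBOL.Sequence))
        display_id = str(take(s, SBOL.displayId) or _guess_display_id(str(s)))
        take(s, SBOL.persistentIdentity)
        version = str(take(s, SBOL.version) or "1")
        elements = str(take(s, SBOL.elements) or "")
        take(s, SBOL.encoding)
        rec = SequenceRecord(display_id=display_id, elements=elements, version=version,
                             identity=str(s))
        for _, p, o in g.triples((s, None, None)):
            if (s, p, o) not in consumed:
                rec.extra_properties.append((str(p), o))
                consumed.add((s, p, o))
        doc.sequences.append(rec)
        seq_display[str(s)] = display_id

    cd_display = {}
    for s in cd_subjects:
        display_id = None
        for o in g.objects(s, SBOL.displayId):
            display_id = str(o)
            break
        cd_display[str(s)] = display_id or _guess_display_id(str(s))

    for s in cd_subjects:
        consumed.add((s, RDF.type, SBOL.ComponentDefinition))
        display_id = str(take(s, SBOL.displayId) or cd_display[str(s)])
        take(s, SBOL.persistentIdentity)
        version = str(take(s, SBOL.version) or "1")
        rec = ComponentRecord(display_id=display_id, version=version, identity=str(s))
        name = take(s, DCTERMS.title)
        rec.name = str(name) if name is not None else None
        desc = take(s, DCTERMS.description)
        rec.description = str(desc) if desc is not None else None
        notes = take(s, RDFS.comment)
        rec.notes = str(notes) if notes is not None else None
        rec.creators = [str(o) for o in take_all(s, DC.creator)]
        rec.roles = {str(o) for o in take_all(s, SBOL.role)}
        rec.types = {str(o) for o in take_all(s, SBOL.type)}
        seq_uri = take(s, SBOL.sequence)
        if seq_uri is not None:
            rec.sequence_ref = seq_display.get(str(seq_uri), str(seq_uri))

        comp_by_uri: dict[str, SubcomponentUse] = {}
        for cu in take_all(s, SBOL.component):
            if (cu, RDF.type, SBOL.Component) not in g:
                continue
            consumed.add((cu, RDF.type, SBOL.Component))
            inst = str(take(cu, SBOL.displayId) or _guess_display_id(str(cu)))
            take(cu, SBOL.persistentIdentity)
            take(cu, SBOL.version)
            take(cu, SBOL.access)
            definition = take(cu, SBOL.definition)
            child_ref = cd_display.get(str(definition), str(definition)) if definition else ""
            use = SubcomponentUse(instance_id=inst, child_ref=child_ref, identity=str(cu))
            for _, p, o in g.triples((cu, None, None)):
                if (cu, p, o) not in consumed:
                    doc.foreign_properties.add((str(cu), str(p), o))
                    consumed.add((cu, p, o))
            rec.subcomponents.append(use)
            comp_by_uri[str(cu)] = use

        for sa in list(g.objects(s, SBOL.sequenceAnnotation)):
            loc_node = next(iter(g.objects(sa, SBOL.location)), None)
            if loc_node is None or (loc_node, RDF.type, SBOL.Range) not in g:
                continue  # non-Range location: left in foreign_properties untouched
            consumed.add((s, SBOL.sequenceAnnotation, sa))
            consumed.add((sa, RDF.type, SBOL.SequenceAnnotation))
            sa_display = str(take(sa, SBOL.displayId) or _guess_display_id(str(sa)))
            take(sa, SBOL.persistentIdentity)
            take(sa, SBOL.version)
            consumed.add((sa, SBOL.location, loc_node))
            consumed.add((loc_node, RDF.type, SBOL.Range))
            take(loc_node, SBOL.displayId)
            take(loc_node, SBOL.persistentIdentity)
            take(loc_node, SBOL.version)
            start = int(str(take(loc_node, SBOL.start)))
            end = int(str(take(loc_node, SBOL.end)))
            orient_uri = take(loc_node, SBOL.orientation)
            orientation = _URI_TO_ORIENT.get(str(orient_uri), INLINE)
            loc = RangeLocation(start=start, end=end, orientation=orientation)
            comp_ref = take(sa, SBOL.component)
            if comp_ref is not None and str(comp_ref) in comp_by_uri:
                use = comp_by_uri[str(comp_ref)]
                use.location = loc
                use.sa_identity = str(sa)
                use.range_identity = str(loc_node)
            else:
                title = take(sa, DCTERMS.title)
                roles = {str(o) for o in take_all(sa, SBOL.role)}
                rec.annotations.append(Annotation(
                    display_id=sa_display, location=loc,
                    name=str(title) if title is not None else None, roles=roles))
            for node in (sa, loc_node):
                for _, p, o in g.triples((node, None, None)):
                    if (node, p, o) not in consumed:
                        doc.foreign_properties.add((str(node), str(p), o))
                        consumed.add((node, p, o))

        for sc in take_all(s, SBOL.sequenceConstraint):
            restriction = next(iter(g.objects(sc, SBOL.restriction)), None)
            if restriction != SBOL.precedes:
                continue
            consumed.add((sc, RDF.type, SBOL.SequenceConstraint))
            take(sc, SBOL.displayId)
            take(sc, SBOL.persistentIdentity)
            take(sc, SBOL.version)
            take(sc, SBOL.restriction)
            subj = take(sc, SBOL.subject)
            obj = take(sc, SBOL.object)
            subj_use = comp_by_uri.get(str(subj))
            obj_use = comp_by_uri.get(str(obj))
            if subj_use and obj_use:
                rec.constraints.append((subj_use.instance_id, obj_use.instance_id, str(sc)))
            for _, p, o in g.triples((sc, None, None)):
                if (sc, p, o) not in consumed:
                    doc.foreign_properties.add((str(sc), str(p), o))
                    consumed.add((sc, p, o))

        for _, p, o in g.triples((s, None, None)):
            if (s, p, o) not in consumed:
                rec.extra_properties.append((str(p), o))
                consumed.add((s, p, o))
        rec.extra_properties.sort(key=lambda kv: (kv[0], str(kv[1])))
        doc.components.append(rec)

    for s in col_subjects:
        consumed.add((s, RDF.type, SBOL.Collection))
        display_id = str(take(s, SBOL.displayId) or _guess_display_id(str(s)))
        take(s, SBOL.persistentIdentity)
        version = str(take(s, SBOL.version) or "1")
        name = take(s, DCTERMS.title)
        desc = take(s, DCTERMS.description)
        rec = CollectionRecord(
            display_id=display_id, version=version, identity=str(s),
            name=str(name) if name is not None else None,
            description=str(desc) if desc is not None else None,
            member_uris=[str(o) for o in take_all(s, SBOL.member)])
        for _, p, o in g.triples((s, None, None)):
            if (s, p, o) not in consumed:
                rec.extra_properties.append((str(p), o))
                consumed.add((s, p, o))
        doc.collections.append(rec)

    for s, p, o in g:
        if (s, p, o) not in consumed:
            doc.foreign_properties.add((str(s), str(p), o))

    # mark generic (sequence-less) children as template slots
    for c in doc.components:
        for use in c.subcomponents:
            child = doc.resolve_child(use)
            use.is_generic = child is not None and child.sequence_ref is None

    if doc.components:
        first = doc.components[0]
        pid = doc.persistent_identity(first)
        if pid.endswith("/" + first.display_id):
            doc.uri_prefix = pid[: -len("/" + first.display_id)]
    return doc


def _guess_display_id(uri: str) -> str:
    token = uri.rstrip("/").split("/")[-1].split("#")[-1]
    return "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in token) or "entity"


# ---------------------------------------------------------------------------
# deterministic RDF/XML serialization
# ---------------------------------------------------------------------------

def _qname(uri: str, prefixes: dict[str, str]) -> tuple[str, str, str]:
    """Return (prefix, namespace, localname) for a predicate/type URI."""
    try:
        ns, local = split_uri(uri)
    except Exception as exc:
        raise SbolFormatError(f"cannot serialize predicate {uri!r} as XML QName") from exc
    for pfx, n in prefixes.items():
        if n == ns:
            return pfx, ns, local
    raise KeyError(ns)


def _collect_prefixes(g: Graph, doc_namespaces: dict[str, str]) -> dict[str, str]:
    needed_uris = set()
    for s, p, o in g:
        needed_uris.add(str(p))
        if p == RDF.type and isinstance(o, URIRef):
            needed_uris.add(str(o))
    needed_ns = {split_uri(u)[0] for u in needed_uris if _splits(u)}
    prefixes = {"rdf": str(RDF)}  # always required for rdf:RDF / rdf:about
    taken = {str(RDF)}
    for pfx, ns in _BASE_PREFIXES.items():
        if ns in needed_ns and ns not in taken:
            prefixes[pfx] = ns
            taken.add(ns)
    for prefix, ns in sorted(doc_namespaces.items()):
        if ns in needed_ns and ns not in taken and prefix not in prefixes:
            prefixes[prefix] = ns
            taken.add(ns)
    for i, ns in enumerate(sorted(needed_ns - taken), start=1):
        prefixes[f"ns{i}"] = ns
    return prefixes


def _splits(uri: str) -> bool:
    try:
        split_uri(uri)
        return True
    except Exception:
        return False


def _node_ref(term) -> str:
    if isinstance(term, BNode):
        return f'rdf:nodeID="{term}"'
    return f"rdf:resource={quoteattr(str(term))}"


def write_sbol(doc: SbolDocument, path) -> Path:
    """Serialize the document as deterministic SBOL2 RDF/XML."""
    path = Path(path)
    g = to_graph(doc)
    prefixes = _collect_prefixes(g, doc.namespaces)

    by_subject: dict = {}
    for s, p, o in g:
        by_subject.setdefault(s, []).append((p, o))

    lines = ['<?xml version="1.0" encoding="utf-8"?>']
    decls = " ".join(
        f'xmlns:{pfx}={quoteattr(ns)}' for pfx, ns in sorted(prefixes.items())
    )
    lines.append(f"<rdf:RDF {decls}>")
    for s in sorted(by_subject, key=lambda t: (isinstance(t, BNode), str(t))):
        if isinstance(s, BNode):
            lines.append(f'  <rdf:Description rdf:nodeID="{s}">')
        else:
            lines.append(f"  <rdf:Description rdf:about={quoteattr(str(s))}>")
        props = by_subject[s]
        def sort_key(po):
            p, o = po
            return (p != RDF.type, str(p), str(o))
        for p, o in sorted(props, key=sort_key):
            pfx, _, local = _qname(str(p), prefixes)
            tag = f"{pfx}:{local}"
            if isinstance(o, (URIRef, BNode)):
                lines.append(f"    <{tag} {_node_ref(o)}/>")
            else:
                attrs = ""
                if o.datatype is not None:
                    attrs += f" rdf:datatype={quoteattr(str(o.datatype))}"
                if o.language:
                    attrs += f' xml:lang="{o.language}"'
                lines.append(f"    <{tag}{attrs}>{escape(str(o))}</{tag}>")
        lines.append("  </rdf:Description>")
    lines.append("</rdf:RDF>")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def documents_equal(a: SbolDocument, b: SbolDocument) -> bool:
    """Triple-level equality (blank-node aware) of two documents."""
    from rdflib.compare import to_isomorphic

    return to_isomorphic(to_graph(a)) == to_isomorphic(to_graph(b))


# ---------------------------------------------------------------------------
# GenBank / FASTA export
# ---------------------------------------------------------------------------

def _features_of(flat: ComponentRecord, doc: SbolDocument):
    """(label, roles, RangeLocation) for each annotated span of a flat record."""
    out = []
    for a in flat.annotations:
        out.append((a.name or a.display_id, sorted(a.roles), a.location))
    for use in flat.subcomponents:
        if use.location is None:
            raise SbolError(
                f"subcomponent {use.instance_id} of {flat.display_id} has no Range "
                "location; flatten the design first"
            )
        child = doc.resolve_child(use)
        label = (child.name or child.display_id) if child else use.instance_id
        roles = sorted(child.roles) if child else []
        out.append((label, roles, use.location))
    out.sort(key=lambda t: (t[2].start, -t[2].length, t[0]))
    return out


def export_genbank(flat: ComponentRecord, doc: SbolDocument, path) -> Path:
    """Write a flat (single-sequence) design as an annotated GenBank record."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    seq = doc.sequence_of(flat)
    if seq is None or not seq.elements:
        raise SbolError(
            f"{flat.display_id} has no sequence; run flatten first to assemble one"
        )
    record = SeqRecord(
        Seq(seq.elements),
        id=flat.display_id[:16],
        name=flat.display_id[:16],
        description=flat.description or (flat.name or ""),
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    length = len(seq.elements)
    record.features.append(
        SeqFeature(SimpleLocation(0, length, strand=1), type="source")
    )
    for label, roles, loc in _features_of(flat, doc):
        strand = -1 if loc.orientation == REVERSE_COMPLEMENT else 1
        qualifiers = {"label": [label]}
        if roles:
            qualifiers["note"] = roles
        record.features.append(
            SeqFeature(
                SimpleLocation(loc.start - 1, loc.end, strand=strand),
                type="misc_feature",
                qualifiers=qualifiers,
            )
        )
    path = Path(path)
    with path.open("w") as handle:
        SeqIO.write([record], handle, "genbank")
    return path


def export_fasta(flat: ComponentRecord, doc: SbolDocument, path) -> Path:
    """Write a flat design's sequence as FASTA (convenience export)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seq = doc.sequence_of(flat)
    if seq is None or not seq.elements:
        raise SbolError(f"{flat.display_id} has no sequence to export")
    record = SeqRecord(Seq(seq.elements), id=flat.display_id,
                       description=flat.name or "")
    path = Path(path)
    with path.open("w") as handle:
        SeqIO.write([record], handle, "fasta")
    return path
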