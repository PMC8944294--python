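"""FLATTEN: collapse a hierarchical design into one annotated linear sequence.

Repositories render annotated sequences only for simple designs; once
subcomponents nest, the full sequence disappears from view. Flattening maps the
whole subcomponent tree onto a single ComponentDefinition whose sequence covers
the entire construct and which carries one annotation per descendant
subcomponent — a representation directly exportable to GenBank.

Coordinate arithmetic (all positions 1-based inclusive):

* child at relative Range [s, e] inside an *inline* parent spanning absolute
  [P, Q] maps to absolute [P - 1 + s, P - 1 + e], orientation unchanged;
* inside a *reverse-complement* parent it maps to [Q - e + 1, Q - s + 1] with
  the orientation flipped — an even number of reverse_complement steps along
  the ancestor chain composes to inline, an odd number to reverse_complement.

Only Range locations are supported; designs using Cut or GenericLocation are
rejected, and "abstract" designs (a leaf without a concrete sequence) cannot
be flattened.
"""

from __future__ import annotations

from .model import (
    Annotation,
    ComponentRecord,
    INLINE,
    REVERSE_COMPLEMENT,
    RangeLocation,
    SbolDocument,
    SbolError,
    SequenceRecord,
    is_iupac_dna,
)

__all__ = [
    "StructureError",
    "flatten_design",
    "flatten_to_document",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


class StructureError(SbolError):
    """The design's subcomponent tree cannot be flattened."""


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement; case is preserved per character."""
    if not is_iupac_dna(seq):
        bad = next(i for i, c in enumerate(seq) if c.upper() not in set("ACGTURYSWKMBDHVN"))
        raise SbolError(f"non-IUPAC character {seq[bad]!r} at position {bad + 1}")
    return seq.translate(_COMPLEMENT)[::-1]


def _compose(parent: str, child: str) -> str:
    return child if parent == INLINE else (
        INLINE if child == REVERSE_COMPLEMENT else REVERSE_COMPLEMENT
    )


def _child_sequence(record: ComponentRecord, doc: SbolDocument, visiting: set[str]) -> str:
    """Concrete sequence of a component, assembling recursively if needed."""
    seq = doc.sequence_of(record)
    if seq is not None and seq.elements:
        return seq.elements
    if not record.subcomponents:
        raise StructureError(
            f"component {record.display_id!r} has no sequence and no subcomponents; "
            "abstract designs cannot be flattened"
        )
    return _assemble(record, doc, visiting)


def _tiles(record: ComponentRecord, doc: SbolDocument):
    tiles = []
    for use in record.subcomponents:
        if use.location is None:
            raise StructureError(
                f"subcomponent {use.instance_id!r} of {record.display_id} has no "
                "Range location; only Range locations are supported"
            )
        child = doc.resolve_child(use)
        if child is None:
            raise StructureError(
                f"subcomponent {use.instance_id!r} of {record.display_id}: "
                f"unresolvable child {use.child_ref!r}"
            )
        tiles.append((use, child))
    tiles.sort(key=lambda t: (t[0].location.start, t[0].location.end))
    for (a, _), (b, _) in zip(tiles, tiles[1:]):
        if b.location.start <= a.location.end:
            raise StructureError(
                f"{record.display_id}: sibling ranges overlap at positions "
                f"[{b.location.start}, {a.location.end}]"
            )
    return tiles


def _assemble(record: ComponentRecord, doc: SbolDocument, visiting: set[str]) -> str:
    """Build the record's sequence from child tiles; tiles must cover 1..L."""
    if record.display_id in visiting:
        raise StructureError(f"cyclic containment through {record.display_id!r}")
    visiting = visiting | {record.display_id}
    tiles = _tiles(record, doc)
    parts = []
    pos = 1
    for use, child in tiles:
        loc = use.location
        if loc.start != pos:
            raise StructureError(
                f"{record.display_id}: gap in assembly between position {pos} and "
                f"{loc.start}"
            )
        content = _child_sequence(child, doc, visiting)
        if len(content) != loc.length:
            raise StructureError(
                f"{record.display_id}: child {use.instance_id!r} sequence length "
                f"{len(content)} does not fill its Range [{loc.start}, {loc.end}]"
            )
        if loc.orientation == REVERSE_COMPLEMENT:
            content = reverse_complement(content)
        parts.append(content)
        pos = loc.end + 1
    return "".join(parts)


def flatten_design(design_id: str, doc: SbolDocument) -> tuple[ComponentRecord, SequenceRecord]:
    """Flatten ``design_id`` into a new self-contained record + sequence.

    Returns a fresh ComponentRecord (display_id = original + ``_flat``) with
    one :class:`Annotation` per descendant subcomponent use, and the full
    SequenceRecord it references. The original design is left untouched.
    """
    design = doc.find_component(design_id)
    if design is None:
        raise SbolError(f"design {design_id!r} not found in document")

    own = doc.sequence_of(design)
    if own is not None and own.elements:
        elements = own.elements
        # warn (non-fatally) when child tiles disagree with the verified sequence
        try:
            assembled = _assemble(design, doc, set()) if design.subcomponents else elements
        except StructureError:
            assembled = None
        if assembled is not None and assembled.upper() != elements.upper():
            import logging

            logging.getLogger(__name__).warning(
                "%s: design sequence differs from assembled child tiles; "
                "keeping the design's own sequence", design_id)
    else:
        if not design.subcomponents:
            raise StructureError(
                f"design {design_id!r} has neither a sequence nor subcomponents"
            )
        elements = _assemble(design, doc, set())

    annotations: list[Annotation] = []

    def walk(record: ComponentRecord, span: RangeLocation, visiting: set[str]) -> None:
        if record.display_id in visiting:
            raise StructureError(f"cyclic containment through {record.display_id!r}")
        for use, child in _tiles(record, doc) if record.subcomponents else []:
            loc = use.location
            if span.orientation == INLINE:
                abs_start = span.start - 1 + loc.start
                abs_end = span.start - 1 + loc.end
            else:
                abs_start = span.end - loc.end + 1
                abs_end = span.end - loc.start + 1
            orient = _compose(span.orientation, loc.orientation)
            abs_loc = RangeLocation(start=abs_start, end=abs_end, orientation=orient)
            annotations.append(Annotation(
                display_id=f"{use.instance_id}_ann_{len(annotations)}",
                name=child.name or child.display_id,
                roles=set(child.roles),
                location=abs_loc,
            ))
            walk(child, abs_loc, visiting | {record.display_id})

    top_span = RangeLocation(start=1, end=len(elements), orientation=INLINE)
    if design.subcomponents:
        walk(design, top_span, set())
    # existing standalone annotations carry over verbatim (flattening is stable)
    for a in design.annotations:
        annotations.append(Annotation(
            display_id=a.display_id, name=a.name, roles=set(a.roles),
            location=RangeLocation(a.location.start, a.location.end,
                                   a.location.orientation),
        ))
    annotations.sort(key=lambda a: (a.location.start, -a.location.length,
                                    a.display_id))

    flat_id = f"{design_id}_flat"
    seq = SequenceRecord(display_id=f"{flat_id}_seq", elements=elements)
    flat = ComponentRecord(
        display_id=flat_id,
        name=design.name,
        description=design.description,
        notes=design.notes,
        creators=list(design.creators),
        roles=set(design.roles),
        types=set(design.types),
        annotations=annotations,
        sequence_ref=seq.display_id,
    )
    return flat, seq


def flatten_to_document(design_id: str, doc: SbolDocument,
                        uri_prefix: str | None = None) -> SbolDocument:
    """Flatten and emit the result as a new single-record document."""
    flat, seq = flatten_design(design_id, doc)
    out = SbolDocument(uri_prefix=uri_prefix or doc.uri_prefix)
    out.add_sequence(seq)
    out.add_component(flat)
    return out
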