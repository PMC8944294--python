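"""GENERATE: instantiate a library of concrete designs from an abstract template.

A template ComponentDefinition carries fixed backbone parts (with sequences)
and generic slots (subcomponents whose child has no sequence). Each metadata
row yields one new design: a copy of the template in which every generic slot
is filled with a freshly minted child component + sequence holding the row's
DNA for the matching column, descriptive metadata is set from the row (after
``{placeholder}`` interpolation), contiguous Range locations are laid out over
the children, and a full concatenated sequence is attached so the design
renders with complete sequence content.
"""

from __future__ import annotations

import logging

from .model import (
    ComponentRecord,
    INLINE,
    RangeLocation,
    SbolDocument,
    SbolError,
    SequenceRecord,
    SubcomponentUse,
    is_iupac_dna,
    topological_child_order,
)
from .tableio import KEYWORD_COLUMNS, MetadataRow, MetadataTable, interpolate

__all__ = ["BindingError", "generate_library", "layout_ranges", "template_slots"]

log = logging.getLogger(__name__)

_IGNORED = set(KEYWORD_COLUMNS)


class BindingError(SbolError):
    """A table row does not bind cleanly onto the template's slots."""


def template_slots(template: ComponentRecord, doc: SbolDocument) -> list[SubcomponentUse]:
    """The template's generic slots (children lacking a sequence), in layout order."""
    return [u for u in topological_child_order(template) if u.is_generic]


def _set_metadata(design: ComponentRecord, row: MetadataRow) -> None:
    def rendered(column: str):
        value = row.get(column)
        return interpolate(value, row) if value is not None else None

    name = rendered("name")
    if name is not None:
        design.name = name
    description = rendered("description")
    if description is not None:
        design.description = description
    notes = rendered("notes")
    if notes is not None:
        design.notes = notes
    author = rendered("author")
    if author is not None:
        design.creators = [a.strip() for a in author.split(";") if a.strip()]
    version = row.get("version")
    if version is not None:
        design.version = version


def generate_library(
    template_doc: SbolDocument,
    template_id: str,
    table: MetadataTable,
    uri_prefix: str,
) -> SbolDocument:
    """One concrete design per table row, plus the untouched template parts.

    Raises :class:`BindingError` when a row supplies a sequence for an unknown
    slot or lacks one for a generic slot, and a validation error on non-IUPAC
    DNA content.
    """
    template = template_doc.find_component(template_id)
    if template is None:
        raise SbolError(f"template {template_id!r} not found in document")

    slots = template_slots(template, template_doc)
    slot_ids = [u.instance_id for u in slots]
    for use in template.subcomponents:
        if not use.is_generic:
            child = template_doc.resolve_child(use)
            if child is None or template_doc.sequence_of(child) is None:
                raise SbolError(
                    f"template part {use.instance_id!r} has no concrete sequence"
                )

    out = SbolDocument(uri_prefix=uri_prefix)
    out.namespaces = dict(template_doc.namespaces)
    # carry over the template and everything it references, unmodified
    for c in template_doc.components:
        out.components.append(c)
    for s in template_doc.sequences:
        out.sequences.append(s)
    out.foreign_properties |= set(template_doc.foreign_properties)

    unknown_warned: set[str] = set()
    for row in table:
        extra = set(row.subcomponent_sequences) - set(slot_ids)
        if extra:
            raise BindingError(
                f"row {row.display_id!r} provides sequences for unknown slot(s) "
                f"{sorted(extra)}; template slots are {slot_ids}"
            )
        missing = [s for s in slot_ids if s not in row.subcomponent_sequences]
        if missing:
            raise BindingError(
                f"row {row.display_id!r} is missing a sequence for slot(s) {missing}"
            )
        for col in row.values:
            if col not in _IGNORED and col not in row.subcomponent_sequences and \
                    col not in unknown_warned:
                log.warning("ignoring unrecognized metadata column %r", col)
                unknown_warned.add(col)

        design = ComponentRecord(
            display_id=row.display_id,
            roles=set(template.roles),
            types=set(template.types),
        )
        _set_metadata(design, row)

        override_ok = len(slots) == 1
        if (row.subcomponent_id_override or row.subcomponent_name_override) and not override_ok:
            log.warning(
                "row %s: SUBCOMPONENT_id/SUBCOMPONENT_name ignored (template has "
                "%d generic slots)", row.display_id, len(slots))

        for use in topological_child_order(template):
            if use.is_generic:
                seq_text = row.subcomponent_sequences[use.instance_id]
                if not is_iupac_dna(seq_text):
                    raise SbolError(
                        f"row {row.display_id!r}, column {use.instance_id!r}: "
                        "invalid DNA characters"
                    )
                local = use.instance_id
                if override_ok and row.subcomponent_id_override:
                    local = row.subcomponent_id_override
                child_id = f"{row.display_id}_{local}"
                template_child = template_doc.resolve_child(use)
                child = ComponentRecord(
                    display_id=child_id,
                    roles=set(template_child.roles) if template_child else set(),
                    types=set(template_child.types) if template_child else set(),
                    name=row.subcomponent_name_override if override_ok else None,
                )
                child.sequence_ref = out.add_sequence(
                    SequenceRecord(display_id=f"{child_id}_seq", elements=seq_text)
                ).display_id
                out.add_component(child)
                design.subcomponents.append(
                    SubcomponentUse(instance_id=local, child_ref=child_id)
                )
            else:
                design.subcomponents.append(
                    SubcomponentUse(instance_id=use.instance_id, child_ref=use.child_ref)
                )
        layout_ranges(design, out)
        full = "".join(
            out.sequence_of(out.resolve_child(u)).elements
            for u in design.subcomponents
        )
        design.sequence_ref = out.add_sequence(
            SequenceRecord(display_id=f"{row.display_id}_seq", elements=full)
        ).display_id
        out.add_component(design)
    return out


def layout_ranges(design: ComponentRecord, doc: SbolDocument) -> ComponentRecord:
    """Assign contiguous 1-based Ranges to the design's children in layout order.

    Child k starts at 1 + sum of the lengths of children 1..k-1; orientations
    default to inline.
    """
    ordered = topological_child_order(design)
    pos = 1
    for use in ordered:
        child = doc.resolve_child(use)
        seq = doc.sequence_of(child) if child else None
        if seq is None:
            raise SbolError(
                f"child {use.instance_id!r} of {design.display_id} has no sequence; "
                "cannot lay out Ranges"
            )
        length = len(seq.elements)
        if length == 0:
            raise SbolError(
                f"child {use.instance_id!r} of {design.display_id} has an empty sequence"
            )
        use.location = RangeLocation(start=pos, end=pos + length - 1, orientation=INLINE)
        pos += length
    design.subcomponents = ordered
    return design
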