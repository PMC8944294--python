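"""In-memory data model for SBOL2 genetic designs.

The model covers the entities that batch operations act on — ComponentDefinitions,
Sequences and Collections — as plain dataclasses, while every RDF triple that does
not map onto a typed field is retained verbatim (``extra_properties`` on an entity,
``foreign_properties`` on the document) so that documents round-trip losslessly
through read/write.

Only SBOL2 is supported; coordinates follow the SBOL2 convention of 1-based
inclusive ``Range`` start/end positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "INLINE",
    "REVERSE_COMPLEMENT",
    "IUPAC_DNA",
    "SbolError",
    "ValidationError",
    "RangeLocation",
    "Annotation",
    "SubcomponentUse",
    "ComponentRecord",
    "SequenceRecord",
    "CollectionRecord",
    "SbolDocument",
    "is_valid_display_id",
    "is_iupac_dna",
]

INLINE = "inline"
REVERSE_COMPLEMENT = "reverse_complement"

#: IUPAC nucleotide codes (unambiguous + ambiguity codes + gap-free)
IUPAC_DNA = set("ACGTURYSWKMBDHVN")

_DISPLAY_ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class SbolError(Exception):
    """Base class for errors raised by sbolbatch."""


class ValidationError(SbolError):
    """An entity violates a model invariant."""


def is_valid_display_id(token: str) -> bool:
    return bool(_DISPLAY_ID_RE.match(token or ""))


def is_iupac_dna(seq: str) -> bool:
    return all(c.upper() in IUPAC_DNA for c in seq)


@dataclass
class RangeLocation:
    """1-based inclusive span on a parent sequence with an orientation."""

    start: int
    end: int
    orientation: str = INLINE

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"Range requires 1 <= start <= end, got [{self.start}, {self.end}]"
            )
        if self.orientation not in (INLINE, REVERSE_COMPLEMENT):
            raise ValidationError(f"unknown orientation {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Annotation:
    """A standalone sequence annotation (label + roles placed on a Range).

    Used for annotations that do not instantiate a subcomponent, notably the
    feature set of a flattened design.
    """

    display_id: str
    location: RangeLocation
    name: Optional[str] = None
    roles: set[str] = field(default_factory=set)


@dataclass
class SubcomponentUse:
    """A child component instantiation inside a ComponentDefinition.

    ``child_ref`` is the display_id of a component in the same document, or a
    bare URI when the definition is not present (a dangling reference).
    ``is_generic`` marks template slots: children that carry no sequence.
    Identity fields are populated on read so written output preserves the
    original URIs of Component / SequenceAnnotation / Range nodes.
    """

    instance_id: str
    child_ref: str
    location: Optional[RangeLocation] = None
    is_generic: bool = False
    identity: Optional[str] = None
    sa_identity: Optional[str] = None
    range_identity: Optional[str] = None


@dataclass
class ComponentRecord:
    """One SBOL2 ComponentDefinition."""

    display_id: str
    version: str = "1"
    name: Optional[str] = None
    description: Optional[str] = None
    notes: Optional[str] = None
    creators: list[str] = field(default_factory=list)
    roles: set[str] = field(default_factory=set)
    types: set[str] = field(default_factory=set)
    subcomponents: list[SubcomponentUse] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)
    #: (subject_instance_id, object_instance_id[, identity URI]) "precedes" constraints
    constraints: list[tuple] = field(default_factory=list)
    sequence_ref: Optional[str] = None
    identity: Optional[str] = None
    extra_properties: list[tuple[str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not is_valid_display_id(self.display_id):
            raise ValidationError(f"invalid display_id {self.display_id!r}")

    def validate(self) -> None:
        seen: set[str] = set()
        for use in self.subcomponents:
            if use.instance_id in seen:
                raise ValidationError(
                    f"duplicate subcomponent id {use.instance_id!r} in {self.display_id}"
                )
            seen.add(use.instance_id)

    def find_use(self, instance_id: str) -> Optional[SubcomponentUse]:
        for use in self.subcomponents:
            if use.instance_id == instance_id:
                return use
        return None


@dataclass
class SequenceRecord:
    """An SBOL2 Sequence holding IUPAC DNA elements."""

    display_id: str
    elements: str
    version: str = "1"
    identity: Optional[str] = None
    extra_properties: list[tuple[str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not is_valid_display_id(self.display_id):
            raise ValidationError(f"invalid display_id {self.display_id!r}")
        if not is_iupac_dna(self.elements):
            bad = next(i for i, c in enumerate(self.elements) if c.upper() not in IUPAC_DNA)
            raise ValidationError(
                f"sequence {self.display_id}: non-IUPAC character "
                f"{self.elements[bad]!r} at position {bad + 1}"
            )


@dataclass
class CollectionRecord:
    """An SBOL2 Collection grouping member URIs."""

    display_id: str
    version: str = "1"
    name: Optional[str] = None
    description: Optional[str] = None
    member_uris: list[str] = field(default_factory=list)
    identity: Optional[str] = None
    extra_properties: list[tuple[str, object]] = field(default_factory=list)

    def validate(self) -> None:
        if len(set(self.member_uris)) != len(self.member_uris):
            raise ValidationError(f"collection {self.display_id}: duplicate member URIs")


@dataclass
class SbolDocument:
    """A set of top-level SBOL2 entities plus pass-through foreign triples."""

    uri_prefix: str = "https://example.org/design"
    components: list[ComponentRecord] = field(default_factory=list)
    sequences: list[SequenceRecord] = field(default_factory=list)
    collections: list[CollectionRecord] = field(default_factory=list)
    #: triples (subject URI, predicate URI, rdflib term) not owned by a typed field
    foreign_properties: set[tuple] = field(default_factory=set)
    namespaces: dict[str, str] = field(default_factory=dict)

    # -- lookup ------------------------------------------------------------
    # display_id indices are rebuilt lazily when entity counts change; call
    # reindex() after mutating display_ids in place
    def reindex(self) -> None:
        self.__dict__["_comp_idx"] = {c.display_id: c for c in self.components}
        self.__dict__["_seq_idx"] = {s.display_id: s for s in self.sequences}

    def _lookup(self, kind: str, entities: list, display_id: str):
        idx = self.__dict__.get(kind)
        if idx is None or len(idx) != len(entities):
            self.reindex()
            idx = self.__dict__[kind]
        hit = idx.get(display_id)
        if hit is not None and hit.display_id != display_id:
            self.reindex()
            hit = self.__dict__[kind].get(display_id)
        return hit

    def find_component(self, display_id: str) -> Optional[ComponentRecord]:
        return self._lookup("_comp_idx", self.components, display_id)

    def find_sequence(self, display_id: str) -> Optional[SequenceRecord]:
        return self._lookup("_seq_idx", self.sequences, display_id)

    def resolve_child(self, use: SubcomponentUse) -> Optional[ComponentRecord]:
        return self.find_component(use.child_ref)

    def sequence_of(self, record: ComponentRecord) -> Optional[SequenceRecord]:
        if record.sequence_ref is None:
            return None
        return self.find_sequence(record.sequence_ref)

    # -- mutation ----------------------------------------------------------
    def add_component(self, record: ComponentRecord) -> ComponentRecord:
        if self.find_component(record.display_id):
            raise ValidationError(f"duplicate top-level display_id {record.display_id!r}")
        self.components.append(record)
        self.__dict__["_comp_idx"][record.display_id] = record
        return record

    def add_sequence(self, record: SequenceRecord) -> SequenceRecord:
        if self.find_sequence(record.display_id):
            raise ValidationError(f"duplicate sequence display_id {record.display_id!r}")
        self.sequences.append(record)
        self.__dict__["_seq_idx"][record.display_id] = record
        return record

    # -- identity minting --------------------------------------------------
    def persistent_identity(self, record) -> str:
        if record.identity:
            # strip trailing /<version> if present
            ident = record.identity
            suffix = "/" + record.version
            return ident[: -len(suffix)] if ident.endswith(suffix) else ident
        return f"{self.uri_prefix.rstrip('/')}/{record.display_id}"

    def identity_of(self, record) -> str:
        if record.identity:
            return record.identity
        return f"{self.persistent_identity(record)}/{record.version}"

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        ids = [e.display_id for e in (*self.components, *self.sequences, *self.collections)]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate top-level display_ids: {sorted(dupes)}")
        for c in self.components:
            c.validate()
            if c.sequence_ref is not None and self.find_sequence(c.sequence_ref) is None:
                raise ValidationError(
                    f"component {c.display_id}: dangling sequence reference {c.sequence_ref!r}"
                )
        for col in self.collections:
            col.validate()

    def root_components(self) -> list[ComponentRecord]:
        """Components never instantiated as a child of another component."""
        used = {
            use.child_ref for c in self.components for use in c.subcomponents
        }
        return [c for c in self.components if c.display_id not in used]


def topological_child_order(record: ComponentRecord) -> list[SubcomponentUse]:
    """Child order for layout: explicit Ranges, else precedes-constraints, else declaration.

    Raises ValidationError on a cyclic precedes graph.
    """
    uses = record.subcomponents
    if uses and all(u.location is not None for u in uses):
        return sorted(uses, key=lambda u: (u.location.start, u.location.end))
    if record.constraints:
        order = {u.instance_id: i for i, u in enumerate(uses)}
        succ: dict[str, set[str]] = {u.instance_id: set() for u in uses}
        indeg = {u.instance_id: 0 for u in uses}
        for a, b in ((t[0], t[1]) for t in record.constraints):
            if a in succ and b in succ and b not in succ[a]:
                succ[a].add(b)
                indeg[b] += 1
        ready = sorted([k for k, d in indeg.items() if d == 0], key=order.get)
        out: list[str] = []
        while ready:
            n = ready.pop(0)
            out.append(n)
            for m in sorted(succ[n], key=order.get):
                indeg[m] -= 1
                if indeg[m] == 0:
                    ready.append(m)
            ready.sort(key=order.get)
        if len(out) != len(uses):
            raise ValidationError(
                f"cyclic precedes constraints in {record.display_id}"
            )
        by_id = {u.instance_id: u for u in uses}
        return [by_id[i] for i in out]
    return list(uses)
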