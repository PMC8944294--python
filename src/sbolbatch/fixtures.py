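"""Seeded synthetic example data: template plasmids, library-definition
workbooks, hierarchical designs and repository-"dirty" documents.

These stand in for a real knockout-plasmid project's inputs: an abstract
template with homology-flank and barcode slots, and a spreadsheet with one row
per target gene supplying slot sequences plus descriptive metadata. Sequences
are uniform random A/C/G/T — deliberately not biologically realistic — with
per-slot lengths spanning the barcode (tens of nt) to homology-flank (hundreds
to ~1.2 kb) scale so that layout arithmetic is exercised across magnitudes.

Everything is deterministic given its seed, including workbook bytes.
"""

from __future__ import annotations

import datetime
import io
import random
import zipfile
import zlib
from pathlib import Path

import openpyxl

from .model import (
    ComponentRecord,
    INLINE,
    REVERSE_COMPLEMENT,
    RangeLocation,
    SbolDocument,
    SbolError,
    SequenceRecord,
    SubcomponentUse,
)
from .sbolio import SYNBIOHUB_TERMS_NS

__all__ = [
    "random_dna",
    "make_template",
    "make_library_table",
    "make_dirty_document",
    "make_hierarchical_design",
    "write_example_inputs",
]

DEFAULT_SLOTS = ("left", "barcode", "right")
DEFAULT_PREFIX = "https://example.org/library"

# ontology terms used on fixture parts
SO_ENGINEERED_REGION = "http://identifiers.org/so/SO:0000804"
SO_PLASMID = "http://identifiers.org/so/SO:0000155"
BIOPAX_DNA = "http://www.biopax.org/release/biopax-level3.owl#DnaRegion"

_FIXED_TIMESTAMP = datetime.datetime(2022, 1, 26, 0, 0, 0)


def random_dna(length: int, seed: int) -> str:
    """Uniform random A/C/G/T string; same (length, seed) -> same string."""
    if length < 0:
        raise ValueError(f"length must be non-negative, got {length}")
    rng = random.Random(f"dna:{seed}:{length}")
    return "".join(rng.choice("ACGT") for _ in range(length))


def _slot_length(row: int, slot: str, seed: int) -> int:
    rng = random.Random(f"len:{seed}:{row}:{slot}")
    if "barcode" in slot:
        return rng.randint(20, 40)
    return rng.randint(200, 1200)


def make_template(
    slots=DEFAULT_SLOTS,
    backbone_len: int = 2400,
    seed: int = 1,
    uri_prefix: str = DEFAULT_PREFIX,
) -> SbolDocument:
    """A template plasmid: concrete backbone parts interleaved with generic slots.

    The template ComponentDefinition is named ``plasmid_template``; slot
    children carry no sequence (``is_generic``), and child order is fixed by
    precedes constraints since slots have no Ranges yet.
    """
    slots = list(slots)
    if len(set(slots)) != len(slots):
        raise SbolError(f"duplicate slot ids: {slots}")
    doc = SbolDocument(uri_prefix=uri_prefix)
    n_parts = len(slots) + 1
    part_len = max(backbone_len // n_parts, 20)

    template = ComponentRecord(
        display_id="plasmid_template",
        name="Template plasmid",
        description="Abstract knockout-plasmid template with generic slots",
        roles={SO_PLASMID},
        types={BIOPAX_DNA},
    )
    order: list[str] = []
    for i in range(n_parts):
        part_id = f"backbone_part{i + 1}"
        seq = SequenceRecord(
            display_id=f"{part_id}_seq",
            elements=random_dna(part_len, seed=seed * 1000 + i),
        )
        doc.add_sequence(seq)
        doc.add_component(ComponentRecord(
            display_id=part_id,
            name=f"Backbone part {i + 1}",
            roles={SO_ENGINEERED_REGION},
            types={BIOPAX_DNA},
            sequence_ref=seq.display_id,
        ))
        template.subcomponents.append(
            SubcomponentUse(instance_id=part_id, child_ref=part_id))
        order.append(part_id)
        if i < len(slots):
            slot = slots[i]
            doc.add_component(ComponentRecord(
                display_id=slot,
                name=f"Generic {slot} slot",
                roles={SO_ENGINEERED_REGION},
                types={BIOPAX_DNA},
            ))
            template.subcomponents.append(
                SubcomponentUse(instance_id=slot, child_ref=slot, is_generic=True))
            order.append(slot)
    template.constraints = [(a, b) for a, b in zip(order, order[1:])]
    doc.add_component(template)
    return doc


def _save_workbook_deterministic(wb: openpyxl.Workbook, path: Path) -> Path:
    """Save a workbook with byte-stable output (fixed timestamps, stable zip)."""
    wb.properties.created = _FIXED_TIMESTAMP
    wb.properties.modified = _FIXED_TIMESTAMP
    buf = io.BytesIO()
    wb.save(buf)
    buf.seek(0)
    with zipfile.ZipFile(buf) as src, path.open("wb") as out_handle:
        with zipfile.ZipFile(out_handle, "w", zipfile.ZIP_DEFLATED) as dst:
            for name in sorted(src.namelist()):
                info = zipfile.ZipInfo(name, date_time=(2022, 1, 26, 0, 0, 0))
                info.compress_type = zipfile.ZIP_DEFLATED
                dst.writestr(info, src.read(name))
    return path


def make_library_table(
    n_rows: int,
    slots=DEFAULT_SLOTS,
    seed: int = 1,
    path=None,
) -> Path:
    """A library-definition workbook: one row per target gene.

    display_ids follow ``cs{row:04d}_gene{row}``; every row provides author,
    name and notes, every third row a description carrying a ``{display_id}``
    placeholder, and one DNA column per slot with seeded random sequences.
    """
    if n_rows < 0:
        raise ValueError("n_rows must be non-negative")
    path = Path(path) if path else Path("lib_def.xlsx")
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "library"
    headers = ["display_id", "author", "name", "notes", "description", *slots]
    ws.append(headers)
    for row in range(1, n_rows + 1):
        display_id = f"cs{row:04d}_gene{row}"
        description = (
            "Attachment {display_id}.xls contains activity data"
            if row % 3 == 0
            else f"Knockout plasmid targeting gene{row}"
        )
        values = [
            display_id,
            "A. Researcher",
            f"Knockout plasmid {row}",
            "stage 1: designed",
            description,
        ]
        for slot in slots:
            slot_tag = zlib.crc32(slot.encode()) % 97
            values.append(random_dna(_slot_length(row, slot, seed),
                                     seed=seed * 1000000 + row * 100 + slot_tag))
        ws.append(values)
    return _save_workbook_deterministic(wb, path)


def make_dirty_document(
    n_components: int,
    seed: int = 1,
    server_prefix: str = "https://synbiohub.example.org/user/demo",
) -> SbolDocument:
    """A document as downloaded from a repository: server-rooted identities and
    repository bookkeeping properties under the SynBioHub terms namespace."""
    if n_components < 0:
        raise ValueError("n_components must be non-negative")
    doc = SbolDocument(uri_prefix=server_prefix)
    doc.namespaces["sbh"] = SYNBIOHUB_TERMS_NS
    for i in range(1, n_components + 1):
        display_id = f"design_{i}"
        seq = SequenceRecord(
            display_id=f"{display_id}_seq",
            elements=random_dna(60 + i, seed=seed * 500 + i),
            identity=f"{server_prefix}/{display_id}_seq/1",
        )
        doc.add_sequence(seq)
        rec = ComponentRecord(
            display_id=display_id,
            name=f"Downloaded design {i}",
            description="As retrieved from the repository",
            types={BIOPAX_DNA},
            sequence_ref=seq.display_id,
            identity=f"{server_prefix}/{display_id}/1",
        )
        rec.extra_properties = [
            (SYNBIOHUB_TERMS_NS + "ownedBy", server_prefix),
            (SYNBIOHUB_TERMS_NS + "topLevel", f"{server_prefix}/{display_id}/1"),
        ]
        doc.add_component(rec)
    return doc


def make_hierarchical_design(
    seed: int,
    max_depth: int = 3,
    uri_prefix: str = DEFAULT_PREFIX,
) -> tuple[SbolDocument, str]:
    """A random 2–3 level design with Range locations, for flatten testing.

    Composite children have no sequence of their own (their content must be
    assembled recursively); leaves carry concrete sequences. Orientations are
    drawn at random. Returns (document, top design display_id).
    """
    rng = random.Random(f"tree:{seed}")
    doc = SbolDocument(uri_prefix=uri_prefix)
    counter = [0]

    def build(depth: int) -> ComponentRecord:
        counter[0] += 1
        my_id = f"node{counter[0]}"
        rec = ComponentRecord(display_id=my_id, name=f"Part {counter[0]}",
                              types={BIOPAX_DNA})
        n_children = rng.randint(2, 4)
        pos = 1
        for _ in range(n_children):
            composite = depth + 1 < max_depth and rng.random() < 0.4
            if composite:
                child = build(depth + 1)
                child_len = _record_length(child, doc)
            else:
                counter[0] += 1
                child = ComponentRecord(display_id=f"node{counter[0]}",
                                        name=f"Part {counter[0]}",
                                        types={BIOPAX_DNA})
                seq = SequenceRecord(
                    display_id=f"{child.display_id}_seq",
                    elements="".join(rng.choice("ACGT")
                                     for _ in range(rng.randint(3, 40))),
                )
                doc.add_sequence(seq)
                child.sequence_ref = seq.display_id
                child_len = len(seq.elements)
                doc.add_component(child)
            orientation = REVERSE_COMPLEMENT if rng.random() < 0.4 else INLINE
            rec.subcomponents.append(SubcomponentUse(
                instance_id=f"{child.display_id}_in_{my_id}",
                child_ref=child.display_id,
                location=RangeLocation(start=pos, end=pos + child_len - 1,
                                       orientation=orientation),
            ))
            pos += child_len
        doc.add_component(rec)
        return rec

    top = build(0)
    return doc, top.display_id


def _record_length(rec: ComponentRecord, doc: SbolDocument) -> int:
    seq = doc.sequence_of(rec)
    if seq is not None:
        return len(seq.elements)
    return sum(u.location.length for u in rec.subcomponents)


def write_example_inputs(workdir, n_rows: int = 5, seed: int = 1) -> dict[str, Path]:
    """Scaffold example input files (template, library table, dirty document)."""
    from .sbolio import write_sbol

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    template_path = write_sbol(make_template(seed=seed), workdir / "lib_template.xml")
    table_path = make_library_table(n_rows, seed=seed, path=workdir / "lib_def.xlsx")
    dirty_path = write_sbol(make_dirty_document(3, seed=seed), workdir / "downloaded.xml")
    return {"template": template_path, "table": table_path, "dirty": dirty_path}
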