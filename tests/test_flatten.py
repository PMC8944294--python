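"""Flattening hierarchical designs onto one annotated linear sequence.

The randomized checks compare the implementation against an independent
oracle that works by coordinate-transform composition: each leaf base's
absolute position is computed by folding the affine position maps of its
ancestor chain (inline: x -> P-1+x; reverse_complement: x -> Q-x+1 with a
complement toggle), which is a different formulation from the string
concatenation the implementation uses.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbolbatch import fixtures
from sbolbatch.flatten import (
    StructureError,
    flatten_design,
    reverse_complement,
)
from sbolbatch.model import (
    ComponentRecord,
    INLINE,
    REVERSE_COMPLEMENT,
    RangeLocation,
    SbolDocument,
    SbolError,
    SequenceRecord,
    SubcomponentUse,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# -- reverse_complement -----------------------------------------------------

@pytest.mark.parametrize("seq,expected", [
    ("", ""),
    ("AAAC", "GTTT"),
    ("acgt", "acgt"),
    ("ARYN", "NRYT"),
])
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


def test_reverse_complement_rejects_non_iupac():
    with pytest.raises(SbolError, match="position 3"):
        reverse_complement("ACXG")


@settings(derandomize=True, max_examples=200)
@given(st.text(alphabet="ACGTRYSWKMBDHVNacgt", max_size=60))
def test_reverse_complement_is_an_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


# -- worked examples --------------------------------------------------------

def _doc():
    return SbolDocument()


def _leaf(doc, display_id, elements):
    doc.add_sequence(SequenceRecord(display_id=f"{display_id}_seq", elements=elements))
    return doc.add_component(ComponentRecord(display_id=display_id,
                                             name=display_id,
                                             sequence_ref=f"{display_id}_seq"))


def _use(parent, child, start, end, orientation=INLINE):
    parent.subcomponents.append(SubcomponentUse(
        instance_id=f"{child.display_id}_in_{parent.display_id}",
        child_ref=child.display_id,
        location=RangeLocation(start, end, orientation),
    ))


def test_design_without_subcomponents_flattens_to_identity():
    doc = _doc()
    _leaf(doc, "solo", "ACGTACGT")
    flat, seq = flatten_design("solo", doc)
    assert seq.elements == "ACGTACGT"
    assert flat.display_id == "solo_flat"
    assert flat.annotations == []


def test_two_level_offsets_follow_ancestor_chain():
    """top = A@[1,4] + B@[5,10]; B = C@[1,3] + D@[4,6] -> C@[5,7], D@[8,10]."""
    doc = _doc()
    a = _leaf(doc, "A", "AAAA")
    c = _leaf(doc, "C", "CCC")
    d = _leaf(doc, "D", "GGG")
    b = doc.add_component(ComponentRecord(display_id="B", name="B"))
    _use(b, c, 1, 3)
    _use(b, d, 4, 6)
    top = doc.add_component(ComponentRecord(display_id="top"))
    _use(top, a, 1, 4)
    _use(top, b, 5, 10)
    flat, seq = flatten_design("top", doc)
    spans = {a.name: (a.location.start, a.location.end) for a in flat.annotations}
    assert spans == {"A": (1, 4), "B": (5, 10), "C": (5, 7), "D": (8, 10)}
    assert seq.elements == "AAAACCCGGG"
    assert len(flat.annotations) == 4


def test_reverse_complement_tile_in_assembly():
    """Child "AAAC" placed at [3,6] reverse_complement reads GTTT there."""
    doc = _doc()
    x = _leaf(doc, "X", "GG")
    y = _leaf(doc, "Y", "AAAC")
    top = doc.add_component(ComponentRecord(display_id="top"))
    _use(top, x, 1, 2)
    _use(top, y, 3, 6, REVERSE_COMPLEMENT)
    _, seq = flatten_design("top", doc)
    assert seq.elements[2:6] == "GTTT"


def test_nested_reverse_complement_orientations_compose():
    """rc-in-rc composes to inline; coordinates flip within the parent span."""
    doc = _doc()
    c = _leaf(doc, "C", "ACG")
    d = _leaf(doc, "D", "TT")
    b = doc.add_component(ComponentRecord(display_id="B", name="B"))
    _use(b, c, 1, 3, REVERSE_COMPLEMENT)
    _use(b, d, 4, 5)
    top = doc.add_component(ComponentRecord(display_id="top"))
    _use(top, b, 1, 5, REVERSE_COMPLEMENT)
    flat, seq = flatten_design("top", doc)
    ann = {a.name: a for a in flat.annotations}
    # B spans everything, reverse_complement
    assert (ann["B"].location.start, ann["B"].location.end) == (1, 5)
    assert ann["B"].location.orientation == REVERSE_COMPLEMENT
    # C: relative [1,3] rc inside an rc parent spanning [1,5] -> [3,5] inline
    assert (ann["C"].location.start, ann["C"].location.end) == (3, 5)
    assert ann["C"].location.orientation == INLINE
    # D: relative [4,5] inline inside rc parent -> [1,2] rc
    assert (ann["D"].location.start, ann["D"].location.end) == (1, 2)
    assert ann["D"].location.orientation == REVERSE_COMPLEMENT
    # sequence: rc(assembled B) = rc(rc("ACG") + "TT") = rc("CGTTT") = "AAACG"
    assert seq.elements == "AAACG"
    assert seq.elements[2:5] == "ACG"  # C inline at [3,5]


# -- error contracts --------------------------------------------------------

def test_missing_range_location_rejected():
    doc = _doc()
    x = _leaf(doc, "X", "ACGT")
    top = doc.add_component(ComponentRecord(display_id="top"))
    top.subcomponents.append(SubcomponentUse(instance_id="x", child_ref="X"))
    with pytest.raises(StructureError, match="Range"):
        flatten_design("top", doc)


def test_abstract_leaf_rejected():
    doc = _doc()
    doc.add_component(ComponentRecord(display_id="ghost"))
    top = doc.add_component(ComponentRecord(display_id="top"))
    top.subcomponents.append(SubcomponentUse(
        instance_id="g", child_ref="ghost", location=RangeLocation(1, 4)))
    with pytest.raises(StructureError, match="abstract|ghost"):
        flatten_design("top", doc)


def test_gap_and_overlap_in_assembly_rejected():
    doc = _doc()
    x = _leaf(doc, "X", "AC")
    y = _leaf(doc, "Y", "GT")
    top = doc.add_component(ComponentRecord(display_id="top"))
    _use(top, x, 1, 2)
    _use(top, y, 4, 5)  # gap at position 3
    with pytest.raises(StructureError, match="gap"):
        flatten_design("top", doc)
    top.subcomponents[1].location = RangeLocation(2, 3)  # overlap
    with pytest.raises(StructureError, match="overlap"):
        flatten_design("top", doc)


def test_cyclic_containment_detected():
    doc = _doc()
    a = doc.add_component(ComponentRecord(display_id="a"))
    b = doc.add_component(ComponentRecord(display_id="b"))
    a.subcomponents.append(SubcomponentUse("b_in_a", "b", RangeLocation(1, 4)))
    b.subcomponents.append(SubcomponentUse("a_in_b", "a", RangeLocation(1, 4)))
    with pytest.raises(StructureError, match="cyclic"):
        flatten_design("a", doc)


# -- randomized oracle equivalence ------------------------------------------

def oracle_flatten(doc, design_id):
    """Per-base coordinate-transform oracle; see module docstring."""
    design = doc.find_component(design_id)

    placements = []  # (abs_pos, char)
    spans = {}  # child name -> (start, end, orientation)

    def visit(record, transform, complemented):
        for use in record.subcomponents:
            loc = use.location
            child = doc.find_component(use.child_ref)
            ends = sorted([transform(loc.start), transform(loc.end)])
            child_flip = complemented ^ (loc.orientation == REVERSE_COMPLEMENT)
            spans[child.name] = (
                ends[0], ends[1],
                REVERSE_COMPLEMENT if child_flip else INLINE,
            )
            # the local coordinate map depends on how the child is placed in
            # its parent; the cumulative flip only decides complementation
            if loc.orientation == REVERSE_COMPLEMENT:
                t = lambda x, T=transform, e=loc.end: T(e - x + 1)
            else:
                t = lambda x, T=transform, s=loc.start: T(s - 1 + x)
            seq = doc.sequence_of(child)
            if seq is not None and not child.subcomponents:
                for i, ch in enumerate(seq.elements.upper(), start=1):
                    placements.append(
                        (t(i), _COMP[ch] if child_flip else ch))
            else:
                visit(child, t, child_flip)

    visit(design, lambda x: x, False)
    placements.sort()
    assert [p for p, _ in placements] == list(range(1, len(placements) + 1))
    return "".join(ch for _, ch in placements), spans


@pytest.mark.parametrize("seed", range(40))
def test_flatten_matches_coordinate_transform_oracle(seed):
    doc, top = fixtures.make_hierarchical_design(seed=seed)
    flat, seq = flatten_design(top, doc)
    expected_seq, expected_spans = oracle_flatten(doc, top)
    assert seq.elements.upper() == expected_seq
    got = {a.name: (a.location.start, a.location.end, a.location.orientation)
           for a in flat.annotations}
    assert got == expected_spans
    # every annotation stays inside the flat sequence
    for a in flat.annotations:
        assert 1 <= a.location.start <= a.location.end <= len(seq.elements)


def test_annotation_count_equals_descendant_uses():
    doc, top = fixtures.make_hierarchical_design(seed=11)
    total_uses = sum(len(c.subcomponents) for c in doc.components)
    flat, _ = flatten_design(top, doc)
    assert len(flat.annotations) == total_uses


def test_flattening_a_flat_design_is_stable():
    doc, top = fixtures.make_hierarchical_design(seed=5)
    flat, seq = flatten_design(top, doc)
    doc2 = SbolDocument()
    doc2.add_sequence(seq)
    doc2.add_component(flat)
    flat2, seq2 = flatten_design(flat.display_id, doc2)
    assert seq2.elements == seq.elements
    assert [(a.location.start, a.location.end, a.location.orientation)
            for a in flat2.annotations] == \
           [(a.location.start, a.location.end, a.location.orientation)
            for a in flat.annotations]
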