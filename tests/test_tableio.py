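"""Excel parsing, the minimal formula evaluator, and {placeholder} templating."""

import openpyxl
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbolbatch.tableio import (
    FormulaError,
    InterpolationError,
    MetadataRow,
    TableError,
    eval_cell,
    interpolate,
    read_table,
    write_table,
)


def _workbook(tmp_path, rows, name="t.xlsx"):
    wb = openpyxl.Workbook()
    ws = wb.active
    for row in rows:
        ws.append(row)
    path = tmp_path / name
    wb.save(path)
    return path


# -- read_table -------------------------------------------------------------

def test_header_only_sheet_yields_zero_rows(tmp_path):
    path = _workbook(tmp_path, [["display_id", "name"]])
    table = read_table(path)
    assert len(table) == 0
    assert table.columns == ["display_id", "name"]


def test_keyword_columns_are_canonicalized_and_populated(tmp_path):
    path = _workbook(tmp_path, [
        ["Display_ID", "Author", " Name", "notes"],
        ["d1", "J. Doe", "first", "to do"],
        ["d2", "A. Poe", "second", "done"],
    ])
    table = read_table(path)
    assert [r.display_id for r in table] == ["d1", "d2"]
    assert table.rows[0].values == {"author": "J. Doe", "name": "first",
                                    "notes": "to do"}


def test_dna_column_classified_as_subcomponent_sequence(tmp_path):
    path = _workbook(tmp_path, [
        ["display_id", "barcode", "comment_col"],
        ["d1", "ACGTAC", "not dna"],
        ["d2", "TTGGCC", "words"],
    ])
    table = read_table(path)
    assert table.rows[0].subcomponent_sequences == {"barcode": "ACGTAC"}
    assert "comment_col" in table.rows[0].values


def test_missing_display_id_column_is_schema_error(tmp_path):
    path = _workbook(tmp_path, [["name"], ["x"]])
    with pytest.raises(TableError, match="display_id"):
        read_table(path)


def test_duplicate_display_id_names_both_rows(tmp_path):
    path = _workbook(tmp_path, [["display_id"], ["dup"], ["dup"]])
    with pytest.raises(TableError, match=r"rows 2 and 3"):
        read_table(path)


def test_trailing_empty_rows_dropped_and_numbers_unpadded(tmp_path):
    path = _workbook(tmp_path, [
        ["display_id", "version"],
        ["d1", 42.0],
        [None, None],
    ])
    table = read_table(path)
    assert len(table) == 1
    assert table.rows[0].values["version"] == "42"


def test_subcomponent_override_columns_extracted(tmp_path):
    path = _workbook(tmp_path, [
        ["display_id", "SUBCOMPONENT_id", "SUBCOMPONENT_name"],
        ["d1", "my_slot", "My slot"],
    ])
    row = read_table(path).rows[0]
    assert row.subcomponent_id_override == "my_slot"
    assert row.subcomponent_name_override == "My slot"


# -- formulas ---------------------------------------------------------------

def test_concatenate_with_absolute_reference(tmp_path):
    """CONCATENATE($B$2, "is a PCR file") resolves through the referenced cell."""
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.append(["display_id", "attachment", "notes"])
    ws.append(["pcr_001", "pcr_001.fsa", '=CONCATENATE($B$2, "is a PCR file")'])
    path = tmp_path / "f.xlsx"
    wb.save(path)
    table = read_table(path)
    assert table.rows[0].values["notes"] == "pcr_001.fsais a PCR file"


@pytest.mark.parametrize(
    "formula,expected",
    [
        ('=CONCATENATE("a", CONCATENATE("b","c"))', "abc"),
        ('=CONCATENATE("a"; "b")', "ab"),
        ('="solo"', "solo"),
        ('=CONCATENATE("x", 1)', "x1"),
        ('=CONCATENATE()', ""),
        ('=CONCATENATE("he said ""hi""")', 'he said "hi"'),
    ],
)
def test_formula_evaluator(formula, expected):
    assert eval_cell(formula, lambda c, r: None) == expected


def test_cell_reference_resolves_recursively():
    cells = {("B", 2): "pcr_001", ("C", 2): "=CONCATENATE($B$2, \"!\")"}
    ctx = lambda c, r: cells.get((c, r))
    assert eval_cell("=CONCATENATE(C2, \"?\")", ctx) == "pcr_001!?"


def test_unsupported_function_without_cache_errors_with_address():
    with pytest.raises(FormulaError, match="VLOOKUP"):
        eval_cell("=VLOOKUP(A1,B:C,2)", lambda c, r: None, address="D4")


def test_cached_value_preferred_over_evaluation():
    assert eval_cell("=SUM(A1:A3)", lambda c, r: None, cached=6) == "6"


@pytest.mark.parametrize("literal,expected", [
    ("hello", "hello"), (42.0, "42"), (1.5, "1.5"), (None, ""), (7, "7"),
])
def test_literals_render_as_plain_text(literal, expected):
    assert eval_cell(literal) == expected


# -- interpolation ----------------------------------------------------------

def _row(display_id="x", **values):
    return MetadataRow(display_id=display_id, values=values)


def test_display_id_placeholder_substitution():
    row = _row("cs0002_slr0612_codA")
    out = interpolate("Attachment {display_id}.xls contains activity data", row)
    assert out == "Attachment cs0002_slr0612_codA.xls contains activity data"


def test_interpolate_plain_text_unchanged():
    assert interpolate("no braces here", _row()) == "no braces here"


def test_interpolate_repeated_placeholder():
    assert interpolate("{display_id}-{display_id}", _row("x")) == "x-x"


def test_interpolate_any_column_and_unknown_placeholder_error():
    row = _row("d", name="thing")
    assert interpolate("a {name}", row) == "a thing"
    with pytest.raises(InterpolationError, match="absent"):
        interpolate("{nope}", row)


@settings(derandomize=True, max_examples=50)
@given(st.text(alphabet=st.characters(blacklist_characters="{}"), max_size=30))
def test_interpolation_idempotent_on_brace_free_values(text):
    row = MetadataRow(display_id="d", values={"name": "plain value"})
    once = interpolate(text + "{name}", row)
    assert interpolate(once, row) == once


# -- write_table ------------------------------------------------------------

def test_write_read_round_trip(tmp_path):
    records = [
        ("d1", {"name": "first", "notes": "n1"}),
        ("d2", {"description": "second"}),
    ]
    path = write_table(records, tmp_path / "out.xlsx")
    table = read_table(path)
    assert [r.display_id for r in table] == ["d1", "d2"]
    assert table.rows[0].values["name"] == "first"
    assert table.rows[1].values["description"] == "second"
    assert "attachment" in table.columns


def test_empty_record_list_writes_header_only(tmp_path):
    path = write_table([], tmp_path / "out.xlsx")
    assert len(read_table(path)) == 0


def test_leading_equals_written_as_text_not_formula(tmp_path):
    path = write_table([("d1", {"description": "=2+2"})], tmp_path / "out.xlsx")
    ws = openpyxl.load_workbook(path).active
    headers = [c.value for c in ws[1]]
    cell = ws.cell(row=2, column=headers.index("description") + 1)
    assert cell.data_type == "s"
    assert cell.value == "=2+2"
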