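"""Excel metadata tables: parsing, simple formula evaluation, templating, writing.

Every batch operation is driven by a workbook with one row per design and a
mandatory ``display_id`` column. Recognized keyword columns (name, description,
notes, author, version, attachment, key, summary) are canonicalized; columns
whose header matches a template subcomponent id and whose cells hold DNA feed
the GENERATE operation; ``SUBCOMPONENT_id`` / ``SUBCOMPONENT_name`` customize
minted children.

Cells may contain simple formulas — a cached computed value stored in the
workbook is used when present, otherwise a minimal evaluator handles
``CONCATENATE(...)``, string literals, numbers and same-sheet cell references,
recursively. Text values may carry ``{column_name}`` placeholders interpolated
per row (``{display_id}`` being the common case).
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import openpyxl

from .model import SbolError, is_iupac_dna

__all__ = [
    "KEYWORD_COLUMNS",
    "TableError",
    "FormulaError",
    "InterpolationError",
    "MetadataRow",
    "MetadataTable",
    "read_table",
    "write_table",
    "eval_cell",
    "interpolate",
]

#: canonical keyword columns understood by the batch operations
KEYWORD_COLUMNS = (
    "display_id",
    "name",
    "description",
    "notes",
    "author",
    "version",
    "attachment",
    "key",
    "summary",
)

_CANONICAL = {
    "displayid": "display_id",
    "display_id": "display_id",
    "subcomponent_id": "subcomponent_id",
    "subcomponent_name": "subcomponent_name",
}
for _k in KEYWORD_COLUMNS:
    _CANONICAL[_k] = _k


class TableError(SbolError):
    """Workbook violates the metadata-table schema."""


class FormulaError(SbolError):
    """A cell formula could not be evaluated."""


class InterpolationError(SbolError):
    """A {placeholder} names a column absent from the row."""


@dataclass
class MetadataRow:
    display_id: str
    values: dict[str, str] = field(default_factory=dict)
    subcomponent_sequences: dict[str, str] = field(default_factory=dict)
    subcomponent_id_override: Optional[str] = None
    subcomponent_name_override: Optional[str] = None
    attachment_path: Optional[str] = None

    def get(self, column: str) -> Optional[str]:
        return self.values.get(column)


@dataclass
class MetadataTable:
    rows: list[MetadataRow] = field(default_factory=list)
    columns: list[str] = field(default_factory=list)
    source: str = ""

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


def _canonical_column(header: str) -> str:
    return _CANONICAL.get(header.strip().lower(), header.strip().lower())


def render_scalar(value) -> str:
    """Render a cell value as text without spurious decimal padding."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, _dt.datetime):
        if value.time() == _dt.time(0, 0):
            return value.date().isoformat()
        return value.isoformat(sep=" ")
    if isinstance(value, _dt.date):
        return value.isoformat()
    if isinstance(value, float):
        return str(int(value)) if value.is_integer() else repr(value)
    return str(value)


# ---------------------------------------------------------------------------
# formula evaluation
# ---------------------------------------------------------------------------

_CELL_REF_RE = re.compile(r"^\$?([A-Za-z]{1,3})\$?([0-9]+)$")


class _FormulaParser:
    """Recursive-descent parser for the minimal formula subset."""

    def __init__(self, text: str, context, address: str):
        self.text = text
        self.pos = 0
        self.context = context  # callable (col, row) -> raw cell value
        self.address = address

    def parse(self) -> str:
        value = self._expression()
        self._skip_ws()
        if self.pos != len(self.text):
            raise FormulaError(
                f"cell {self.address}: trailing characters in formula at offset {self.pos}"
            )
        return value

    def _skip_ws(self):
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def _expression(self) -> str:
        self._skip_ws()
        if self.pos >= len(self.text):
            raise FormulaError(f"cell {self.address}: empty expression")
        ch = self.text[self.pos]
        if ch in "\"“”":
            return self._string()
        token = self._token()
        self._skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == "(":
            return self._call(token)
        m = _CELL_REF_RE.match(token)
        if m:
            return self._deref(m.group(1).upper(), int(m.group(2)))
        try:
            return render_scalar(float(token)) if "." in token else str(int(token))
        except ValueError:
            raise FormulaError(
                f"cell {self.address}: cannot evaluate token {token!r}"
            ) from None

    def _token(self) -> str:
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos].isalnum() or self.text[self.pos] in "$._"
        ):
            self.pos += 1
        if self.pos == start:
            raise FormulaError(
                f"cell {self.address}: unexpected character {self.text[self.pos]!r}"
            )
        return self.text[start : self.pos]

    def _string(self) -> str:
        quote = self.text[self.pos]
        closers = {'"': '"', "“": "”", "”": "”"}
        closer = closers[quote]
        self.pos += 1
        out = []
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch == closer or (closer != '"' and ch in "“”"):
                if closer == '"' and self.text[self.pos : self.pos + 2] == '""':
                    out.append('"')
                    self.pos += 2
                    continue
                self.pos += 1
                return "".join(out)
            out.append(ch)
            self.pos += 1
        raise FormulaError(f"cell {self.address}: unterminated string literal")

    def _call(self, func: str) -> str:
        if func.upper() != "CONCATENATE":
            raise FormulaError(
                f"cell {self.address}: unsupported function {func.upper()} "
                "(no cached value available)"
            )
        assert self.text[self.pos] == "("
        self.pos += 1
        args = []
        self._skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == ")":
            self.pos += 1
            return ""
        while True:
            args.append(self._expression())
            self._skip_ws()
            if self.pos >= len(self.text):
                raise FormulaError(f"cell {self.address}: unterminated argument list")
            ch = self.text[self.pos]
            self.pos += 1
            if ch == ")":
                return "".join(args)
            if ch not in ",;":
                raise FormulaError(
                    f"cell {self.address}: expected ',' or ')' at offset {self.pos - 1}"
                )

    def _deref(self, col: str, row: int) -> str:
        raw = self.context(col, row)
        return eval_cell(raw, self.context, address=f"{col}{row}")


def eval_cell(cell, table_context=None, cached=None, address: str = "?") -> str:
    """Evaluate a raw cell to its string value.

    ``cell`` is the raw content (literal value, or a formula string starting
    with ``=``). ``table_context`` is a callable ``(column_letter, row_index)
    -> raw value`` for same-sheet references; ``cached`` is the workbook's
    cached computed value, used in preference to re-evaluation when present.
    """
    if isinstance(cell, str) and cell.startswith("="):
        if cached is not None:
            return render_scalar(cached)
        if table_context is None:
            table_context = lambda c, r: None
        return _FormulaParser(cell[1:], table_context, address).parse()
    return render_scalar(cell)


# ---------------------------------------------------------------------------
# templating
# ---------------------------------------------------------------------------

_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*)\}")


def interpolate(template_text: str, row: MetadataRow) -> str:
    """Substitute each ``{column_name}`` with the row's value for that column."""

    def repl(m: re.Match) -> str:
        key = _canonical_column(m.group(1))
        if key == "display_id":
            return row.display_id
        value = row.values.get(key)
        if value is None:
            raise InterpolationError(
                f"row {row.display_id!r}: placeholder {{{m.group(1)}}} names an "
                "absent column"
            )
        return value

    return _PLACEHOLDER_RE.sub(repl, template_text)


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def read_table(path, sheet: Optional[str] = None) -> MetadataTable:
    """Parse a workbook sheet into a :class:`MetadataTable`.

    Formulas are resolved (cached value first), trailing fully-empty rows are
    dropped, and non-keyword columns whose cells all hold IUPAC DNA are exposed
    as subcomponent sequence columns.
    """
    path = Path(path)
    wb = openpyxl.load_workbook(path, data_only=False)
    wb_cached = openpyxl.load_workbook(path, data_only=True)
    ws = wb[sheet] if sheet else wb.worksheets[0]
    ws_cached = wb_cached[ws.title]

    headers: list[tuple[int, str]] = []
    for idx, cell in enumerate(ws[1], start=1):
        if cell.value is None or str(cell.value).strip() == "":
            continue
        headers.append((idx, _canonical_column(str(cell.value))))
    columns = [h for _, h in headers]
    if "display_id" not in columns:
        raise TableError(
            f"sheet {ws.title!r} of {path.name}: missing mandatory 'display_id' column"
        )

    def context(col_letter: str, row_idx: int):
        return ws[f"{col_letter}{row_idx}"].value

    raw_rows: list[tuple[int, dict[str, str]]] = []
    for r in range(2, ws.max_row + 1):
        values: dict[str, str] = {}
        empty = True
        for col_idx, header in headers:
            cell = ws.cell(row=r, column=col_idx)
            cached = ws_cached.cell(row=r, column=col_idx).value
            text = eval_cell(cell.value, context, cached=cached,
                             address=f"{cell.column_letter}{r}")
            if text != "":
                empty = False
            values[header] = text
        if not empty:
            raw_rows.append((r, values))

    # classify non-keyword columns: all-DNA columns are subcomponent sequences
    keyword = set(KEYWORD_COLUMNS) | {"subcomponent_id", "subcomponent_name"}
    dna_columns = set()
    for col in columns:
        if col in keyword:
            continue
        cells = [v[col] for _, v in raw_rows if v.get(col)]
        if cells and all(is_iupac_dna(c) for c in cells):
            dna_columns.add(col)

    rows: list[MetadataRow] = []
    seen: dict[str, int] = {}
    for r, values in raw_rows:
        display_id = values.get("display_id", "").strip()
        if not display_id:
            raise TableError(f"sheet {ws.title!r} row {r}: empty display_id")
        if display_id in seen:
            raise TableError(
                f"sheet {ws.title!r}: duplicate display_id {display_id!r} "
                f"(rows {seen[display_id]} and {r})"
            )
        seen[display_id] = r
        row = MetadataRow(display_id=display_id)
        for col, text in values.items():
            if col == "display_id" or text == "":
                continue
            row.values[col] = text
            if col in dna_columns:
                row.subcomponent_sequences[col] = text
        row.subcomponent_id_override = row.values.pop("subcomponent_id", None)
        row.subcomponent_name_override = row.values.pop("subcomponent_name", None)
        row.attachment_path = row.values.get("attachment")
        rows.append(row)

    return MetadataTable(rows=rows, columns=columns, source=f"{path}:{ws.title}")


def write_table(records, path, extra_columns: tuple[str, ...] = ()) -> Path:
    """Write ``(display_id, metadata dict)`` records to a workbook.

    The header holds ``display_id`` plus every supported keyword column (and
    any ``extra_columns``); absent values are left blank. Values beginning
    with ``=`` are stored as text, never as live formulas.
    """
    path = Path(path)
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "designs"
    headers = ["display_id"] + [c for c in KEYWORD_COLUMNS if c != "display_id"]
    headers += [c for c in extra_columns if c not in headers]
    ws.append(headers)
    for display_id, meta in records:
        ws.append(None for _ in headers)
        r = ws.max_row
        values = {"display_id": display_id, **{str(k).lower(): v for k, v in meta.items()}}
        for i, h in enumerate(headers, start=1):
            v = values.get(h)
            if v is None:
                continue
            cell = ws.cell(row=r, column=i, value=str(v))
            cell.data_type = "s"  # keep leading '=' as text
    wb.save(path)
    return path
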