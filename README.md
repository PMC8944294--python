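# sbolbatch

Batch operations on libraries of SBOL2 genetic designs, driven by Excel
metadata tables.

Synthetic-biology projects increasingly produce *libraries* of related
constructs — hundreds to thousands of plasmids sharing a common backbone and
varying only in a few parts (homology flanks, barcodes, target genes). Sharing
such libraries FAIRly means encoding every member as an SBOL2
ComponentDefinition and depositing it in a repository such as SynBioHub, which
is impracticable by hand at that scale. `sbolbatch` automates the whole
lifecycle for bench scientists who already keep their designs in spreadsheets:

- **generate** — instantiate one concrete design per spreadsheet row from an
  abstract template whose variable subcomponents ("generic slots") carry no
  sequence;
- **annotate** — batch-apply names, descriptions, notes and authorship from a
  table onto matching components in a document, offline;
- **flatten** — collapse a hierarchical subcomponent tree into a single
  component with one fully annotated linear sequence, exportable to GenBank;
- **clean** — strip repository-specific annotations from a downloaded document
  and re-root its identities so it can be re-uploaded;
- **deposit / update / synbio2table** — batch submission, table-driven record
  updates (including file attachments) and collection export against a
  SynBioHub-compatible HTTP API, with retries on transient failures.

Every operation is driven by `.xlsx` tables with a mandatory `display_id`
column; recognized keyword columns (`name`, `description`, `notes`, `author`,
`version`, `attachment`, ...) map onto record fields. Cells may hold simple
formulas (`CONCATENATE(...)`, cell references) and `{display_id}`-style
placeholders interpolated per row.

Scope: SBOL2 RDF/XML only; batch edits act on ComponentDefinitions; flattening
requires `Range` sequence locations. These limits are explicit contracts —
out-of-scope inputs are rejected with clear errors rather than mangled.

## Coordinate model

All positions are SBOL2 `Range` coordinates: 1-based, inclusive, with
orientation `inline` or `reverseComplement`. Flattening maps a child at
relative range [s, e] inside a parent spanning absolute [P, Q] to

- [P − 1 + s, P − 1 + e] when the parent is inline, and
- [Q − e + 1, Q − s + 1], with orientation flipped, when the parent is
  reverse-complement;

composed along the ancestor chain (an odd number of flips yields a
reverse-complement annotation). GenBank export writes the same 1-based
inclusive coordinates, using `complement(start..end)` for flipped features.

## Worked example

```python
from pathlib import Path
from sbolbatch import fixtures, tableio, sbolio
from sbolbatch.generate import generate_library
from sbolbatch.flatten import flatten_to_document

work = Path("demo"); work.mkdir()
paths = fixtures.write_example_inputs(work, n_rows=3, seed=1)

template = sbolio.read_sbol(paths["template"])
table = tableio.read_table(paths["table"])
library = generate_library(template, "plasmid_template", table,
                           "https://example.org/library")
sbolio.write_sbol(library, work / "generated.xml")

design = library.find_component("cs0001_gene1")
print(f"designs generated: {len(table)}")
print("cs0001_gene1 children: "
      + ", ".join(f"{u.instance_id}[{u.location.start}..{u.location.end}]"
                  for u in design.subcomponents))

flat_doc = flatten_to_document("cs0001_gene1", library)
flat = flat_doc.components[0]
print(f"flat sequence: {len(flat_doc.sequences[0].elements)} nt, "
      f"{len(flat.annotations)} annotations")
sbolio.export_genbank(flat, flat_doc, work / "cs0001_gene1.gb")
```

prints

```
designs generated: 3
cs0001_gene1 children: backbone_part1[1..600], left[601..1499], backbone_part2[1500..2099], barcode[2100..2138], backbone_part3[2139..2738], right[2739..3925], backbone_part4[3926..4525]
flat sequence: 4525 nt, 7 annotations
```

The three designs each fill the template's `left`, `barcode` and `right` slots
with that row's DNA, laid out contiguously after each backbone part — the
barcode is short (39 nt here), the homology flanks run to ~1.2 kb. The
flattened record carries one annotation per subcomponent on a single 4525 nt
sequence, and the exported GenBank file opens directly in sequence editors:

```
LOCUS       cs0001_gene1_fla        4525 bp    DNA     linear   UNK 01-JAN-1980
FEATURES             Location/Qualifiers
     source          1..4525
     misc_feature    1..600
                     /label="Backbone part 1"
```

The same steps are available from the shell (`sbolbatch generate ...`,
`sbolbatch flatten ...`); run `sbolbatch` with no arguments for the command
list, or `sbolbatch end2end --workdir demo` for a scripted tour of all
operations against the bundled repository emulator. Missing options are
prompted for interactively unless `--no-prompt` is given.

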