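# Methods

## The data model and its serialization

`sbolbatch` operates on a typed in-memory model of the SBOL2 entities that
batch operations touch — ComponentDefinitions (with subcomponent
instantiations, sequence annotations, precedes-constraints and Range
locations), Sequences and Collections. Everything else in a document is
carried as opaque RDF: triples whose subject is a typed top-level entity live
in that entity's `extra_properties`, all other triples in the document's
`foreign_properties`. This split is what makes the offline edits safe: an
operation can rewrite the fields it owns while provenance, attachments and
third-party extensions survive a read/write cycle untouched, verified at the
triple level against an independent RDF parse.

Reading accepts RDF/XML only — the dialect SynBioHub exchanges — and rejects
SBOL3 documents explicitly. Writing is deterministic: the document is lowered
to an RDF graph and serialized with sorted subjects, predicates and objects,
so identical documents produce byte-identical files. Determinism is a
first-class contract here because batch pipelines diff outputs across runs;
it also gives a cheap template-immutability check (serialize before and after,
compare bytes). Sequence case is preserved on round-trip; sequence comparisons
are case-insensitive. Entities minted by this package get version "1", the
SBOL2 persistent-identity convention `prefix/display_id/version`, and child
node URIs derived from the parent's persistent identity. Non-`Range` locations
(Cut, GenericLocation) found on read are preserved as foreign data, but any
operation that needs locations rejects them with an explicit error.

One representational choice deserves a note: the repository's "notes" field is
stored as `rdfs:comment` rather than under the repository's own terms
namespace. CLEAN removes *every* property under the configured repository
namespaces (see below), and notes written by ANNOTATE must survive a
clean/re-upload cycle, so they cannot live in the namespace being stripped.

## Generation from a template

A template is a ComponentDefinition whose variable children ("generic slots")
have no sequence. Slot-to-column matching uses the subcomponent instance id
against table column headers; a non-keyword column whose cells all parse as
IUPAC DNA is treated as a slot column. Each row yields one design:

1. every generic slot is replaced by a freshly minted child
   (`<design_id>_<slot_id>`) plus a Sequence holding the row's cell string;
2. fixed backbone children are shared by reference with the template;
3. children receive contiguous 1-based Ranges in layout order (child k starts
   at 1 + Σ lengths of children 1..k−1), all inline;
4. a full-length concatenated Sequence is attached to the design so
   repositories render it with complete sequence content;
5. name/description/notes/author/version are set from the row after
   `{placeholder}` interpolation.

Layout order is the template's explicit Range order when present, else the
topological order of its precedes-constraints, else declaration order. The
`SUBCOMPONENT_id`/`SUBCOMPONENT_name` override columns are singular per row,
so they are applied only when the template has exactly one generic slot;
with several slots they are ignored with a logged warning rather than guessed.
Unrecognized metadata columns are ignored with a warning instead of being
attached as ad-hoc annotations — predictable output beats silent schema drift.

## Flattening

Flattening recurses through the subcomponent tree (cycle-checked via a
visited set), composing Range offsets and orientations along each ancestor
chain as described in the README. If the design carries its own full sequence
it wins — assembled-tile disagreement is logged per child, not fatal, since a
sequencing-verified top-level sequence legitimately overrides design-time
tiles. Otherwise the sequence is assembled from child tiles, which must tile
1..L contiguously; gaps, overlaps and length mismatches are structural errors
naming positions. Reverse-complementation is IUPAC-aware and
case-preserving. Descendant roles and names are copied verbatim onto the flat
annotations; annotation order is deterministic (start ascending, longer span
first, then display_id). Existing standalone annotations on the input design
are carried over unchanged, which makes flattening a flat design stable.

The randomized validation compares this implementation against an
independently formulated oracle that computes each leaf base's absolute
position by folding per-ancestor affine coordinate maps (rather than by
string concatenation), over 1000 seeded random 2–3-level designs.

## Cleaning and the repository contract

CLEAN removes every property triple whose predicate falls under the configured
namespaces — by default the SynBioHub terms namespace
(`http://wiki.synbiohub.org/wiki/Terms/synbiohub#`, e.g. `ownedBy`,
`topLevel`) — and re-roots top-level persistent identities onto a target URI
prefix, preserving display_id and version and rewriting any foreign triples
rooted under the old identities. The strip list is logged on every run and
extensible, because no repository publishes an authoritative enumeration of
its bookkeeping properties. The operation is idempotent.

The online client pins a compact SynBioHub-compatible contract behind an
injectable transport: form login returning a token, multipart
submit-to-collection with an overwrite flag, a JSON member listing, per-member
field edits and multipart attachment upload. The bundled emulator
(`sbolbatch.mockhub`) implements exactly this contract in-process — including
rejection of submissions that still carry repository bookkeeping triples, and
scripted fault injection — and is what defines testability of the online
operations; endpoint shapes on a live server may differ by version and are
deliberately isolated in one transport layer. Retries default to 3 attempts
with 1 s / 4 s backoff and fire only on timeouts, dropped connections and
5xx responses; per-item failures never abort a batch, and every attempt is
recorded in the batch report (also writable as CSV). Credentials are never
logged.

## Spreadsheet semantics

Column names are matched case-insensitively with whitespace stripped
(`display_id` and `displayId` both address the key column). Formula support is
deliberately minimal: a cached computed value stored by the spreadsheet
application is used first; otherwise a recursive evaluator handles
`CONCATENATE`, string literals, numbers and same-sheet cell references, and
anything else is a loud error naming the cell — silent mis-evaluation of batch
metadata is the costliest failure mode, and unknown `{placeholders}` are hard
errors for the same reason. Numbers render in shortest exact form (42, not
42.0), dates as ISO-8601. Values beginning with `=` are written back as text,
never as live formulas.

## Synthetic example data

The fixtures module emulates a knockout-plasmid library project: a template
with fixed backbone parts interleaved with `left`/`barcode`/`right` generic
slots, and a library-definition workbook with one row per target gene
(`cs0001_gene1`, ...) carrying author/name/notes, a description with a
`{display_id}` placeholder in every third row, and seeded random slot
sequences. Slot lengths span the scales that matter for layout arithmetic —
barcodes 20–40 nt, flanks 200–1200 nt. Sequences are uniform random A/C/G/T:
the generator exercises structure, coordinates and metadata flow, not
biology. It does not emulate real backbone or marker sequences, restriction
sites, assembly junctions, or the skewed GC content of a real genome, so
passing tests demonstrate correctness of the batch machinery, not fitness of
any particular biological design. All fixture outputs are byte-deterministic
given their seeds (workbook timestamps and zip metadata are pinned).

Randomized hierarchical designs for flattening tests draw 2–4 children per
node, ~40 % composite recursion to depth 3, ~40 % reverse-complement
placement, and leaf lengths of 3–40 nt — small enough to run a thousand cases
in seconds while covering orientation-composition paths several levels deep.

## Problem sizes and verification

The library-scale computation (`scripts/acceptance.py`) regenerates the full
3661-member collection from synthetic inputs in a few seconds and reports the
design count produced. The test suite validates generation on tables of 1–500
rows, flattening on 1000 random hierarchies plus hand-computed worked
examples, round-trips on every fixture family, the clean/re-upload loop and
the full online batch contract against the emulator, and a scripted
end-to-end workflow whose GenBank output is re-parsed with an independent
reader and compared feature-by-feature against the flattener's annotation
set.

## Known limitations

- SBOL3, ModuleDefinitions, Models and Activities are pass-through only.
- The flattener requires `Range` locations and concrete leaf sequences;
  abstract designs cannot be flattened (by design).
- The formula evaluator is not a spreadsheet engine; cross-sheet references
  and functions other than `CONCATENATE` rely on cached values.
- The online contract is verified against the bundled emulator, not a live
  SynBioHub instance; whether a live server's note edits append or replace is
  version-dependent (the emulator pins append).
- GENERATE emits one multi-design document rather than one file per design;
  DEPOSIT handles folders of files independently.
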