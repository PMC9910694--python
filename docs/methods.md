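# Methods

## The coding model

`amrcodes` implements a hierarchical classification-and-coding scheme for
human-disease animal-model resource records. A record is classified along
three *trunk* dimensions — system disease (A), animal species (B), modeling
method (C) — each a shallow tree of layers, plus one *branch* dimension of
three parallel essential attributes (D: cooperation, sharing, preservation).
The canonical code concatenates the fixed identification prefix `CSTR09` with
the four dimension segments; each trunk layer contributes a fixed-width,
zero-padded sequence code, each attribute one digit. Because the code is a
positional transcription of the classification, encoding and decoding are
exact inverses wherever every referenced node exists in the registry, and
partial knowledge of a model translates directly into a digit pattern that
retrieves it.

Two width profiles are supported. The **paper profile** (default) codes A as
major+intermediate (4 digits) and C as category only (2 digits) — the form in
which the scheme's published examples are printed. The **extended profile**
adds the optional disease minor layer and method subcategory (A 6 digits, C 4
digits), zero-filling them when empty. `00`/`000` is reserved at every layer
as the supplementary "empty" code, and attribute digit `0` marks a missing
attribute; decoding against a registry that lacks the optional layers accepts
zero-filled optional segments and drops them, while a nonzero segment that
resolves to no node is a violation.

Sequence codes are assigned incrementally: `assign_next_code` returns the
smallest unused nonzero code under a parent and reserves it, so interleaved
loads and assignments can never collide and repeated calls are strictly
increasing. Capacity per layer is therefore `10^width − 1` labelled children
(01–99 or 001–999).

## The reference taxonomy

The bundled fixture (`amrcodes/data/paper_taxonomy.{tsv,yaml}`) contains
exactly the nodes the scheme's published tables and worked examples
enumerate: 16 disease major categories; the eight cardiovascular intermediate
categories (myocarditis through atherosclerosis, coded in that order); the
laboratory-animal major (`11`) with species mouse `11`, rat `13`, guinea pig
`15`, rabbit `27`; strains BALB/c `001`, KM `002`, C57 `003`, ICR-Tg(hACE2)
`017` (mouse), SD/Wistar (rat), New Zealand (rabbit); and the three modeling
categories. Nodes whose codes are deduced from printed example codes rather
than an explicit listing (rabbit `27`, strain `017`, the respiratory
intermediate `12` for SARS-CoV-2 infection) carry `provenance: inferred`.
Mouse strains `004`–`016` are deliberately left unassigned: the source
vocabulary is unpublished beyond the printed rows, and inventing fillers
would corrupt lookups. One conflict in the source material — species `15`
glossed both as guinea pig and as pig — is resolved in favour of the running
text (guinea pig). The full disease vocabulary (118 intermediate categories)
is likewise unpublished; the fixture makes no attempt to complete it, which
is why desk-scale counts cover majors (16) and methods (3) but not the
intermediate total.

## Retrieval

A `QueryPattern` constrains each code segment either not at all (`*`) or
digit by digit, `?` matching any digit. Search is implemented as an anchored
regular-expression match over canonical codes; the test suite checks it
against an independent character-by-character scan oracle up to 10,000
records. Results are ordered by `(code, record_id)` so output is byte-stable.
*Neighbor expansion* wildcards a chosen set of layers of a base code and
excludes records carrying the base code itself — the code-native form of
"find related models". *One-shot* success in the benchmark is defined
strictly: the result set equals exactly `{target}`. Codes are categories, not
identifiers, so several records may share a code; a fully literal pattern is
one-shot precisely when its code is unique in the catalog.

The keyword baseline emulates the national database front end: all supplied
fields must match (Boolean AND), with substring matching on the three long
text fields (name, english_name, disease_description) and exact matching on
the three short ones (cooperation, date, preservation). Matching is
case-sensitive on NFC-normalized, trimmed text; the emulated system defines
no fuzziness, and none is added.

## Synthetic catalogs

Real model holdings cluster heavily: a few disease × species × method cells
(induced mouse models of common diseases, above all) hold a large share of
deposits. The generator reproduces that shape: leaf cells are the product of
disease intermediates × strains × method categories; cell weights are drawn
from a symmetric Dirichlet with concentration `cell_skew` (default 0.3 —
values below 1 concentrate mass on few cells), after which any configured
hotspot cells are pinned to fixed probabilities and the remainder is
renormalized. Defaults: 865 records (the scale of the national deposit the
scheme targets) with one hotspot cell at weight 0.21 (mirroring the reported
~181-of-865 concentration of mouse–tumor models; mapped onto a cardiovascular
cell because the tumor branch has no published intermediate vocabulary).
Attributes are independently missing with probability 0.1 by default.
Metadata text is assembled from the record's own labels plus noise tokens and
a serial number, so keyword queries drawn from a record's name always match
it, usually among many others.

All randomness flows through one `numpy` generator seeded from the config, so
catalogs are byte-identical given the same config. A chi-square
goodness-of-fit test (10,000 records, cells with expected count < 5 pooled,
α = 0.01) confirms empirical cell frequencies follow the configured weights.

What the generator does *not* emulate: the real database's mixed
Chinese/English text, its actual (unpublished) cell distribution, accession
histories, or duplicated/near-duplicate deposits. Benchmark results on
synthetic catalogs therefore demonstrate the *mechanism* of the efficiency
gain — candidate lists shrink from hundreds (keyword AND-matching over skewed
text fields) to the occupancy of a single code cell — not the precise hit
counts any live database would return.

## Numerical and design choices

* **Canonical form** has no whitespace; input canonicalization uppercases and
  strips all whitespace (printed tables put a space after the colon), and is
  idempotent.
* **Attribute order** in the D segment is cooperation, sharing, preservation;
  the valid D-parts are exactly {0–3}×{0–2}×{0–2} (36 strings, maximum 322).
* **Validation returns data, not exceptions**: `validate_code` accumulates
  machine-readable violations (part, layer, position, message); the codec
  raises `CodecError` carrying the same violation objects.
* **Profile detection on parse** is by segment widths; mixed-profile widths
  are rejected rather than guessed.
* **Benchmark rates on an empty query set** are reported as undefined
  (`None`/`n/a`) rather than 0 or NaN.
* **Determinism**: result ordering is lexicographic by (code, record_id);
  query sampling uses `numpy.random.default_rng` with explicit seeds.
* Problem sizes in the shipped tests and acceptance script — the full fixture
  enumeration (189 leaf cells × 36 attribute triples = 6,804 codes), 10,000
  records for the search-oracle comparison, 865-record default benchmarks
  with 100 queries — are the package's chosen desk-scale defaults; all run in
  seconds.

## Known limitations

* The registry is in-memory and rebuilt from text files; no persistence or
  concurrent mutation is provided.
* Labels are treated as opaque byte strings; no multilingual synonymy
  (the real vocabularies are bilingual Chinese/English).
* The keyword baseline implements only the documented AND field matching —
  no ranking, stemming, or fuzzy matching, because the emulated system has
  none.
* The national identifier's 10-character unit code is treated as opaque; its
  internal structure (if any) is not published, and no checksum is defined.
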