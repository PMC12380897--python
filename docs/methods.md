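# Methods

This note documents the models, procedures and design choices behind
`smpc2idmp`: what each stage assumes, which parameters matter, what the
synthetic corpus does and does not emulate, and the numerical conventions
used throughout.

## The minimal-IDMP schema

The schema is a fixed registry of 28 fields across six sections
(medicinal product, marketing authorization, therapeutic indications,
packaged medicinal product, ingredients, pharmaceutical product). Each
field carries a nesting level 1–4 grading how much reconstruction a
text-extraction system must perform, a dotted path into the nested record,
a value kind (scalar text, scalar date, list of text, list of records), a
natural-language question used in prompts, and the SmPC chapters the
rule-based retriever consults.

Two representation choices deserve note:

* **Component/material grouping.** The packaging-component rows group the
  dose *value* separately from the *component/material* pair, so the
  registry has one field owning `package_component[].value` and one owning
  each component's `component` and `material` leaves. Record paths still
  partition the flattened record: every leaf is owned by exactly one field.
* **Single-entry active composition.** Documents with a single dosage form
  carry exactly one active-composition entry holding both the salt and the
  base sub-records (either may be empty, since many texts state only the
  base form). Multi-form SmPCs are out of scope.

Missing values are always the empty string (scalars) or empty list (list
kinds); keys are lowercase snake_case after normalization. Dates, once
parseable, are stored ISO-8601; unparseable strings are kept verbatim
rather than destroyed.

## SmPC parsing

Input is plain UTF-8 text following the EMA QRD template; PDF-to-text
conversion is an external concern. Headings are lines starting with a one-
or two-digit chapter number (optionally dotted subsection) followed by a
separator. Three guards keep body lines that begin with numbers (doses,
street numbers, "3 years …") from being misread as headings: top-level
numbers must ascend (with small forward jumps allowed, capped at the QRD's
ten chapters), subsections must ascend under their parent, and a candidate
whose title starts with a lowercase letter is rejected. Chapter spans are
0-based half-open character ranges that include the heading line and
exactly tile the document, so chunk offsets and chapter bodies share one
coordinate system. Duplicate chapter numbers keep the first occurrence and
log a warning.

## Retrieval

**Semantic.** Documents are chunked by a sliding window of 500 characters
with 200-character overlap (stride 300); the final chunk may be shorter.
Defaults reproduce exact stride arithmetic; an optional `snap_window`
moves boundaries to nearby whitespace for prompting over clean token
boundaries, at the cost of exact-overlap arithmetic. Chunks are embedded
and ranked by cosine similarity against the field's question; the top
k = 20 are returned, ties broken by ascending chunk id so rankings are
insertion-order invariant. Zero-norm vectors score 0 against any query.

The default embedding backend is a deterministic hashed bag-of-words:
tokens (lowercased, stopwords removed) are md5-hashed to one of 256 signed
buckets, weighted 1 + log tf. It is a lexical-overlap embedding with no
pretrained weights — identical inputs always embed identically, across
processes and platforms. Transformer encoders plug in through the same
three-member contract (`name`, `dim`, `embed`) and are deliberately not
bundled. The retrieval quality the test suite demonstrates is therefore
lexical: questions share vocabulary with the chapters that answer them,
which holds for SmPCs ("ATC code", "shelf life", "marketing
authorisation") but understates what a semantic encoder would do on
paraphrased text.

**Rule-based.** Each field maps to fixed chapters: name → 1; composition →
2 and 6.1; pharmaceutical form and the administrable-product fields → 3 and
4.2; indications → 4; ATC → 5; shelf life → 6.3; storage → 6.4; packaging →
6.5; holder → 7; authorization numbers → 8; dates → 9. A top-level chapter
id includes its subsections. Mapped-chapter-absent is a per-field warning
and a missing value, never an abort.

## Prompting and generation

Three few-shot prefix patterns are shipped as plain-text templates with
`$slot` markers: CARE (context, action, result, example), RISE (role,
input, steps, expectation; no examples by design) and the CIAEE hybrid.
Every prompt carries the field's question, all retrieved passages between
explicit context markers, and a format instruction matched to the value
kind. In semantic mode the prompt additionally instructs the model to
return an empty string when the context holds no relevant information;
rule-based mode omits the fallback because the mapping guarantees context.
The example bank ships one structured example per level-3/4 field and a
per-section fallback for the rest.

Generation backends implement `complete(prompt) -> reply`. Remote models
are configuration, not code: a JSON-lines transcript cache keyed by the
SHA-256 of the prompt records replies and replays them bit-identically,
so benchmark grids are reproducible after the fact. The shipped
*reference backend* is a deterministic pattern matcher that inverts the
synthetic-corpus grammar — it reads the question line, identifies the
field, and applies the field's inverse regular expressions to the context.
It exists to close the loop in tests and is documented as such; it is not
a language model and makes no claim about real-model behaviour.

Reply parsing extracts the first JSON fragment for structured kinds and
otherwise keeps the stripped reply verbatim; trimming heuristics are
deliberately absent so that normalization remains the single place where
surface forms are canonicalized.

## Normalization

Applied identically to predictions and gold before comparison, in a fixed
order: recursive key lowercasing (collisions keep the first key), embedded
JSON parsing for list fields (repair is limited to quoting bare tokens
inside flat brackets), range expansion for authorization numbers (prefix +
zero-padded tail, `-`/`–`/`to` separators, padding preserved; descending
ranges pass through with a warning), list cleaning (strip stray
brackets/quotes, de-duplicate keeping first occurrence), default-phrase
canonicalization, and date parsing (ISO, long-form English in either
order, day-first numerics — EU documents motivate the day-first choice;
calendar validity enforced). Every operation is idempotent and total.

Default equivalence has two classes: the storage-precautions field, where
the standard "does not require any special storage conditions" phrase is
canonically the empty string and is rewritten as such inside the record;
and the shelf-life value, where the empty string and configured standard
phrases ("3 years", "6 years" by default) form one equivalence class.
The shelf-life class is applied only at scoring time — rewriting
"3 years" to a canonical empty token inside the stored record would
destroy data, so the record keeps the stated value and the comparison
layer grants full similarity within the class.

## Evaluation

All metrics are clipped to [0, 1] and obey the identity law (1 on
identical normalized inputs). Exact match is an indicator: dates compare
as parsed dates, lists as sets, and for list-of-records fields it is 1
only when every item pairs up and every paired leaf matches. Jaccard uses
token sets (element sets for lists). ANLS is 1 − edit distance divided by
the longer length (edlib under the hood; the test suite checks it against
an independent dynamic-programming oracle). TF-IDF cosine uses
scikit-learn's smoothed-idf convention, fitted on supplied corpus
statistics or, failing that, on the pair itself. BLEU applies add-one
smoothing to higher-order n-grams so two- and three-token field values do
not vanish; ROUGE is ROUGE-L F1; METEOR uses exact then light-stem unigram
matching with the standard recall-weighted F-mean and fragmentation
penalty (a single contiguous match chunk incurs no penalty, preserving the
identity law). The semantic score is a greedy token-matching F1 when the
encoder provides token vectors and pooled cosine otherwise; with the
offline hashed encoder it measures lexical, not semantic, similarity, and
published transformer encoders are opt-in.

List-valued fields are order-invariant throughout; for string metrics a
list renders as its sorted elements joined with commas. Lists of records
are matched on their name-like key (order-insensitive, each item used at
most once); matched pairs score leaf-wise and average, unmatched items
score 0 — the zero-penalty rule is a documented choice. Excipient names
and dosages are scored as parallel lists, so dosage scores do not track
pairing with their excipient; the paired view is available through the
record itself.

Factor analysis uses the Kruskal–Wallis rank test (scipy, tie-corrected)
per factor × metric across configurations; fully tied data returns H = 0,
p = 1 by convention. No multiple-testing correction is applied to the
p-values. Score distributions from this task are strongly bimodal
(missing extractions cluster at 0, correct ones at 1), which is what
motivates a rank test over ANOVA.

## Synthetic corpus

The generator renders grammar-based SmPCs (templates plus lexicons of
invented brands, real substance and excipient names, containers,
materials, holders) with paired gold records. Defaults emulate the study
conditions: 81 documents per corpus, single dosage form and packaging,
all four nesting levels represented, and exactly the surface variations
the normalizer exists to undo — ranged vs. enumerated authorization
numbers (range probability 0.5), four date renderings (weights
0.3/0.4/0.2/0.1 for ISO/long-EU/long-US/numeric), salt-vs-base
composition phrasing (level-3 probability 0.8), default-vs-explicit
storage phrases (0.5), and measuring-spoon packaging narratives on powder
forms (level-4 probability 0.85 given level 3). Standard safety chapters
(4.3–4.9, 5.2–5.3, 6.2, 6.6) are filled with generic prose so a document
yields roughly 26–32 chunks and top-20 retrieval is a genuine ranking
problem. A single seeded generator drives every choice; the seed is
recorded in the corpus manifest.

Gold records are canonical by construction (normalizing a gold record is
a no-op), every gold value appears in its mapped chapter verbatim or as a
deterministic surface variant, and documents are mutually distinct.

What the corpus does *not* emulate: real EMA language variability,
multi-product or multi-form SmPCs, OCR noise, tables, and genuinely
implicit phrasing that requires inference rather than pattern inversion.
A perfect closed-loop score therefore validates the pipeline's plumbing —
parsing, retrieval, prompting, parsing, assembly, normalization, scoring —
not the linguistic competence of any particular language model on real
documents.

## Test-suite problem sizes

The suite exercises the closed loop on a 25-document corpus (all 28 fields,
700 field scores), retrieval recall on a 50-document corpus (~900
level-1/2 field instances), chunker invariants on 200 random documents,
the ANLS oracle on 1000 random pairs, and the Kruskal–Wallis implementation
exhaustively against the textbook formula on every two-group rank split of
total size ≤ 8. These sizes keep the whole suite under a few seconds while
covering every level and field at least once.

## Known limitations

* The offline embedding backend is lexical; semantic-retrieval results on
  paraphrase-heavy text will differ with a transformer encoder.
* The reference backend inverts only the synthetic grammar; on real SmPCs
  a hosted-model backend (via the transcript cache) is required.
* METEOR ships without a synonym stage (exact + stem only); a synonym
  resource can be plugged in where needed.
* Excipient dosages are scored as an unpaired list (see above).
* English-language, single-form SmPCs only.
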