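# Methods

## The hyb record model and format dialect

A hybrid record is one chimeric read: read id, read sequence, an optional
hybridization energy, and two aligned segments, each with a reference
identifier, a 1-based inclusive read-span, an optional 1-based inclusive
reference-span, and an optional mapping score. Serialization is
tab-delimited with 15 fixed columns in the order
`id, seq, energy, seg1(ref, read_start, read_end, ref_start, ref_end,
score), seg2(...)`, plus an optional 16th flags column of `key=value`
pairs joined by `;`. The missing-value token is `.` and is legal only in
energy, reference-span, and score fields; id, sequence, reference names,
and read-spans are mandatory. Decimal tokens must match
`[+-]?digits(.digits)?([eE][+-]?digits)?`; anything else (locale commas,
`inf`, bare exponents) is a parse error to be triaged rather than guessed.

Conventions chosen where upstream tools leave the behavior open:

- **Coordinates are 1-based inclusive** in read- and reference-space,
  matching hybrid-caller output.
- **seg1 is the 5′ segment** (smaller `read_start`). A file whose columns
  violate this is parsed in file order and surfaced as a `seg-order`
  warning by `hyb_check`, not rejected — upstream variability should be
  visible, not fatal. Overlapping read-spans are likewise permitted
  (ligation chimeras can be called with overlap) and warned as
  `span-overlap`.
- **Duplicate read ids are legal** (clustered outputs reuse ids) and
  warned, never errored.
- **Numeric fidelity**: the original text tokens of energy and score
  fields are retained beside their parsed values, so records that pass
  through unmodified are rewritten byte-exactly. This matters for QC
  diffs, not correctness; records constructed in memory format floats
  minimally.
- Comment (`#`) and blank lines are tolerated on read, never written;
  gzip inputs are auto-detected by magic bytes; output is UTF-8 with
  Unix newlines.
- A `span-exceeds-seq` violation is treated as a parse error (not only a
  check finding), so the check report's error count always equals the
  number of lines that fail to parse into a valid record.

Flags are an ordered, unique-key table. A recognized-key list
(`count_total`, `read_count`, `seg1_type`, `seg2_type`, `miRNA_seg`,
`target_reg`, `dataset`, …) documents known vocabulary; unrecognized keys
are preserved verbatim and may be written explicitly with
`allow_undefined=True`. Record multiplicity is exposed as an explicit
**count mode** — `record` (each line once), `read_count`, or
`count_total` (flag value, falling back to 1 when absent) — rather than a
silent precedence chain, so weighted analyses are reproducible under a
stated mode. A flag present but not a positive integer is an error naming
the record and key.

## Vienna fold records and merging

Fold records are the 3-line dot-bracket form: `>id`, sequence, structure
with an optional trailing `(energy)` in kcal/mol. The structure must
equal the sequence in length and be balanced; pseudoknot alphabets and
multi-structure records are out of scope. Energy is parsed at full
precision and written back as the original token (or `%.1f` for records
built in memory, the common folder output style).

Hyb and Vienna files are merged positionally — the k-th record with the
k-th — with id equality as an additional check (on by default). This
keeps memory O(1); id-keyed joining is deliberately not offered.
Sequence comparison treats T and U as equal, since hyb files are
DNA-alphabet and folders emit RNA. `static` matching requires equal
lengths; `dynamic` matching scans offsets left-to-right and accepts the
smallest offset placing the fold sequence inside the hyb sequence within
the mismatch budget (a fold sequence longer than the hyb sequence is a
failure, not a reverse search). Match failure is a value: under
`warn_skip` the pair is counted and skipped, under `raise` the first
failure aborts naming both records and the pair index. Exhausting one
stream before the other is always an error naming the exhausted stream.

## Annotation

Segment types are inferred from reference identifiers only — no
sequence-based inference. The default `hyb_split` method takes the last
underscore-delimited field (the `gene_transcript_name_type` layout of
Hyb-style reference libraries); position and separator are configurable.
`string_match` rules fire first-match-wins in file order;
`id_map` is an exact two-column CSV with duplicate keys rejected at load
time. Raw types pass through an idempotent alias table
(`microRNA → miRNA` by default) so the canonical miRNA type string is
`miRNA`. Type detection is case-sensitive: reference libraries are
case-stable, and case-folding would hide data errors. Types are open
strings; vocabulary policy lives in rule files, not code.

miRNA placement follows an exhaustive truth table over the two type
flags: `5p` (only seg1 is an miRNA), `3p` (only seg2), `B` (both),
`N` (neither), `U` (either type flag missing). Re-evaluation overwrites
prior flags rather than erroring, supporting iterative workflows.

## Filtration

Filter specs are flat atom lists (`seg_type_contains`, `seg_type_is`,
`any_seg_type_in`, `mirna_seg_in`, `id_in`/`id_matches`,
`ref_name_contains`, `flag_equals`, `energy_le`/`energy_ge`, `count_ge`)
combined with `all`/`any` and applied as include or exclude. Missing
flags or energies never match and never raise, keeping filtering
streaming-safe; strict pipelines should run `hyb_check`/`hyb_eval`
first. On the CLI, excludes are applied after includes, each group
combined internally with the configured combiner. Exclude is the exact
complement of include, so the two partition any input with order
preserved — a property the test suite checks on randomized specs.

## Analyses

All five analyses update from a single pass: each record is added once,
weighted by the configured count mode. Deterministic outputs: counters
are sorted by descending count with lexicographic tie-breaks, plot
category order follows table order, and palette colors are assigned by
rank from the Bang Wong colorblind-safe palette.

- **energy / fold-energy** summaries report n, total weight, weighted
  mean, min, max, and a fixed-width histogram (default 1.0 kcal/mol bins
  spanning the observed range).
- **type** counts the unordered segment-type pair, with the miRNA member
  listed first when present (`miRNA--mRNA` ≡ `mRNA--miRNA`), plus
  per-slot counters.
- **mirna** counts placements and miRNA/target type pairs.
- **target** tallies hybrids per (miRNA reference, target reference) and
  summarizes per-miRNA totals and unique-target counts.
- **fold** computes the binding profile: position i of the miRNA
  (5′→3′, read-span translated by the merge offset into fold
  coordinates) is *bound* when its dot-bracket character is `(` or `)`.
  Wobble/mismatch detail is not recoverable from dot-bracket alone.
  Because miRNAs differ in length, per-position denominators are always
  reported; the profile is computed under the configured count mode
  **and** record-weighted, since the right weighting is dataset-
  dependent.
- Records lacking what an analysis needs (type flags, `miRNA_seg`, an
  attached fold) are tallied as skipped for that analysis, never errors.
- `B`-placement records count under `B` in the placement distribution
  but are excluded from target analysis and the binding profile by
  default; `both_as_mirna=True` treats seg1 as the miRNA instead. The
  default avoids double-reading a miRNA–miRNA chimera as a targeting
  event.

## Command-line tools

`hyb_check`, `hyb_eval`, `hyb_filter`, and `hyb_analyze` are thin shells
over the library; a run's TSVs are byte-identical to the API path under
the same settings. Flags map one-to-one to library parameters; a YAML
config file may supply any of them with precedence CLI > config >
defaults; every run logs a provenance header (tool, version, resolved
settings) to stderr. Exit codes: 0 success, 1 usage/configuration error,
2 data error. Outputs are written next to the input (or to `--out-dir`)
as `stem + suffix` (`.evaluated.hyb`, `.filtered.hyb`); inputs are never
modified in place.

## Synthetic data generator

`chimerakit.fixtures` emulates a qCLASH-style dataset: each record draws
a placement from a mixture (defaults 5p 0.40, 3p 0.20, B 0.10, N 0.30 —
a miRNA-enriched library with realistic contamination), an miRNA
(18–22 nt, Hyb-style 4-part ids ending `_microRNA`) and a target drawn
by type mixture (defaults mRNA 0.60, lncRNA 0.30, rRNA 0.10; sequences
20–40 nt), a `count_total` from a geometric distribution (p = 0.5,
support ≥ 1, mimicking the head-heavy read-count distribution of
clustered hybrids), and a duplex of b base pairs (uniform on 4–12) as a
contiguous block placed at a seeded offset within the miRNA and mirrored
on the target side. The pseudo-energy is `-(0.5·b) + U(-0.5, 0.5)`
kcal/mol — a deliberately simple, monotone-in-b synthetic model for
testing plumbing and weighted statistics, not thermodynamics. Vienna
records carry the RNA transliteration of the read sequence, exercising
the T/U equivalence; an optional mismatch rate mutates one base per
selected fold record for negative-control merging. A ground-truth table
(types, placement, count, 0/1 bound vector) accompanies every dataset,
and a defect injector produces files with exactly one known bad record
(`field-count`, `bad-coordinate`, `unbalanced-fold`, `seq-mismatch`).

What passing on this generator shows — and does not. It proves exact
bookkeeping: parsing, byte-faithful writing, annotation, filtering,
merging, weighting, and the binding-profile arithmetic all invert the
generator exactly. It does not validate biological realism: real folds
are not single contiguous blocks, real energies are not linear in pair
count, and real data contain sequencing errors, adapters, and multi-way
chimeras that the generator (and the 2-segment format) deliberately
omit.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use n = 1000 records for
round-trip and closed-loop recovery checks, n = 500 for the
binding-profile oracle, n = 400 at a 5% mismatch rate for merge
robustness, and 50 randomized specs for the filter partition property —
sizes at which binomial 3σ bounds on the mixtures are tight enough to be
meaningful while the whole suite runs in seconds. All counter
comparisons are exact (integer arithmetic); the only tolerances in the
toolkit are the 3σ binomial bounds on empirical mixture proportions.
Ties in result tables are broken lexicographically; histogram bin edges
are floor/ceil-aligned multiples of the bin width; an empty accumulator
finalizes to empty tables and plots become warnings + no-ops.

## Known limitations

- Only 2-segment chimeras: multi-way dialects are field-count errors by
  design.
- No folding computation, pseudoknots, or `.ct` connectivity tables.
- No genomic re-annotation: `target_reg` is carried as an opaque flag.
- Classification is identifier-driven; datasets with uninformative
  reference names need an id-map or custom callable.
- The boolean filter language is two-level include/exclude, not a full
  expression tree.
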