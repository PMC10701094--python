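# chimerakit

A Python toolkit for **hyb-format chimeric (hybrid) RNA sequence data**
from RNA-ligation experiments (CLASH, qCLASH, CLEAR-CLIP, chimeric
e-CLIP). These methods ligate an miRNA to its bound target RNA in situ, so
a single sequencing read — a *hybrid* — contains two segments that directly
report one miRNA–target interaction. Hybrid callers emit these reads in the
tab-delimited, GFF-related **hyb** format, often paired with predicted
secondary structures in Vienna **dot-bracket** files.

chimerakit is for bioinformaticians who have hyb output in hand and need
to annotate, filter, and summarize it. It provides:

- **Record model and bit-faithful I/O** — `HybRecord` / `HybFile` for hyb
  files (15 fixed columns + optional `key=value;` flags column, `.` for
  missing values), `FoldRecord` / `ViennaFile` for 3-line dot-bracket
  records with an optional parenthesized free energy. Unmodified records
  round-trip byte-exactly.
- **Annotation** — segment biotypes (miRNA, mRNA, tRNA, …) inferred from
  reference identifiers by a user-selectable method (identifier splitting
  for Hyb-style `gene_transcript_name_type` ids, ordered pattern-matching
  rules, exact id→type CSV maps, or any callable), followed by miRNA
  placement annotation: `miRNA_seg` ∈ {`5p`, `3p`, `B`, `N`, `U`}.
- **Filtration** — predicate atoms over types, placements, identifiers,
  flags, energies, and read counts, composed with include/exclude polarity;
  filtering partitions the input exactly and preserves order.
- **Concurrent hyb+fold iteration** — positional (k-th with k-th) merging
  of hyb and Vienna streams with sequence-mismatch checking (T ≡ U).
- **Five streaming analyses** in a single pass: hybrid energy
  distribution, sequence-pair type distribution, miRNA placement and
  miRNA/target type distribution, per-miRNA target tallies, and the
  per-nucleotide **binding profile**: for each miRNA position *i* (5′→3′),

      bound_fraction[i] = (weight of hybrids whose miRNA position i is paired)
                          / (weight of hybrids covering position i)

  where "paired" means the dot-bracket character at that nucleotide is
  `(` or `)`, and weights follow a configurable count mode (`record`,
  `read_count`, or `count_total`). Results are written as TSVs and plotted
  with matplotlib using the colorblind-safe Bang Wong palette.
- **CLI tools** — `hyb_check`, `hyb_eval`, `hyb_filter`, `hyb_analyze`
  (plus `hyb_fixture`), thin shells over the library with standardized
  flags and YAML config support.
- **Seeded synthetic data** — `chimerakit.fixtures` generates paired
  hyb + Vienna files with a full ground-truth table, so every pipeline
  stage is testable without downloads.

## Worked example

```python
import chimerakit as ck

data = ck.generate(ck.FixtureSpec(n_records=500, seed=42))
classifier = ck.hyb_split_classifier()            # last "_" field is the type
records = [ck.evaluate_record(r, classifier) for r in data.hyb_records]
merger = ck.iterate_merge(iter(records), iter(data.fold_records))
acc = ck.AnalysisAccumulator(count_mode="count_total")
acc.add_records(merger)
res = acc.finalize()
print(res.mirna_placements.to_string(index=False))
```

prints the read-count-weighted miRNA placement distribution:

```
miRNA_seg  count
       5p    434
        N    286
       3p    195
        B     77
```

i.e. 434 weighted hybrids carry the miRNA as the 5′ segment, 195 as the
3′ segment, 77 are miRNA–miRNA chimeras, and 286 contain no miRNA. The
pair-type table, per-miRNA target summary, and binding profile come from
the same pass:

```
         pair  count
  miRNA--mRNA    361
miRNA--lncRNA    185
   mRNA--mRNA    109
 lncRNA--mRNA     92
```

```python
print("%.2f kcal/mol" % res.fold_energy_summary["weighted_mean"])  # -2.60
print(res.binding_profile.fraction[:6])   # [0.11 0.161 0.24 0.318 0.397 0.477]
```

The rising bound fraction over the first positions reflects the
generator's randomly placed duplex blocks; on real data this curve shows
seed-region pairing. The same run from the shell:

```bash
hyb_fixture --n 500 --seed 42 --out-dir demo
hyb_check   --in demo/fixture.hyb --vienna demo/fixture.vienna
hyb_eval    --in demo/fixture.hyb --out-dir demo
hyb_filter  --in demo/fixture.evaluated.hyb --include mirna_seg_in=5p,3p --out-dir demo
hyb_analyze --in demo/fixture.evaluated.filtered.hyb --vienna demo/fixture.vienna \
            --out-dir demo --prefix run --count-mode count_total
```

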