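# Methods

## The p-value representation

GWAS on biobank-scale cohorts produce p-values far below the smallest
positive IEEE-754 double (≈ 4.9 × 10⁻³²⁴); a float pipeline silently turns
them into 0, which then fails range checks and destroys ordering. `PValue`
therefore stores a decimal mantissa m ∈ [1, 10) (a `decimal.Decimal`) and an
unbounded integer exponent e, representing m × 10ᵉ. Canonical form is
enforced at construction, so the total order is simply lexicographic on
(e, m) and thresholding (`p < 5e-8`, `p < 1e-5`) never touches a float.

Choices worth stating:

- **p = 0 is rejected, not floored.** An explicit 0 in input is an
  out-of-range error (`P_OUT_OF_RANGE`); silent coercion hides an upstream
  underflow bug. The reader accepts an opt-in `p_zero_floor` that maps 0 to
  a declared floor with a warning.
- **Rounding is half-even** at every precision reduction (`format_pvalue`,
  privacy rounding): bias-free and platform-reproducible. A carry
  (9.99 → 10.0) re-canonicalises the exponent.
- **The type can hold non-probabilities** (e.g. 2e0). Parsing through
  `parse_pvalue` enforces (0, 1]; the permissive constructor exists so the
  validator can *report* out-of-range values instead of the container
  refusing to hold them.
- Rounding to k significant digits has relative error ≤ 0.5 × 10^(1−k) and
  is monotone non-decreasing, so privacy rounding can merge but never invert
  p-value order. Both properties are asserted exhaustively in the tests.

## Records, datasets, and where validation lives

`SumStatsRecord` and `Dataset` are deliberately permissive containers:
fields hold whatever the file said (after type coercion where possible).
All judgement lives in `validator`, which returns coded findings
(ERROR/WARNING, row, column) rather than raising — a submission tool must
report *all* problems at once, not die on the first. Row 0 is the
file/header level; data rows count from 1. Issue ordering is deterministic
(row, then the standard's printed column order) so reports diff cleanly.

Interpretation decisions embedded in the rules:

- `effect_allele_frequency` is schema-mandatory (the column must exist), but
  missing *values* are accepted when the study metadata declare a
  frequency-masking privacy profile — this reconciles the mandatory-element
  list with the recommended privacy mitigation for sensitive cohorts.
- Both `odds_ratio` and `beta` present is an ERROR (`EFFECT_COLUMN_CONFLICT`):
  one effect scale per file keeps downstream parsing unambiguous. Neither
  present is reported as `MISSING_MANDATORY` with column token `effect`.
- Duplicate (chromosome, position, effect allele, other allele) tuples are a
  WARNING, not an ERROR: multi-allelic sites and legitimate re-tests exist.
- Alleles are non-empty uppercase A/C/G/T strings; indels are full alternate
  sequences. Legacy `D`/`I`/`-` tokens are rejected because they are
  meaningless without a reference genome. Coordinates are 1-based, fully
  closed.
- A genome build is required whenever any record is identified only by
  chromosome + position (`MISSING_GENOME_BUILD`).

## File format

UTF-8, LF, tab-delimited, one header row, one GWAS per file, `NA` for
missing (empty cells are normalised to missing with a warning). Writing is
canonical and byte-deterministic: standard columns in the printed order,
then preserved auxiliary columns. Floats are emitted via `repr` (shortest
round-trip form); p-values are emitted at full stored precision by default,
or through `format_pvalue` when `FileDescriptor.sig_digits` is set. A
multi-study submission is a directory of `<accession>.tsv[.gz]` files with
`<accession>-meta.yaml` sidecars, not a multi-study file — simpler
validation semantics, at the cost of deferring a `study_id` column.

## Harmonisation policy

The alias table (packaged YAML, editable without code changes) maps only
tokens whose community usage is unambiguous (`SNP`, `CHR`, `BP`, `EA`,
`NEA`, `EAF`, `OR`, `BETA`, `SE`, …). Tokens with conflicting conventions —
`A1`/`A2`/`Allele1`/`Allele2`/`ALT`/`REF` for alleles, and `MAF`/`FRQ`/
`FREQ`/`AF`-style frequency headers (minor-allele vs effect-allele
frequency) — are *declared ambiguous* and require an explicit override; a
wrong silent guess would flip effect directions or corrupt frequencies with
no downstream symptom. When two headers claim one element the first wins
and later claimants become ambiguous. The harmonizer performs only the two
normalisations that are provably safe (`chr7` → `7`, lowercase alleles
uppercased), each with a warning; everything else is left for the validator.

## Metadata, lifecycle, FAIR

Metadata are a sidecar YAML/JSON document (the data file stays strictly
tabular). Parsing is lossless and invents nothing; the only default ever
applied is CC0 for an absent license, at write time, behind an explicit
flag. The ancestry vocabulary is packaged configuration seeded from the
standardised ancestry categories used by the major deposition resource;
unknown categories warn rather than fail, since the list is curated, not
closed.

The accession ledger is a *local* stand-in for repository accessioning:
`GCST` + zero-padded serial from 000001, version chains 1..k with SHA-256
content digests of the canonical serialised bytes, retraction as a
tombstone that preserves the accession, metadata and full version history
while blocking new versions. Persistence is an append-only JSON-lines
operation log written *before* the in-memory mutation, so a persistence
failure consumes no serial; replaying the log reconstructs the state.
The real serial-number policy of the central repository is not public;
this scheme is a documented artifact convention, and tokens should be
declared as locally issued in metadata.

FAIR assessment reports all fifteen indicators. Ten are auto-checkable from
a local bundle (identifier presence/pattern/registration, metadata
completeness, identifier-in-metadata, metadata-outlives-data,
vocabulary use, license, provenance link, data validity; the
authentication indicator passes trivially for open data). Five —
searchability, retrieval protocols, protocol openness, API representation
format, qualified cross-references — are repository service properties and
are reported as `not_auto_checkable`, never guessed. rsID coverage is
reported as evidence under the vocabulary indicator rather than gating it,
since full dbSNP coverage is not attainable for all variant types. Note
that the metadata-richness check is shared by definition between F2 and R1,
so a metadata-completeness ablation flips that pair together.

## The simulator

`simulate_sumstats` draws, per variant: EAF ~ Uniform(eaf_range); causal
flag ~ Bernoulli(prop_causal); true effect β ~ Normal(0, effect_sd²) if
causal else 0; SE from the quantitative-trait approximation
1/√(2·n·f·(1−f)); β̂ ~ Normal(β, SE²); and p = 2Φ(−|z|) computed via
`scipy.stats.norm.logsf` so the result lives in log space until it is
stored as a `PValue` (mantissa kept to six significant digits). Under the
null, z is exactly standard normal, so p-values are exactly uniform — this
is what makes the calibration checks (KS uniformity; mean count of
p < 10⁻⁵ equal to n × 10⁻⁵) legitimate expectations rather than tuned
targets. Defaults (10,000 variants, 10,000 samples, 1% causal, effect SD
0.05, EAF ∈ (0.01, 0.5)) describe a modest quantitative-trait GWAS on
common variants.

Deliberately not modelled: linkage disequilibrium, population
stratification, case-control ascertainment, genotyping error. Passing tests
therefore demonstrate correctness of the *format toolchain and its
statistical contracts*, not robustness to the correlation structure of real
genomes. The truth table (causal flags, true effects, exact −log₁₀ p) is
emitted alongside every dataset for power/FDR demonstrations.

The error injector corrupts one cell per requested finding, each in its own
record so findings cannot interact, with values engineered to trigger
exactly one code (corrupted chromosomes/positions are derived from the row
index so two corruptions can never collide into a spurious duplicate-variant
warning). `NONPOS_OR` requires an odds-ratio dataset and `CI_ORDER` requires
confidence bounds; an unsatisfiable request fails loudly with the shortfall.

## Problem sizes and numerical notes

The test suite and the acceptance script use the sizes the guarantees are
stated at: 1,000-record round trips, 50 injection seeds on 500-record
fixtures, 100 KS seeds at 1,000 variants, 200 null GWAS of 100,000 variants
for the top-hit expectation, 10,000 ledger assignments. The
arbitrary-precision oracle in tests is the stdlib `decimal` module with an
80-digit context and widened exponent range — exact for every quantity
checked. Hypothesis property tests run derandomised. Determinism contracts
(byte-identical writes, identical reports) are asserted on identical
in-memory inputs; ledger timestamps are excluded from those comparisons.

## Known limitations

- No variant normalisation against a reference, no strand/orientation
  checks, no liftover between builds.
- No VCF serialisation and no aggregate (multi-variant burden/SKAT-O)
  association records.
- Ontology IDs are validated by pattern only; no live EFO/PubMed/DOI
  resolution.
- Statistical sanity checks across columns (e.g. p vs β/SE concordance) are
  out of scope for the validation gate.
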