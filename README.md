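# sumstatskit

A toolkit for the standard tab-separated GWAS summary-statistics (SumStats)
format, aimed at data submitters, repository curators, and meta-analysts who
need association results that are valid, harmonised, and FAIR (findable,
accessible, interoperable, reusable) before they are shared or reused.

A GWAS reports, per variant, an effect allele and other allele, the effect
size β (or odds ratio OR), its standard error, the effect-allele frequency
(EAF), and a p-value. The standard fixes the column tokens and mandatory set:

| column | mandatory |
|---|---|
| `variant_id` / `chromosome` + `base_pair_location` | one form of identification (location requires a genome build) |
| `p_value` | yes |
| `effect_allele`, `other_allele` | yes |
| `effect_allele_frequency` | yes |
| `odds_ratio` **or** `beta` | exactly one |
| `standard_error` | yes |
| `ci_upper`, `ci_lower` | optional |

What the package provides:

- **`core_model`** — typed records, and a p-value held as a decimal mantissa
  in [1, 10) with an unbounded integer exponent, so large-cohort p-values like
  3.2 × 10⁻⁴⁵⁰ survive parsing, comparison (`p < 5e-8` without float
  underflow), half-even rounding and re-serialisation exactly.
- **`standard_io`** — byte-deterministic reader/writer for the TSV format
  (gzip supported), `NA` for missing, unknown columns preserved; plus
  top-association extraction (default threshold p < 1 × 10⁻⁵).
- **`harmonizer`** — maps foreign headers (PLINK, METAL, BOLT-LMM, SAIGE, …)
  onto the standard via a shipped alias table, and *refuses to guess* for
  conflicted tokens (`A1`/`A2`, `MAF`-style frequencies) until you supply
  `--map SRC=ELEMENT` overrides.
- **`validator`** — machine-readable ERROR/WARNING findings from a published
  code registry, at header, record and dataset level.
- **`metadata`** — YAML/JSON sidecar schema for the mandatory study
  descriptors (samples, ancestry, imputation, covariates, model, software,
  MAF cutoff, QC, …) with pure rule-based validation.
- **`lifecycle`** — a local GCST-style accession ledger (assign / version /
  retract with tombstones, append-only JSON-lines log) and privacy-reduction
  transforms (mask EAFs, round p-values to k significant digits).
- **`fair`** — per-indicator FAIR self-assessment of a bundle (F1–R1.3),
  honest about which indicators only a hosting repository can satisfy.
- **`synthetic`** — a seeded simulator (null p-values exactly uniform;
  extreme signals exercise the underflow-safe representation) and an error
  injector that plants exactly k findings per validation code, with a log.

## Worked example

```python
from sumstatskit import (
    SimulationParams, simulate_sumstats, write_standard, read_standard,
    extract_top_associations, validate_dataset, parse_pvalue, format_pvalue,
)

dataset, truth = simulate_sumstats(
    SimulationParams(n_variants=10_000, n_samples=50_000,
                     prop_causal=0.01, effect_sd=0.05, seed=7)
)
write_standard(dataset, "GCST000001.tsv")

report = validate_dataset(dataset)
print(report.valid, report.records_checked)   # True 10000

top = extract_top_associations(dataset)       # p < 1e-5
print(len(top.records))                       # 42
best = min(top.records, key=lambda r: (r.p_value.exponent, r.p_value.mantissa))
print(best.variant_id, format_pvalue(best.p_value, 3))   # rs7187 3.60e-49
```

The simulated study recovers its planted signals: of 10,000 variants, 42
reach the top-association threshold, and the strongest (rs7187, p =
3.60 × 10⁻⁴⁹) is one of the ~1% causal variants. On null data
(`prop_causal=0`) the same pipeline returns ~0.1 hits per 10,000 variants,
matching the binomial expectation n · 10⁻⁵.

From the shell:

```bash
sumstatskit simulate --n-variants 10000 --seed 7 --out bundle/
sumstatskit validate bundle/sumstats.tsv            # exit 0 = valid
sumstatskit harmonize plink.assoc.tsv --map A1=effect_allele --map A2=other_allele --out std.tsv
sumstatskit accession --ledger ledger.jsonl assign  # GCST000001
sumstatskit privacy std.tsv --mask-eaf --p-digits 2 --out reduced.tsv
sumstatskit fair bundle/ --json fair.json
```

Exit codes: 0 success/valid, 1 validation failures, 2 usage or I/O error.

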