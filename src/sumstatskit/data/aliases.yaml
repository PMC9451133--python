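# Column-header alias table for the SumStats dialect harmonizer.
#
# `aliases` maps each standard element to source headers (matched
# case-insensitively) that are safe to auto-assign: community usage of these
# tokens is unambiguous.
#
# `ambiguous` lists headers whose community usage conflicts and which are
# therefore *never* auto-assigned — the harmonizer demands an explicit
# override.  A1/A2 (and Allele1/Allele2, ALT/REF) denote the effect allele in
# some tools and the other/reference allele in others; MAF-style frequency
# headers may be minor-allele rather than effect-allele frequency, and a
# wrong guess corrupts every downstream effect interpretation silently.
#
# This file is editable configuration: adding a dialect needs no code change.
aliases:
  variant_id: [variant_id, snp, rsid, rs_id, snpid, markername, marker_name, variant]
  chromosome: [chromosome, chr, chrom, "#chrom", chr_name]
  base_pair_location: [base_pair_location, bp, pos, position, base_pair, bp_location, genpos]
  p_value: [p_value, p, pval, pvalue, p-value, p_val, p.value, p_bolt_lmm]
  effect_allele: [effect_allele, ea]
  other_allele: [other_allele, nea, oa, non_effect_allele]
  effect_allele_frequency: [effect_allele_frequency, eaf]
  odds_ratio: [odds_ratio, or, oddsratio]
  beta: [beta, effect, b, effect_size]
  standard_error: [standard_error, se, stderr, std_err, stderr_beta]
  ci_upper: [ci_upper, upper_ci, ci95_upper]
  ci_lower: [ci_lower, lower_ci, ci95_lower]
ambiguous:
  a1: [effect_allele, other_allele]
  a2: [effect_allele, other_allele]
  allele1: [effect_allele, other_allele]
  allele2: [effect_allele, other_allele]
  allele0: [effect_allele, other_allele]
  alt: [effect_allele, other_allele]
  ref: [effect_allele, other_allele]
  maf: [effect_allele_frequency]
  frq: [effect_allele_frequency]
  freq: [effect_allele_frequency]
  freq1: [effect_allele_frequency]
  af: [effect_allele_frequency]
  a1freq: [effect_allele_frequency]
  af_allele2: [effect_allele_frequency]
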