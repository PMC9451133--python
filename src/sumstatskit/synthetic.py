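"""Synthetic GWAS summary statistics and a deterministic error injector.

The simulator draws a simple but statistically faithful single-variant
association model.  For variant i with effect-allele frequency f_i drawn
uniformly from ``eaf_range``:

* a Bernoulli(``prop_causal``) flag decides whether the variant is causal;
* the true per-allele effect is b_i ~ Normal(0, effect_sd^2) if causal, else 0;
* the standard error follows the quantitative-trait approximation
  se_i = 1 / sqrt(2 * n_samples * f_i * (1 - f_i));
* the estimate is b_hat_i ~ Normal(b_i, se_i^2), z_i = b_hat_i / se_i, and
  the two-sided p-value is 2 * Phi(-|z_i|) computed in log space, so a
  |z| of 45 (p ~ 1e-440) is stored exactly in the decimal PValue type
  instead of underflowing.

Under the null (``prop_causal = 0``) the z-scores are exactly standard
normal, so p-values are exactly Uniform(0, 1) — the calibration every
consumer of the format can rely on.  No linkage disequilibrium, population
structure, or case-control ascertainment is modelled.

The error injector corrupts a clean dataset with exactly the requested
number of findings per validation code, each engineered to trigger that code
and no other, and returns a log of every corrupted cell so the validator can
be checked for both soundness and completeness.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import Dataset, EffectType, PValue, SumStatsError, SumStatsRecord
from .metadata import StudyMetadata, SampleGroup
from .validator import INJECTABLE_CODES

_LOG10 = math.log(10.0)
_LN2 = math.log(2.0)
_BASES = np.array(list("ACGT"))


class InjectionError(SumStatsError):
    code = "INJECTION_UNSATISFIABLE"


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated GWAS.

    Defaults describe a modest quantitative-trait GWAS: 10,000 common
    variants, 10,000 samples, 1% causal variants with per-allele effects of
    SD 0.05 phenotype-SD units, effect-allele frequencies uniform on
    (0.01, 0.5).
    """

    n_variants: int = 10_000
    n_samples: int = 10_000
    prop_causal: float = 0.01
    effect_sd: float = 0.05
    eaf_range: tuple[float, float] = (0.01, 0.5)
    effect_type: EffectType = EffectType.BETA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 <= self.prop_causal <= 1.0:
            raise ValueError("prop_causal must be in [0, 1]")
        if self.effect_sd <= 0:
            raise ValueError("effect_sd must be > 0")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("eaf_range must satisfy 0 < low < high < 1")


def _pvalue_from_log10(log10p: float) -> PValue:
    """Build a canonical PValue from log10(p), mantissa kept to 6 significant digits."""
    exponent = math.floor(log10p)
    mantissa = 10.0 ** (log10p - exponent)
    # f-format of a mantissa in [1, 10) to 5 decimals = 6 significant digits;
    # a value that rounds up to 10.00000 is re-canonicalised by PValue itself
    return PValue(Decimal(f"{mantissa:.5f}"), exponent)


def simulate_sumstats(params: SimulationParams) -> tuple[Dataset, pd.DataFrame]:
    """Simulate one GWAS; returns the dataset and a per-variant truth table.

    The truth table carries the latent state (causal flag, true effect) and
    the exact ``neg_log10_p`` for every variant, supporting power/FDR
    demonstrations and underflow-free thresholding.  Deterministic given
    ``params.seed``; variants are laid out in 22 contiguous chromosome
    blocks with 1-based sequential positions and ``rs`` + index identifiers.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_variants

    eaf = rng.uniform(params.eaf_range[0], params.eaf_range[1], size=n)
    causal = rng.random(n) < params.prop_causal
    beta_true = np.where(causal, rng.normal(0.0, params.effect_sd, size=n), 0.0)
    se = 1.0 / np.sqrt(2.0 * params.n_samples * eaf * (1.0 - eaf))
    beta_hat = beta_true + rng.normal(0.0, 1.0, size=n) * se
    z = beta_hat / se
    log10p = (stats.norm.logsf(np.abs(z)) + _LN2) / _LOG10  # exact in log space

    ea_idx = rng.integers(0, 4, size=n)
    oa_idx = (ea_idx + rng.integers(1, 4, size=n)) % 4
    ea = _BASES[ea_idx]
    oa = _BASES[oa_idx]

    # 22 contiguous chromosome blocks, sequential 1-based positions within each
    bounds = np.linspace(0, n, 23).astype(int)
    chromosome = np.empty(n, dtype=object)
    position = np.empty(n, dtype=np.int64)
    for c in range(22):
        lo, hi = bounds[c], bounds[c + 1]
        chromosome[lo:hi] = str(c + 1)
        position[lo:hi] = np.arange(1, hi - lo + 1)

    is_or = params.effect_type is EffectType.ODDS_RATIO
    ci_lo = beta_hat - 1.959963984540054 * se
    ci_hi = beta_hat + 1.959963984540054 * se
    if is_or:
        est = np.exp(beta_hat)
        ci_lo, ci_hi = np.exp(ci_lo), np.exp(ci_hi)
    else:
        est = beta_hat

    records = []
    append = records.append
    for i in range(n):
        r = SumStatsRecord(
            variant_id=f"rs{i + 1}",
            chromosome=chromosome[i],
            base_pair_location=int(position[i]),
            effect_allele=str(ea[i]),
            other_allele=str(oa[i]),
            effect_allele_frequency=float(eaf[i]),
            standard_error=float(se[i]),
            p_value=_pvalue_from_log10(float(log10p[i])),
            ci_upper=float(ci_hi[i]),
            ci_lower=float(ci_lo[i]),
        )
        if is_or:
            r.odds_ratio = float(est[i])
        else:
            r.beta = float(est[i])
        append(r)

    dataset = Dataset(
        records=records,
        effect_type=params.effect_type,
        genome_build="GRCh38",
        source_name=f"simulated(seed={params.seed})",
    )
    truth = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(n)],
            "chromosome": chromosome,
            "base_pair_location": position,
            "effect_allele_frequency": eaf,
            "is_causal": causal,
            "beta_true": beta_true,
            "beta_hat": beta_hat,
            "z": z,
            "neg_log10_p": -log10p,
        }
    )
    return dataset, truth


def simulated_study_metadata(
    params: SimulationParams, accession: Optional[str] = None
) -> StudyMetadata:
    """A fully populated, conformant metadata document for a simulated study."""
    return StudyMetadata(
        accession=accession,
        trait_label="simulated quantitative trait",
        trait_efo_id="EFO_0004725",
        measurement_method="simulated continuous measurement",
        samples=[
            SampleGroup(
                n_total=params.n_samples,
                ancestry_category="NR",
                cohort_names=["SYNTH"],
            )
        ],
        genotyping_technology="array",
        imputation_method="none (effects simulated directly)",
        imputation_panel="not applicable (simulation)",
        covariates=["none"],
        analysis_software=f"sumstatskit.synthetic (seed={params.seed})",
        analysis_model="additive per-allele linear model",
        maf_cutoff=params.eaf_range[0],
        n_variants_analyzed=params.n_variants,
        genome_build="GRCh38",
        qc_description="synthetic data; no QC required",
        inclusion_exclusion="all simulated samples included",
        license="CC0",
        doi="10.0000/synthetic-study",
    )


# -- error injection --------------------------------------------------------


@dataclass(frozen=True)
class ErrorInjectionSpec:
    """How many findings of each validation code to plant, and where not to overlap."""

    counts: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for code, k in self.counts.items():
            if code not in INJECTABLE_CODES:
                raise InjectionError(f"code {code!r} is not injectable")
            if k < 0:
                raise InjectionError(f"negative count for {code!r}")


@dataclass(frozen=True)
class InjectionRecord:
    """One corrupted cell: where, which code it triggers, and both values."""

    row: int  # 1-based data row, matching validator coordinates
    column: str
    code: str
    original: str
    corrupted: str


def _corrupt(code: str, record: SumStatsRecord, row: int) -> tuple[str, str, str]:
    """Mutate ``record`` to trigger exactly ``code``; returns (column, old, new).

    Corrupted chromosome/position values are derived from ``row`` so two
    corruptions can never collide into a spurious DUPLICATE_VARIANT finding.
    """
    if code == "P_OUT_OF_RANGE":
        old = str(record.p_value)
        record.p_value = PValue(Decimal(2), 0)
        return "p_value", old, str(record.p_value)
    if code == "EAF_OUT_OF_RANGE":
        old = repr(record.effect_allele_frequency)
        record.effect_allele_frequency = 1.5
        return "effect_allele_frequency", old, "1.5"
    if code == "BAD_ALLELE":
        old = str(record.effect_allele)
        record.effect_allele = "N"
        return "effect_allele", old, "N"
    if code == "ALLELES_IDENTICAL":
        old = str(record.other_allele)
        record.other_allele = record.effect_allele
        return "other_allele", old, str(record.other_allele)
    if code == "BAD_CHROMOSOME":
        old = str(record.chromosome)
        record.chromosome = str(100 + row)
        return "chromosome", old, record.chromosome
    if code == "BAD_POSITION":
        old = str(record.base_pair_location)
        record.base_pair_location = -row
        return "base_pair_location", old, str(-row)
    if code == "BAD_RSID":
        old = str(record.variant_id)
        record.variant_id = "ss" + (old[2:] if old.startswith("rs") else "0")
        return "variant_id", old, record.variant_id
    if code == "NEG_SE":
        old = repr(record.standard_error)
        record.standard_error = -abs(record.standard_error or 1.0)
        return "standard_error", old, repr(record.standard_error)
    if code == "NONPOS_OR":
        old = repr(record.odds_ratio)
        record.odds_ratio = -0.3
        return "odds_ratio", old, "-0.3"
    if code == "CI_ORDER":
        old = f"[{record.ci_lower}, {record.ci_upper}]"
        record.ci_lower = (record.ci_upper or 0.0) + 1.0
        return "ci_lower", old, f"[{record.ci_lower}, {record.ci_upper}]"
    if code == "MISSING_MANDATORY_VALUE":
        old = repr(record.standard_error)
        record.standard_error = None
        return "standard_error", old, "NA"
    raise InjectionError(f"no corruption recipe for {code!r}")  # pragma: no cover


def _eligible(code: str, record: SumStatsRecord, effect_type: EffectType) -> bool:
    if code == "NONPOS_OR":
        return effect_type is EffectType.ODDS_RATIO and record.odds_ratio is not None
    if code == "CI_ORDER":
        return record.ci_lower is not None and record.ci_upper is not None
    if code == "BAD_RSID":
        # keep the record identified via chromosome+position after corruption
        return record.variant_id is not None
    if code == "ALLELES_IDENTICAL":
        return record.effect_allele is not None
    return True


def inject_errors(
    dataset: Dataset, spec: ErrorInjectionSpec
) -> tuple[Dataset, list[InjectionRecord]]:
    """Plant validation findings into a copy of a clean dataset.

    Each requested finding corrupts one cell in its own record (records are
    never shared between codes, so findings cannot interact), with a value
    chosen to trigger exactly the requested code.  Deterministic given
    ``spec.seed``.  Raises :class:`InjectionError` with the shortfall when
    the dataset cannot host the request.
    """
    out = copy.deepcopy(dataset)
    n = len(out.records)
    total = sum(spec.counts.values())
    if total > n:
        raise InjectionError(f"requested {total} corruptions but only {n} records available")

    rng = np.random.default_rng(spec.seed)
    order = [int(i) for i in rng.permutation(n)]
    log: list[InjectionRecord] = []

    for code in sorted(spec.counts):  # sorted for determinism
        need = spec.counts[code]
        planted = 0
        scanned = 0
        while planted < need and scanned < len(order):
            idx = order[scanned]
            record = out.records[idx]
            if _eligible(code, record, out.effect_type):
                column, old, new = _corrupt(code, record, idx + 1)
                log.append(InjectionRecord(row=idx + 1, column=column, code=code, original=old, corrupted=new))
                planted += 1
                # remove this row from the pool
                order.pop(scanned)
            else:
                scanned += 1
        if planted < need:
            raise InjectionError(
                f"cannot plant {need} findings of {code}: only {planted} eligible records"
            )

    log.sort(key=lambda r: (r.row, r.column, r.code))
    return out, log
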