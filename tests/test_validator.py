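"""Validator rules: header-level, record-level, dataset-level, and the
soundness/completeness contract against the error injector."""

from __future__ import annotations

import copy
from decimal import Decimal

import pytest

from sumstatskit import (
    Dataset,
    EffectType,
    ErrorInjectionSpec,
    INJECTABLE_CODES,
    PValue,
    SimulationParams,
    SumStatsRecord,
    check_header,
    inject_errors,
    parse_pvalue,
    simulate_sumstats,
    validate_dataset,
    validate_record,
)
from sumstatskit.core_model import standard_column_order

FULL_BETA_HEADER = list(standard_column_order(EffectType.BETA))


def codes(issues):
    return [i.code for i in issues]


class TestCheckHeader:
    def test_full_standard_header_is_clean(self):
        assert check_header(FULL_BETA_HEADER) == []
        assert check_header(standard_column_order(EffectType.ODDS_RATIO)) == []

    @pytest.mark.parametrize(
        "missing",
        ["p_value", "effect_allele", "other_allele", "effect_allele_frequency", "standard_error"],
    )
    def test_each_missing_mandatory_column_is_named(self, missing):
        header = [c for c in FULL_BETA_HEADER if c != missing]
        found = check_header(header)
        assert codes(found) == ["MISSING_MANDATORY"]
        assert found[0].column == missing

    def test_missing_effect_column_reported_once(self):
        header = [c for c in FULL_BETA_HEADER if c != "beta"]
        found = check_header(header)
        assert codes(found) == ["MISSING_MANDATORY"]
        assert found[0].column == "effect"

    def test_both_effect_columns_conflict(self):
        found = check_header(FULL_BETA_HEADER + ["odds_ratio"])
        assert codes(found) == ["EFFECT_COLUMN_CONFLICT"]

    def test_variant_identification_rule(self):
        # chromosome without position and without variant_id
        header = [c for c in FULL_BETA_HEADER if c not in ("variant_id", "base_pair_location")]
        assert "VARIANT_ID_RULE" in codes(check_header(header))
        # either form alone satisfies the rule
        assert "VARIANT_ID_RULE" not in codes(
            check_header([c for c in FULL_BETA_HEADER if c != "variant_id"])
        )
        assert "VARIANT_ID_RULE" not in codes(
            check_header([c for c in FULL_BETA_HEADER if c not in ("chromosome", "base_pair_location")])
        )

    def test_single_ci_bound_warns(self):
        found = check_header([c for c in FULL_BETA_HEADER if c != "ci_lower"])
        assert codes(found) == ["CI_BOUND_SINGLE"]
        assert found[0].severity == "WARNING"


def valid_record() -> SumStatsRecord:
    return SumStatsRecord(
        variant_id="rs1",
        chromosome="1",
        base_pair_location=1000,
        effect_allele="A",
        other_allele="G",
        effect_allele_frequency=0.3,
        beta=0.05,
        standard_error=0.01,
        p_value=parse_pvalue("1e-4"),
        ci_lower=0.03,
        ci_upper=0.07,
    )


class TestValidateRecord:
    def test_fully_valid_record_has_no_findings(self):
        assert validate_record(valid_record(), 1) == []

    @pytest.mark.parametrize(
        "mutation,expected",
        [
            (dict(effect_allele_frequency=1.2), "EAF_OUT_OF_RANGE"),
            (dict(effect_allele_frequency=-0.1), "EAF_OUT_OF_RANGE"),
            (dict(effect_allele="N"), "BAD_ALLELE"),
            (dict(other_allele="a"), "BAD_ALLELE"),
            (dict(other_allele="A"), "ALLELES_IDENTICAL"),
            (dict(chromosome="23"), "BAD_CHROMOSOME"),
            (dict(chromosome="chr1"), "BAD_CHROMOSOME"),
            (dict(base_pair_location=0), "BAD_POSITION"),
            (dict(base_pair_location=-5), "BAD_POSITION"),
            (dict(variant_id="ss123"), "BAD_RSID"),
            (dict(variant_id="rs12x"), "BAD_RSID"),
            (dict(standard_error=-0.01), "NEG_SE"),
            (dict(p_value=PValue(Decimal(2), 0)), "P_OUT_OF_RANGE"),
            (dict(ci_lower=0.08), "CI_ORDER"),
            (dict(p_value=None), "MISSING_MANDATORY_VALUE"),
            (dict(standard_error=None), "MISSING_MANDATORY_VALUE"),
            (dict(effect_allele_frequency=None), "MISSING_MANDATORY_VALUE"),
        ],
    )
    def test_each_violation_yields_exactly_its_code(self, mutation, expected):
        record = valid_record()
        for attr, value in mutation.items():
            setattr(record, attr, value)
        found = validate_record(record, 7)
        assert codes(found) == [expected]
        assert found[0].row == 7

    def test_nonpositive_odds_ratio(self):
        record = valid_record()
        record.beta = None
        record.odds_ratio = -0.3
        found = validate_record(record, 1, effect_column="odds_ratio")
        assert codes(found) == ["NONPOS_OR"]

    def test_sex_and_mito_chromosomes_accepted(self):
        for token in ("X", "Y", "MT", "22"):
            record = valid_record()
            record.chromosome = token
            assert validate_record(record, 1) == []

    def test_masked_eaf_allowed_under_privacy_profile(self):
        record = valid_record()
        record.effect_allele_frequency = None
        assert validate_record(record, 1, eaf_optional=True) == []


class TestValidateDataset:
    def test_clean_simulated_dataset_is_valid(self):
        dataset, _ = simulate_sumstats(SimulationParams(n_variants=500, seed=4))
        report = validate_dataset(dataset)
        assert report.valid
        assert report.records_checked == 500
        assert report.counts_by_code == {}

    def test_empty_dataset_is_invalid(self):
        report = validate_dataset(Dataset(records=[]))
        assert not report.valid
        assert "EMPTY_DATASET" in report.counts_by_code

    def test_duplicate_variant_tuple_warns(self, beta_dataset):
        dataset = copy.deepcopy(beta_dataset)
        dataset.records.append(copy.deepcopy(dataset.records[0]))
        dataset.records[-1].variant_id = "rs999999"
        report = validate_dataset(dataset)
        assert report.counts_by_code.get("DUPLICATE_VARIANT") == 1
        assert report.valid  # warning, not error

    def test_missing_genome_build_flagged_when_position_identified(self, beta_dataset):
        dataset = copy.deepcopy(beta_dataset)
        dataset.genome_build = None
        dataset.records[0].variant_id = None
        report = validate_dataset(dataset)
        assert "MISSING_GENOME_BUILD" in report.counts_by_code

    def test_report_counts_sum_to_issue_count(self, or_dataset):
        corrupted, _ = inject_errors(
            or_dataset, ErrorInjectionSpec(counts={"NEG_SE": 3, "BAD_ALLELE": 2}, seed=1)
        )
        report = validate_dataset(corrupted)
        assert sum(report.counts_by_code.values()) == len(report.issues)
        assert report.counts_by_code == {"NEG_SE": 3, "BAD_ALLELE": 2}

    def test_issue_ordering_is_deterministic(self, or_dataset):
        corrupted, _ = inject_errors(
            or_dataset, ErrorInjectionSpec(counts={c: 3 for c in INJECTABLE_CODES}, seed=2)
        )
        a = validate_dataset(corrupted)
        b = validate_dataset(copy.deepcopy(corrupted))
        assert a.issues == b.issues
        rows = [i.row for i in a.issues]
        assert rows == sorted(rows)

    def test_valid_flag_monotone_under_record_removal(self, or_dataset):
        corrupted, log = inject_errors(
            or_dataset, ErrorInjectionSpec(counts={"NEG_SE": 1}, seed=3)
        )
        bad_row = log[0].row
        del corrupted.records[bad_row - 1]
        assert validate_dataset(corrupted).valid


class TestInjectorCrossOracle:
    """Soundness and completeness: planted findings are found, nothing else is."""

    @pytest.mark.parametrize("seed", range(10))
    def test_injection_log_and_findings_agree_as_multisets(self, or_dataset, seed):
        spec = ErrorInjectionSpec(counts={c: 5 for c in INJECTABLE_CODES}, seed=seed)
        corrupted, log = inject_errors(or_dataset, spec)
        report = validate_dataset(corrupted)
        found = sorted((i.row, i.column, i.code) for i in report.issues)
        planted = sorted((r.row, r.column, r.code) for r in log)
        assert found == planted
        assert validate_dataset(or_dataset).counts_by_code == {}
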