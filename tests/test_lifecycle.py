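"""Accession ledger semantics and privacy-reduction transforms."""

from __future__ import annotations

import copy
import io
from decimal import Decimal, localcontext

import pytest

from sumstatskit import (
    AccessionLedger,
    FileDescriptor,
    PrivacyProfile,
    SimulationParams,
    apply_privacy_profile,
    dataset_digest,
    simulate_sumstats,
    simulated_study_metadata,
    write_standard,
)
from sumstatskit.lifecycle import RetractedAccessionError, UnknownAccessionError


class TestLedger:
    def test_fresh_ledger_issues_gcst000001(self):
        ledger = AccessionLedger()
        assert ledger.assign_accession() == "GCST000001"

    def test_successive_tokens_increase_lexicographically_and_numerically(self):
        ledger = AccessionLedger()
        tokens = [ledger.assign_accession() for _ in range(50)]
        assert tokens == sorted(tokens)
        serials = [int(t[4:]) for t in tokens]
        assert serials == list(range(1, 51))

    def test_version_chain_is_contiguous(self):
        ledger = AccessionLedger()
        acc = ledger.assign_accession()
        assert ledger.register_version(acc, "sha256:a") == 1
        assert ledger.register_version(acc, "sha256:b") == 2
        assert ledger.register_version(acc, "sha256:c") == 3
        assert ledger.latest(acc) == 3
        assert [v.number for v in ledger.status(acc).versions] == [1, 2, 3]

    def test_unknown_accession_errors(self):
        ledger = AccessionLedger()
        with pytest.raises(UnknownAccessionError):
            ledger.register_version("GCST999999", "sha256:x")
        with pytest.raises(UnknownAccessionError):
            ledger.status("GCST999999")

    def test_retraction_blocks_new_versions_but_keeps_history(self):
        ledger = AccessionLedger()
        acc = ledger.assign_accession()
        ledger.register_version(acc, "sha256:a")
        ledger.register_version(acc, "sha256:b")
        before = copy.deepcopy(ledger.status(acc).versions)
        entry = ledger.retract(acc, "sample mix-up")
        assert entry.status == "retracted"
        assert entry.retraction_reason == "sample mix-up"
        assert entry.versions == before  # history intact
        with pytest.raises(RetractedAccessionError):
            ledger.register_version(acc, "sha256:c")

    def test_double_retraction_is_idempotent(self, caplog):
        ledger = AccessionLedger()
        acc = ledger.assign_accession()
        first = ledger.retract(acc, "reason one")
        with caplog.at_level("WARNING"):
            second = ledger.retract(acc, "reason two")
        assert second.retraction_reason == first.retraction_reason == "reason one"
        assert "idempotent" in caplog.text

    def test_log_replay_reconstructs_state(self, tmp_path):
        path = tmp_path / "ledger.jsonl"
        ledger = AccessionLedger.load(path)
        a = ledger.assign_accession()
        b = ledger.assign_accession()
        ledger.register_version(a, "sha256:1")
        ledger.register_version(a, "sha256:2")
        ledger.retract(b, "withdrawn")
        replayed = AccessionLedger.load(path)
        assert replayed.next_serial == ledger.next_serial
        assert replayed.entries.keys() == ledger.entries.keys()
        assert replayed.status(a).versions == ledger.status(a).versions
        assert replayed.status(b).status == "retracted"
        # serials continue where the log left off
        assert replayed.assign_accession() == "GCST000003"

    def test_persistence_failure_consumes_no_serial(self, tmp_path):
        ledger = AccessionLedger.load(tmp_path / "ledger.jsonl")
        ledger.assign_accession()
        ledger.path = tmp_path / "missing-dir" / "ledger.jsonl"
        with pytest.raises(Exception):
            ledger.assign_accession()
        assert ledger.next_serial == 2
        assert len(ledger.entries) == 1

    def test_digest_is_content_addressed(self, beta_dataset, or_dataset):
        assert dataset_digest(beta_dataset) == dataset_digest(copy.deepcopy(beta_dataset))
        assert dataset_digest(beta_dataset) != dataset_digest(or_dataset)
        assert dataset_digest(beta_dataset).startswith("sha256:")


class TestPrivacyProfile:
    def test_profile_must_enable_a_transform(self):
        with pytest.raises(ValueError):
            PrivacyProfile()

    def test_masking_blanks_every_frequency_and_nothing_else(self, beta_dataset):
        meta = simulated_study_metadata(SimulationParams())
        reduced, new_meta = apply_privacy_profile(
            beta_dataset, meta, PrivacyProfile(mask_frequencies=True)
        )
        assert all(r.effect_allele_frequency is None for r in reduced.records)
        assert new_meta.privacy_profile_applied == "mask_frequencies"
        # all other columns byte-identical
        original, masked = io.StringIO(), io.StringIO()
        write_standard(beta_dataset, FileDescriptor(stream=original))
        write_standard(reduced, FileDescriptor(stream=masked))
        eaf_col = original.getvalue().splitlines()[0].split("\t").index("effect_allele_frequency")
        for before, after in zip(
            original.getvalue().splitlines(), masked.getvalue().splitlines()
        ):
            cells_before = before.split("\t")
            cells_after = after.split("\t")
            cells_before[eaf_col] = cells_after[eaf_col] = "-"
            assert cells_before == cells_after

    def test_rounding_example(self, beta_dataset):
        from sumstatskit import parse_pvalue

        dataset = copy.deepcopy(beta_dataset)
        dataset.records[0].p_value = parse_pvalue("3.14159e-8")
        meta = simulated_study_metadata(SimulationParams())
        reduced, _ = apply_privacy_profile(dataset, meta, PrivacyProfile(p_sig_digits=2))
        assert str(reduced.records[0].p_value) == "3.1e-8"

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_relative_error_bound_from_half_even_rounding(self, beta_dataset, k):
        meta = simulated_study_metadata(SimulationParams())
        reduced, _ = apply_privacy_profile(
            beta_dataset, meta, PrivacyProfile(p_sig_digits=k)
        )
        bound = Decimal("0.5").scaleb(1 - k)
        with localcontext() as ctx:
            ctx.prec = 60
            for before, after in zip(beta_dataset.records, reduced.records):
                orig = before.p_value.mantissa.scaleb(before.p_value.exponent)
                new = after.p_value.mantissa.scaleb(after.p_value.exponent)
                assert abs(new - orig) / orig <= bound

    def test_rounding_preserves_nonstrict_order(self, beta_dataset):
        meta = simulated_study_metadata(SimulationParams())
        reduced, _ = apply_privacy_profile(
            beta_dataset, meta, PrivacyProfile(p_sig_digits=1)
        )
        order = sorted(range(len(beta_dataset)), key=lambda i: (
            beta_dataset.records[i].p_value.exponent,
            beta_dataset.records[i].p_value.mantissa,
        ))
        rounded = [reduced.records[i].p_value for i in order]
        assert all(a <= b for a, b in zip(rounded, rounded[1:]))

    def test_transform_is_idempotent(self, beta_dataset):
        meta = simulated_study_metadata(SimulationParams())
        profile = PrivacyProfile(mask_frequencies=True, p_sig_digits=2)
        once, meta_once = apply_privacy_profile(beta_dataset, meta, profile)
        twice, meta_twice = apply_privacy_profile(once, meta_once, profile)
        assert once.records == twice.records
        assert meta_once.privacy_profile_applied == meta_twice.privacy_profile_applied

    def test_masked_dataset_still_validates_with_declared_profile(self, beta_dataset):
        from sumstatskit import validate_dataset

        meta = simulated_study_metadata(SimulationParams())
        reduced, new_meta = apply_privacy_profile(
            beta_dataset, meta, PrivacyProfile(mask_frequencies=True)
        )
        assert not validate_dataset(reduced).valid  # undeclared masking fails
        assert validate_dataset(reduced, new_meta).valid
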