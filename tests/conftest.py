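"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import pytest

from sumstatskit import (
    EffectType,
    SimulationParams,
    simulate_sumstats,
    simulated_study_metadata,
)


@pytest.fixture(scope="session")
def beta_dataset():
    """A clean 200-variant beta-effect dataset (session-cached, treat as read-only)."""
    dataset, _ = simulate_sumstats(SimulationParams(n_variants=200, seed=11))
    return dataset


@pytest.fixture(scope="session")
def or_dataset():
    """A clean 200-variant odds-ratio dataset (session-cached, treat as read-only)."""
    dataset, _ = simulate_sumstats(
        SimulationParams(n_variants=200, seed=12, effect_type=EffectType.ODDS_RATIO)
    )
    return dataset


@pytest.fixture()
def conformant_metadata():
    """Fully populated metadata that satisfies every validation rule."""
    meta = simulated_study_metadata(SimulationParams(n_variants=200, seed=11))
    meta.accession = "GCST000001"
    return meta


#: (name, headers, expected element assignments, expected ambiguous headers)
DIALECT_FIXTURES = [
    (
        "plink_assoc",
        ["SNP", "CHR", "BP", "A1", "A2", "OR", "SE", "P"],
        {
            "SNP": "variant_id",
            "CHR": "chromosome",
            "BP": "base_pair_location",
            "OR": "odds_ratio",
            "SE": "standard_error",
            "P": "p_value",
        },
        {"A1", "A2"},
    ),
    (
        "metal",
        ["MarkerName", "Allele1", "Allele2", "Freq1", "Effect", "StdErr", "P-value"],
        {
            "MarkerName": "variant_id",
            "Effect": "beta",
            "StdErr": "standard_error",
            "P-value": "p_value",
        },
        {"Allele1", "Allele2", "Freq1"},
    ),
    (
        "bolt_lmm",
        ["SNP", "CHR", "BP", "ALLELE1", "ALLELE0", "A1FREQ", "BETA", "SE", "P_BOLT_LMM"],
        {
            "SNP": "variant_id",
            "CHR": "chromosome",
            "BP": "base_pair_location",
            "BETA": "beta",
            "SE": "standard_error",
            "P_BOLT_LMM": "p_value",
        },
        {"ALLELE1", "ALLELE0", "A1FREQ"},
    ),
    (
        "saige",
        ["CHR", "POS", "SNPID", "Allele1", "Allele2", "AF_Allele2", "BETA", "SE", "p.value"],
        {
            "CHR": "chromosome",
            "POS": "base_pair_location",
            "SNPID": "variant_id",
            "BETA": "beta",
            "SE": "standard_error",
            "p.value": "p_value",
        },
        {"Allele1", "Allele2", "AF_Allele2"},
    ),
    (
        "legacy_eaf",
        ["snp", "chr", "bp", "p", "ea", "nea", "eaf", "beta", "se"],
        {
            "snp": "variant_id",
            "chr": "chromosome",
            "bp": "base_pair_location",
            "p": "p_value",
            "ea": "effect_allele",
            "nea": "other_allele",
            "eaf": "effect_allele_frequency",
            "beta": "beta",
            "se": "standard_error",
        },
        set(),
    ),
]
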