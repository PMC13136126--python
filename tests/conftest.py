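"""Shared fixtures: synthetic families, calibrated models, planted genome."""

from __future__ import annotations

import pytest

from luxminer import genome_scan, profiles, simulate


@pytest.fixture(scope="session")
def kit() -> simulate.FamilyKit:
    return simulate.FamilyKit(13)


@pytest.fixture(scope="session")
def training_sets(kit):
    return kit.training_sets(30, 113)


@pytest.fixture(scope="session")
def luxi_model(training_sets) -> profiles.ProfileModel:
    luxi, _, _, _ = training_sets
    return profiles.build_profile([s for _, s in luxi], family="LuxI", null_seed=0)


@pytest.fixture(scope="session")
def luxr_model(training_sets) -> profiles.ProfileModel:
    _, luxr, _, _ = training_sets
    return profiles.build_profile([s for _, s in luxr], family="LuxR", null_seed=0)


@pytest.fixture(scope="session")
def domain_models(training_sets) -> dict[str, profiles.ProfileModel]:
    _, _, abd, hth = training_sets
    return {
        "IPR005143": profiles.build_profile([s for _, s in abd], family="ABD", null_seed=0),
        "IPR000792": profiles.build_profile([s for _, s in hth], family="HTH", null_seed=0),
    }


@pytest.fixture(scope="session")
def planted_genome(kit):
    """(contig seqs, features, truth table, planted domain hits) for the
    default multi-layout plan."""
    plan = simulate.default_plan(13)
    return simulate.generate_genome(plan, kit)


@pytest.fixture(scope="session")
def planted_proteome(planted_genome):
    genome, features, _, _ = planted_genome
    return genome_scan.extract_proteome(genome, features)
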