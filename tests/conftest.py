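"""Shared fixtures: scaled-down planted truths for fast unit tests and one
session-scoped default-scale run reused by the recovery tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from introscan.scan import IntrogressionScan
from introscan.simulate import (
    HET,
    HOM_REF,
    IntrogressionTruth,
    SimulationConfig,
    generate_congenic_callset,
    generate_strain_panel,
)

MB = 1_000_000


@pytest.fixture
def mini_truth() -> IntrogressionTruth:
    """A 6 Mb mosaic on a 10 Mb chromosome with a 0.8 Mb devoid gap."""
    return IntrogressionTruth(
        chromosome="c1",
        blocks=(
            (2 * MB, 5 * MB, HET),
            (5 * MB, int(5.4 * MB), HOM_REF),
            (int(5.4 * MB), 8 * MB, HET),
        ),
        devoid_gaps=((3 * MB, int(3.8 * MB)),),
        private_site_region=(6 * MB, 7 * MB),
    )


@pytest.fixture
def mini_config() -> SimulationConfig:
    return SimulationConfig(
        chromosome_lengths={"c1": 10 * MB, "c2": 8 * MB},
        het_site_rate=300.0,
        artifact_cluster_rate=5.0,
        seed=7,
    )


@pytest.fixture
def mini_callset(mini_config, mini_truth):
    return generate_congenic_callset(mini_config, mini_truth)


@pytest.fixture(scope="session")
def default_run():
    """One default-scale simulated genome, scanned with default parameters."""
    config = SimulationConfig(seed=1)
    calls, truth_record = generate_congenic_callset(config)
    result = IntrogressionScan(calls, config.chromosome_lengths).fit()
    panel, site_truth = generate_strain_panel(config, calls, truth_record)
    return {
        "config": config,
        "calls": calls,
        "truth_record": truth_record,
        "result": result,
        "panel": panel,
        "site_truth": site_truth,
    }


@pytest.fixture
def toy_calls() -> pd.DataFrame:
    """Hand-built call frame covering every genotype and filter state."""
    rows = [
        # chromosome, position, ref, alt, genotype, MQ, status_pass
        ("c1", 100, "A", "G", "het", 650.0, True),
        ("c1", 200, "C", "T", "het", 199.0, True),   # below MQ threshold
        ("c1", 300, "G", "A", "het", 200.0, True),   # exactly at threshold
        ("c1", 400, "T", "C", "het", 900.0, False),  # failed status check
        ("c1", 500, "A", "C", "hom_ref", 700.0, True),
        ("c1", 600, "G", "T", "hom_alt", 700.0, True),
        ("c1", 700, "C", "G", "missing", 700.0, True),
        ("c2", 150, "T", "A", "het", np.nan, True),  # missing MQ
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "position", "ref", "alt",
            "genotype", "mapping_quality", "status_pass",
        ],
    )
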