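"""Shared fixtures: small synthetic genomes are expensive enough to build
once per session; truth objects derived from them are rebuilt per test
when they mutate the reference."""

from __future__ import annotations

import pytest

from mnthripsis import simulate as sim

SMALL_SPEC = sim.GenomeSpec(
    chromosomes=(("chr1", 2_000_000), ("chr2", 4_000_000)),
    snp_density=1 / 5000,
    informative_fraction=0.4,
    aneuploid_chrom="chr2",
)


@pytest.fixture()
def small_genome():
    """A fresh 2-chromosome toy genome (fresh because simulators edit it)."""
    return sim.simulate_reference(SMALL_SPEC, seed=42)


@pytest.fixture(scope="session")
def default_genome():
    """The default 3 x 10 Mb genome; treat as read-only."""
    return sim.simulate_reference(sim.GenomeSpec(), seed=1234)


@pytest.fixture()
def shattering_truth(small_genome):
    return sim.simulate_shattering(
        small_genome, k_breakpoints=8, deletion_fraction=0.4, seed=7,
        min_fragment=150_000,
    )
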