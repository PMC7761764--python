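from pathlib import Path

import pytest

from rrnalink.synthetic_data import simulate_cohort, simulate_layout_suite


@pytest.fixture(scope="session")
def layout_suite(tmp_path_factory):
    """Small six-configuration suite written to disk, with truth objects."""
    outdir = tmp_path_factory.mktemp("layout_suite")
    genomes = simulate_layout_suite(n_per_layout=3, seed=101, outdir=outdir)
    return outdir, genomes


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Linked/mixed/unlinked cohort under study conditions, written to disk."""
    outdir = tmp_path_factory.mktemp("cohort")
    genomes = simulate_cohort((3, 3, 3), seed=42, outdir=outdir)
    return outdir, genomes
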