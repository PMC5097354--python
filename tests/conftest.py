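import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dualdemux import (
    ReferenceSet,
    Sample,
    SampleSheet,
    SimConfig,
    classify_run,
    generate_design,
    read_triplets,
    simulate,
)


@pytest.fixture(scope="session")
def toy_sheet() -> SampleSheet:
    """Three samples with well-separated 8-bp dual indices."""
    return SampleSheet(
        [
            Sample("s1", "AAAAAAAA", "CCCCCCCC", ("ref_s1",)),
            Sample("s2", "GGGGGGGG", "TTTTTTTT", ("ref_s2",)),
            Sample("s3", "ACACACAC", "GTGTGTGT", ("ref_s3",)),
        ]
    )


@pytest.fixture(scope="session")
def toy_refs() -> ReferenceSet:
    return ReferenceSet(
        {
            "ref_s1": "AAAACCCCGGGGTTTTAAAA",
            "ref_s2": "TTTTGGGGCCCCAAAATTTT",
            "ref_s3": "ACGTACGTACGTACGTACGT",
        }
    )


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """A mid-sized simulated run shared by integration-level tests:
    14 samples x 1000 reads, default injected misassignment rates."""
    outdir = tmp_path_factory.mktemp("sim_run")
    config = SimConfig(reads_per_sample=1000, seed=101)
    sheet, refs = generate_design(config)
    out = simulate(config, sheet, refs, outdir)
    return config, sheet, refs, out


@pytest.fixture(scope="session")
def sim_outcomes(sim_run):
    config, sheet, refs, out = sim_run
    triplets = read_triplets(out.r1_path, out.i7_path, out.i5_path)
    return classify_run(triplets, sheet, refs)
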