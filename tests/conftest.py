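import numpy as np
import pytest

from tcrdyn.contig_io import ContigRecord
from tcrdyn.simulate import CohortConfig, generate_cohort


@pytest.fixture
def toy_contigs() -> list[ContigRecord]:
    """Two cells: one paired TRA/TRB, one beta-only with a non-productive TRA."""
    return [
        ContigRecord("AAAC-1", "TRB", "CASSLGQF", "TGTGCAAGT", "TRBV9", "TRBJ2", True, 9, 200),
        ContigRecord("AAAC-1", "TRA", "CAVRDF", "TGTGCTGTG", "TRAV3", "TRAJ10", True, 4, 100),
        ContigRecord("CCCT-1", "TRB", "CASSDTQF", "TGTGCAAGC", "TRBV5", "TRBJ1", True, 7, 150),
        ContigRecord("CCCT-1", "TRA", "", "", "TRAV1", "TRAJ4", False, 2, 40),
    ]


@pytest.fixture
def toy_csv(tmp_path, toy_contigs):
    from tcrdyn.contig_io import write_contig_table

    path = tmp_path / "contigs.csv"
    write_contig_table(toy_contigs, path)
    return path


#: Small but structurally complete cohort used by pipeline-level tests.
SMALL_COHORT = dict(
    seed=7,
    n_patients=3,
    n_healthy=1,
    cells_per_sample=600,
    n_clones=1200,
    healthy_n_clones=1500,
)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    cfg = CohortConfig(**SMALL_COHORT)
    return cfg, generate_cohort(cfg, outdir)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
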