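import pytest
from hypothesis import settings

from spidrokit import synthetic

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

#: The five screened motifs with their reported database frequencies.
TABLE_MOTIFS = {
    "GVLEGV": 26,
    "KTAAWN": 37,
    "ITVQQ": 3,
    "SVSVSVS": 2,
    "VVVKI": 10,
}


@pytest.fixture(scope="session")
def table_corpus():
    """Corpus with the five screened motifs planted at their frequencies."""
    plan = synthetic.CorpusPlan(planted=TABLE_MOTIFS, seed=7, n_entries=20)
    files, manifest = synthetic.make_strand_corpus(plan)
    return plan, files, manifest


@pytest.fixture(scope="session")
def jittered_traj():
    """Two-chain trajectory with scripted compaction + approach + jitter."""
    plan = synthetic.TrajectoryPlan(seed=11, n_frames=50,
                                    n_beads_per_chain=30,
                                    jitter_sigma_nm=0.05)
    traj, manifest = synthetic.make_assembly_traj(plan)
    return plan, traj, manifest
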