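import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

import khbind


@pytest.fixture(scope="session")
def small_selex_pools(tmp_path_factory):
    """Small planted-motif pools shared across tests (1000+1000 reads)."""
    d = tmp_path_factory.mktemp("selex_small")
    cfg = khbind.SelexSimConfig(
        n_positive_reads=1000, n_control_reads=1000, planted_motif="TCGT",
        enrichment_fraction=0.3, seed=7,
    )
    pos, ctrl = khbind.gen_selex_pools(cfg, d)
    return cfg, pos, ctrl


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    d = tmp_path_factory.mktemp("genome")
    cfg = khbind.GenomeSimConfig(seed=5)
    paths = khbind.gen_toy_genome(cfg, d)
    truth = pd.read_csv(paths["truth"], sep="\t")
    return cfg, paths, truth
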