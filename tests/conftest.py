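import numpy as np
import pytest

from dmskit.seqcore import OrfSequence
from dmskit.simulate import (
    SimConfig,
    clone_pool_to_barcode_library,
    simulate_barseq,
    simulate_library,
    simulate_tileseq,
)


@pytest.fixture(scope="session")
def small_orf() -> OrfSequence:
    # 20 codons incl. stop; hand-checked: no internal stops
    return OrfSequence(
        "mini",
        "ATG" "AAA" "GAA" "TGG" "CTG" "TCC" "GGT" "CAT" "ATC" "CGC"
        "TTC" "GAC" "AAC" "CCG" "GTG" "TAC" "AGC" "ACC" "CAA" "TAA",
    )


@pytest.fixture(scope="session")
def barseq_sim():
    """Small simulated BarSeq screen with recoverable truth."""
    cfg = SimConfig(L=30, n_clones=300, barseq_depth=200_000, seed=3)
    rng = np.random.default_rng(cfg.seed)
    orf, pool, truth = simulate_library(cfg, mode="barseq", rng=rng)
    library = clone_pool_to_barcode_library(pool, cfg, rng)
    counts = simulate_barseq(cfg, library, pool, rng=np.random.default_rng(11))
    return cfg, orf, pool, truth, library, counts


@pytest.fixture(scope="session")
def tileseq_sim():
    """Small simulated TileSeq screen with recoverable truth."""
    cfg = SimConfig(L=30, n_clones=3000, tileseq_depth=500_000, seed=5)
    rng = np.random.default_rng(cfg.seed)
    orf, pool, truth = simulate_library(cfg, mode="tileseq", rng=rng)
    table = simulate_tileseq(cfg, pool, orf, rng=rng)
    return cfg, orf, pool, truth, table
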