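import numpy as np
import pytest

import resectseq as rs


@pytest.fixture(scope="session")
def genome():
    return rs.GenomeSpec({"chr1": 100_000, "chrX": 50_000}, frozenset({"chrX"}))


@pytest.fixture(scope="session")
def analysis_config():
    return rs.AnalysisConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)


def random_sparse_track(genome, rng, n_per_strand=40, max_count=9):
    """Random integer-count track for round-trip and normalization tests."""
    data = {}
    for chrom, length in genome.lengths.items():
        for strand in ("top", "bottom"):
            n = int(rng.integers(1, n_per_strand + 1))
            pos = np.sort(rng.choice(length, size=n, replace=False))
            val = rng.integers(1, max_count + 1, size=n).astype(float)
            data[(chrom, strand)] = (pos, val)
    total = sum(v.sum() for _, v in data.values())
    return rs.StrandedTrack(genome, data, float(total) + 10.0, units="raw")


@pytest.fixture(scope="session")
def wt_small():
    """One small wild-type simulated dataset shared across tests."""
    cfg = rs.SimConfig(n_molecules=100_000)
    preset = rs.get_preset("wt")
    return rs.simulate_dataset(cfg, preset, seed=11)
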