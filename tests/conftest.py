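import numpy as np
import pandas as pd
import pytest

from introscan.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_study():
    """Small single-chromosome study without a sweep, for fast unit tests."""
    cfg = SimConfig(n_chrom=1, n_snps_per_chrom=400, chrom_length_bp=40_000_000,
                    seed=7, sweep_regions=[])
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The default study scenario (2 x 5000 SNPs, 3 hybrids, one 10 Mb sweep)."""
    return simulate_study(SimConfig(seed=1))


def variant_frame(pos_bp, chrom="1", cm_per_mb=1.0):
    """Minimal variant table for hand-built fixtures."""
    pos_bp = np.asarray(pos_bp, dtype=np.int64)
    return pd.DataFrame({
        "chrom": str(chrom),
        "pos_bp": pos_bp,
        "id": [f"s{i}" for i in range(len(pos_bp))],
        "ref_allele": "A",
        "alt_allele": "G",
        "pos_cM": pos_bp / 1e6 * cm_per_mb,
    })
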