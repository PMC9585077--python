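import numpy as np
import pandas as pd
import pytest

import arraybench as ab


@pytest.fixture(scope="session")
def small_panel() -> ab.HaplotypePanel:
    """Two-population panel small enough for fast unit tests."""
    cfg = ab.SimConfig(
        n_samples=60, n_variants=800, populations=("P1", "P2"), seed=7
    )
    return ab.simulate_panel(cfg)


@pytest.fixture(scope="session")
def tiny_panel() -> ab.HaplotypePanel:
    """Hand-checkable 4-sample panel."""
    cfg = ab.SimConfig(n_samples=4, n_variants=20, populations=("P",), seed=3)
    return ab.simulate_panel(cfg)


def make_panel_from_haplotypes(haps, positions=None, chrom="1", populations=None):
    """Build a panel directly from a (2N, M) 0/1 array for constructed cases."""
    haps = np.asarray(haps, dtype=np.uint8)
    n2, m = haps.shape
    n = n2 // 2
    positions = np.arange(1, m + 1) * 100 if positions is None else np.asarray(positions)
    samples = [f"S{i:03d}" for i in range(n)]
    pops = np.array(populations if populations is not None else ["P"] * n, dtype=object)
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": positions.astype(int), "ref": "A", "alt": "G",
         "multiallelic": False}
    )
    return ab.HaplotypePanel(haps, samples, pops, variants)
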