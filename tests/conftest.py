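import numpy as np
import pytest

from rimap.genotypes import SdpPanel
from rimap.simulate import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def toy_panel() -> SdpPanel:
    """Four strains, one informative SDP: the hand-arithmetic fixture."""
    return SdpPanel(
        strains=["a", "b", "c", "d"],
        sdp_ids=["s0"],
        chrom=["1"],
        pos=[1_000_000],
        patterns=np.array([[0, 0, 1, 1]]),
    )


@pytest.fixture(scope="session")
def small_panel() -> SdpPanel:
    """59-strain panel over 5 chromosomes, ~100 SDPs, for mapping tests."""
    cfg = SimConfig(
        n_strains=59,
        n_reps=3,
        n_chromosomes=5,
        snps_per_chromosome=100,
        ld_persistence=0.9,
        n_mirna=1,
        n_mrna=1,
        seed=42,
    )
    return simulate_genotypes(cfg)


def make_panel(n_sdps_per_chrom: dict[str, int], n_strains: int = 8,
               seed: int = 0, spacing: int = 1_000_000) -> SdpPanel:
    """Hand-rolled panel with exact per-chromosome SDP counts."""
    rng = np.random.default_rng(seed)
    ids, chroms, pos, pats = [], [], [], []
    k = 0
    for c, count in n_sdps_per_chrom.items():
        for j in range(count):
            while True:
                p = rng.integers(0, 2, size=n_strains).astype(np.uint8)
                if 1 < p.sum() < n_strains - 1:
                    break
            ids.append(f"sdp{k:05d}")
            chroms.append(c)
            pos.append((j + 1) * spacing)
            pats.append(p)
            k += 1
    return SdpPanel(strains=[f"S{i}" for i in range(n_strains)], sdp_ids=ids,
                    chrom=np.array(chroms, dtype=object), pos=np.array(pos),
                    patterns=np.array(pats))
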