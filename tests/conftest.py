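import numpy as np
import pandas as pd
import pytest

from fadsevo.alignment import HaplotypeAlignment
from fadsevo.synthetic_data import (
    HaplogroupSimConfig,
    simulate_haplogroup_alignment,
    tag_site_position,
)

SMALL_CONFIG = HaplogroupSimConfig(
    n_derived=12,
    n_ancestral=10,
    n_archaic_near_derived=1,
    n_archaic_near_ancestral=1,
    length_total=2_000,
    length_high_quality=1_900,
    seed=11,
)


@pytest.fixture(scope="session")
def small_alignment():
    """A small but fully structured two-cluster alignment."""
    return simulate_haplogroup_alignment(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_tag_pos():
    return tag_site_position(SMALL_CONFIG)


def make_alignment(haplotypes, ancestor, clusters=None, start=1_000, high_quality=None):
    """Hand-built alignment from lists of equal-length strings."""
    mat = np.array([list(s) for s in haplotypes], dtype="<U1")
    anc = np.array(list(ancestor), dtype="<U1")
    n_hap, n_sites = mat.shape
    if high_quality is None:
        high_quality = np.ones(n_sites, dtype=bool)
    meta = pd.DataFrame(
        {
            "haplotype_id": [f"h{i}" for i in range(n_hap)],
            "sample": [f"s{i // 2}" for i in range(n_hap)],
            "hap_index": [i % 2 for i in range(n_hap)],
            "population": "POP",
            "ancestry": "modern",
            "cluster": clusters if clusters is not None else ["x"] * n_hap,
        }
    )
    return HaplotypeAlignment(
        mat, np.arange(start, start + n_sites), "chr11", anc, high_quality, meta
    )
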