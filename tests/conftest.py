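import numpy as np
import pandas as pd
import pytest

from pooledscreen import LibraryManifest, SimConfig, build_manifest, simulate_screen


@pytest.fixture(scope="session")
def default_manifest():
    """The full default library: 540 genes x 12 shRNAs, 6 control genes."""
    return build_manifest()


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale screen: 10 genes x 3 shRNAs with barcodes."""
    return SimConfig(n_genes=10, shrnas_per_gene=3, depth=20_000, barcodes=True, seed=5)


@pytest.fixture(scope="session")
def small_screen(small_cfg):
    return simulate_screen(small_cfg, seed=5)


@pytest.fixture
def toy_manifest():
    """Hand-written 2-gene manifest with fixed barcodes for matching tests."""
    return LibraryManifest(
        pd.DataFrame(
            {
                "shrna_id": ["s1", "s2"],
                "gene": ["GA", "GB"],
                "role": ["target", "target"],
                "barcode": ["AAAA", "CCCC"],
            }
        )
    )


def make_reads(seqs, prefix="T" * 22, pad_to=60):
    """Build (id, seq, qual) read triples embedding barcode windows."""
    reads = []
    for i, s in enumerate(seqs):
        seq = (prefix + s).ljust(pad_to, "G")
        reads.append((f"r{i}", seq, "I" * len(seq)))
    return reads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
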