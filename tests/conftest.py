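import pytest

import spotdomains as sd


@pytest.fixture(scope="session")
def tiny_tissue():
    """6x6 hex lattice, 2 bands, strong markers — fast shared fixture."""
    spec = sd.SyntheticSpec(rows=6, cols=6, k_domains=2, n_genes=20,
                            markers_per_domain=5, seed=11)
    ds, marker_map = sd.generate_layered_tissue(spec)
    return ds, marker_map


@pytest.fixture(scope="session")
def tiny_normalized(tiny_tissue):
    ds, marker_map = tiny_tissue
    ds = sd.select_hvg(sd.normalize_log1p(sd.drop_empty_spots(ds)), 20)
    return ds, marker_map


@pytest.fixture(scope="session")
def banded_tissue():
    """30x30 hex lattice, 4 bands, 5x-baseline markers (study conditions)."""
    spec = sd.SyntheticSpec(seed=7)
    ds, marker_map = sd.generate_layered_tissue(spec)
    return ds, marker_map
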