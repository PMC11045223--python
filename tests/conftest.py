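import numpy as np
import pandas as pd
import pytest

from eomsc.deg import DEGTable
from eomsc.imaging import MultiChannelStack


@pytest.fixture
def tiny_stack():
    """2 z-slices, 2 channels, 4x4, pixel size 0.5 µm."""
    rng = np.random.default_rng(0)
    vox = rng.integers(0, 255, size=(2, 2, 4, 4)).astype(float)
    return MultiChannelStack(voxels=vox, channel_names=["BTX", "SYP"], pixel_size=0.5)


def make_deg_table(group_a, group_b, rows):
    """rows: (gene, log2fc, p, adj) tuples."""
    return DEGTable(group_a, group_b, pd.DataFrame(rows, columns=["gene", "log2fc", "p", "adj"]))


@pytest.fixture
def deg_factory():
    return make_deg_table


def random_deg_tables(rng, n_tables=2, n_genes=20, focal="EOM"):
    """Toy DEG tables over a shared gene universe with random stats."""
    genes = [f"g{i}" for i in range(n_genes)]
    tables = []
    for t in range(n_tables):
        present = rng.random(n_genes) < 0.8
        rows = [
            (g, rng.normal(0, 1), 10.0 ** -rng.uniform(0, 6), 10.0 ** -rng.uniform(0, 6))
            for g, keep in zip(genes, present)
            if keep
        ]
        tables.append(make_deg_table(focal, f"other{t}", rows))
    return tables
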