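import numpy as np
import pytest

from lungcn.banding import BandDefinition, BandLayer

WIDE_BAND = BandDefinition("ALL", -1024, 3072)


def make_layer(pixels, shape=(40, 40), band=WIDE_BAND, spacing=0.4557):
    """Build a BandLayer directly from (row, col, hu) triples."""
    if pixels:
        rows, cols, hus = (np.array(x) for x in zip(*pixels))
    else:
        rows = cols = hus = np.array([], dtype=int)
    return BandLayer(
        band=band,
        rows=rows,
        cols=cols,
        hus=hus,
        source_shape=shape,
        pixel_spacing_mm=(spacing, spacing),
    )


def random_layer(rng, shape=(40, 40), density=0.15, hu_range=(-1024, 5)):
    """A random sparse band layer for oracle-equivalence checks."""
    mask = rng.random(shape) < density
    rows, cols = np.nonzero(mask)
    hus = rng.integers(hu_range[0], hu_range[1], size=rows.size)
    return BandLayer(
        band=BandDefinition("ALL", -1024, 3072),
        rows=rows,
        cols=cols,
        hus=hus,
        source_shape=shape,
        pixel_spacing_mm=(0.4557, 0.4557),
    )


@pytest.fixture
def layer_factory():
    return make_layer


@pytest.fixture
def random_layer_factory():
    return random_layer
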