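import numpy as np
import pytest

from condgwas.reconstruct import CrossProducts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def exact_cross_products(x, y1, y2):
    """Literal centered cross-products of an individual-level dataset."""
    xc = x - x.mean()
    y1c = y1 - y1.mean()
    y2c = y2 - y2.mean()
    return CrossProducts(
        xtx=float(xc @ xc),
        xty1=float(xc @ y1c),
        xty2=float(xc @ y2c),
        y1ty1=float(y1c @ y1c),
        y2ty2=float(y2c @ y2c),
        n=len(x),
        y1ty2=float(y1c @ y2c),
    )
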