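import numpy as np
import pytest


class StubRNG:
    """Deterministic stand-in for numpy's Generator.

    ``uniforms`` feeds every U(0,1)-derived call in order: ``random`` returns
    the raw values, ``uniform(low, high)`` maps each value affinely onto
    [low, high) (elementwise for array bounds), ``integers(n)`` floors
    ``u * n``.  ``normals`` feeds ``standard_normal`` and ``normal`` directly.
    Lets tests inject the exact random draws the update formulas consume.
    """

    def __init__(self, uniforms=(), normals=()):
        self._u = list(uniforms)
        self._n = list(normals)

    def _take_u(self, k):
        vals = self._u[:k]
        if len(vals) < k:
            raise RuntimeError("StubRNG ran out of uniform draws")
        del self._u[:k]
        return np.array(vals, dtype=float)

    def random(self, size=None):
        if size is None:
            return float(self._take_u(1)[0])
        return self._take_u(int(np.prod(size))).reshape(size)

    def uniform(self, low=0.0, high=1.0, size=None):
        low = np.asarray(low, dtype=float)
        high = np.asarray(high, dtype=float)
        shape = np.broadcast(low, high).shape if size is None else (int(size),)
        if shape == ():
            return float(low + self._take_u(1)[0] * (high - low))
        k = int(np.prod(shape))
        u = self._take_u(k).reshape(shape)
        return low + u * (high - low)

    def standard_normal(self, size=None):
        if size is None:
            v = self._n.pop(0)
            return float(v)
        vals = self._n[: int(size)]
        if len(vals) < int(size):
            raise RuntimeError("StubRNG ran out of normal draws")
        del self._n[: int(size)]
        return np.array(vals, dtype=float)

    def normal(self, loc=0.0, scale=1.0, size=None):
        return loc + scale * self.standard_normal(size)

    def integers(self, low, high=None, size=None):
        if high is None:
            low, high = 0, low
        span = high - low
        if size is None:
            return int(low + np.floor(self._take_u(1)[0] * span))
        u = self._take_u(int(size))
        return (low + np.floor(u * span)).astype(int)


@pytest.fixture
def stub_rng_cls():
    return StubRNG


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
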