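"""Buffered random-number streams.

The event loop draws millions of scalar uniforms and normals; pulling them
one at a time from ``numpy.random.Generator`` dominates the profile.  A
:class:`StreamRNG` wraps a Generator and refills fixed-size blocks, giving
cheap scalar draws while keeping the sequence fully determined by the seed.
"""

from __future__ import annotations

import numpy as np

_BLOCK = 1 << 14


class StreamRNG:
    """Deterministic scalar-draw stream backed by a numpy Generator."""

    __slots__ = ("gen", "_u", "_ui", "_n", "_ni")

    def __init__(self, seed) -> None:
        self.gen = np.random.default_rng(seed)
        self._u = self.gen.random(_BLOCK)
        self._ui = 0
        self._n = self.gen.standard_normal(_BLOCK)
        self._ni = 0

    def uniform(self) -> float:
        """One U(0,1) draw."""
        i = self._ui
        if i == _BLOCK:
            self._u = self.gen.random(_BLOCK)
            i = 0
        self._ui = i + 1
        return self._u[i]

    def normal(self, mean: float = 0.0, sd: float = 1.0) -> float:
        """One N(mean, sd) draw."""
        i = self._ni
        if i == _BLOCK:
            self._n = self.gen.standard_normal(_BLOCK)
            i = 0
        self._ni = i + 1
        return mean + sd * self._n[i]

    def integer(self, n: int) -> int:
        """Uniform integer in [0, n)."""
        return int(self.uniform() * n) % n

    def choice_index(self, n: int) -> int:
        return self.integer(n)

    def shuffle(self, seq: list) -> None:
        """In-place Fisher-Yates shuffle using the buffered stream."""
        for i in range(len(seq) - 1, 0, -1):
            j = self.integer(i + 1)
            seq[i], seq[j] = seq[j], seq[i]


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive *n* independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]
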