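"""Bloom filter over canonical edges.

Used to discard candidate triangles whose closing edge provably does not
exist before they reach the second join.  A query answers either "does not
exist" (certain) or "can exist" (with configurable false-positive
probability); false negatives cannot occur, so filtering never changes the
triangle counts, only the amount of intermediate work.

Sizing follows the textbook optimum for ``n`` elements at false-positive
rate ``p``: bit-array size ``m = ceil(-n ln p / (ln 2)^2)`` and hash count
``k = round((m/n) ln 2)``.  The ``k`` probe positions come from double
hashing of a 128-bit BLAKE2b digest of the canonical edge encoding, keyed by
a small seed, so behaviour is fully deterministic per seed.
"""

from __future__ import annotations

import hashlib
import math
import struct
from typing import Iterable

from .errors import ParameterError
from .graph_io import canonical_edge

__all__ = ["BloomFilter", "bloom_build"]


class BloomFilter:
    """Probabilistic membership filter for edges (unordered node pairs)."""

    __slots__ = ("_bits", "size_bits", "num_hashes", "target_fp", "num_inserted", "_seed")

    def __init__(self, capacity: int, fp_rate: float, *, seed: int = 0) -> None:
        if not 0.0 < fp_rate < 1.0:
            raise ParameterError(
                f"false-positive rate must lie in (0, 1), got {fp_rate}"
            )
        if capacity < 0:
            raise ParameterError("capacity must be non-negative")
        n = max(capacity, 1)
        m = math.ceil(-n * math.log(fp_rate) / math.log(2) ** 2)
        self.size_bits: int = max(m, 8)
        self.num_hashes: int = max(1, round((self.size_bits / n) * math.log(2)))
        self.target_fp: float = float(fp_rate)
        self.num_inserted: int = 0
        self._seed = int(seed)
        self._bits = bytearray((self.size_bits + 7) // 8)

    def _probes(self, edge: tuple[int, int]) -> Iterable[int]:
        u, v = canonical_edge(*edge)
        digest = hashlib.blake2b(
            struct.pack(">qq", u, v),
            digest_size=16,
            salt=self._seed.to_bytes(8, "big", signed=True),
        ).digest()
        h1 = int.from_bytes(digest[:8], "big")
        h2 = int.from_bytes(digest[8:], "big") | 1  # odd stride covers all slots
        m = self.size_bits
        for i in range(self.num_hashes):
            yield (h1 + i * h2) % m

    def add(self, edge: tuple[int, int]) -> None:
        for pos in self._probes(edge):
            self._bits[pos >> 3] |= 1 << (pos & 7)
        self.num_inserted += 1

    def __contains__(self, edge: tuple[int, int]) -> bool:
        """True means "can exist"; False means "definitely does not exist"."""
        for pos in self._probes(edge):
            if not self._bits[pos >> 3] & (1 << (pos & 7)):
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BloomFilter(bits={self.size_bits}, k={self.num_hashes}, "
            f"fp={self.target_fp}, n={self.num_inserted})"
        )


def bloom_build(
    edges: Iterable[tuple[int, int]], fp_rate: float, *, seed: int = 0
) -> BloomFilter:
    """Build a filter sized for the given edge collection and insert all edges."""
    edge_list = list(edges)
    f = BloomFilter(len(edge_list), fp_rate, seed=seed)
    for e in edge_list:
        f.add(e)
    return f
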