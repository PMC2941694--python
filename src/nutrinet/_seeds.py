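"""Deterministic seed derivation.

Every stochastic component (network initialisation, fold assignment,
permutation draws, GA operators) receives a child seed derived from a
global seed plus a context tag, so whole runs are bit-reproducible and
fitness is a pure function of (seed, configuration, data).
"""

from __future__ import annotations

import hashlib

_MOD = 2**31 - 1


def derive_seed(*parts: object) -> int:
    """Hash an arbitrary tuple of context parts into a seed below 2^31.

    Parts are rendered with ``repr`` so ints, strings and byte strings all
    contribute their value, not their identity.  SHA-256 keeps the map
    stable across processes and platforms (unlike ``hash()``).
    """
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, bytes):
            h.update(b"b:" + p)
        else:
            h.update(repr(p).encode())
        h.update(b"\x1f")
    return int.from_bytes(h.digest()[:8], "big") % _MOD
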