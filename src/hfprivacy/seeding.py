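"""Deterministic seed derivation for pipeline stages and repetitions."""

from __future__ import annotations

import zlib


def derive_seed(master: int, *labels) -> int:
    """Derive a sub-seed from a master seed and a sequence of stage labels.

    Stable across runs and platforms (CRC32-based), keeps the result in
    [0, 2**31): distinct labels give independent-looking streams from one
    master seed.
    """
    h = zlib.crc32(repr(int(master)).encode())
    for lab in labels:
        h = zlib.crc32(repr(lab).encode(), h)
    return h % (2**31)
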