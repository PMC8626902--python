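"""Small shared helpers: deterministic seed derivation and logging."""

from __future__ import annotations

import logging
import zlib

logger = logging.getLogger("exprnet")


def derive_seed(seed: int, label: str) -> int:
    """Derive a stage-specific RNG seed from a single run seed.

    Deterministic, label-dependent, and always in [0, 2**31) so it can be fed
    to any RNG constructor.
    """
    return (int(seed) ^ zlib.crc32(label.encode("utf-8"))) & 0x7FFFFFFF
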