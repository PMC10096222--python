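"""Small shared helpers."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(*parts) -> int:
    """Stable sub-seed derived from arbitrary labelled parts.

    SHA-256 of the ``|``-joined string representations, truncated to 31 bits.
    Used to give every run / component its own independent, reproducible RNG
    stream without hidden global state.
    """
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)
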