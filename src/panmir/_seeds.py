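"""Deterministic child-seed derivation for stochastic stages."""

from __future__ import annotations

import hashlib


def child_seed(master: int, *names: str) -> int:
    """A stable seed (< 2**31) derived from a master seed and stage labels."""
    key = ":".join([str(int(master)), *names]).encode()
    digest = hashlib.blake2b(key, digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)
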