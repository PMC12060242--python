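"""Stable seed derivation for reproducible, parallel-safe experiments."""

from __future__ import annotations

import zlib


def stable_seed(*parts) -> int:
    """Derive a 32-bit seed from an arbitrary tuple of hashable parts.

    Uses CRC32 over the repr of the parts, so the mapping is stable across
    processes and Python sessions (unlike builtin ``hash``).
    """
    payload = "\x1f".join(repr(p) for p in parts).encode()
    return zlib.crc32(payload) & 0xFFFFFFFF
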