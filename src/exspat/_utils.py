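"""Shared small helpers: seed derivation and file hashing."""

from __future__ import annotations

import hashlib
from pathlib import Path


def child_seed(*parts: object) -> int:
    """Derive a stable 31-bit child seed from a tuple of identifiers.

    Uses SHA-256 of the ':'-joined string representations, so child streams
    are independent of iteration order and of how many siblings exist
    (adding a FOV or a stage never perturbs the others).
    """
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
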