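"""Stable derivation of per-task RNG seeds from one master seed.

Python's builtin ``hash`` is salted per process, so sub-seeds are derived with
SHA-256 over the master seed plus string tokens (species, family, replicate, ...)
and truncated below 2**31.  The same tokens always yield the same seed, on any
platform and in any process.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *tokens: object) -> int:
    """Deterministic sub-seed in [0, 2**31) from a master seed and tokens."""
    key = "|".join(str(t) for t in (master, *tokens))
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") % (2**31)
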