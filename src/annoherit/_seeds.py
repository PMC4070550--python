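"""Stable seed fan-out.

Every stochastic stage derives its own seed from a master seed plus a tuple of
string tokens (stage name, class, trait, replicate ...) via SHA-256, so adding
a trait or class never perturbs the random stream of an existing one, and the
whole pipeline is reproducible from a single integer.
"""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Derive a deterministic 31-bit seed from a master seed and tokens."""
    key = "|".join([str(int(master_seed)), *map(str, tokens)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
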