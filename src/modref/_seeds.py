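"""Deterministic seed derivation.

Every stochastic operation draws from a generator seeded by
``derive_seed(master_seed, stage, entity)``, so reruns with the same
master seed reproduce every stage independently of execution order.
"""

from __future__ import annotations

import hashlib


def derive_seed(*parts) -> int:
    """Stable 31-bit seed from a master seed plus stage/entity labels."""
    key = "|".join(str(p) for p in parts)
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)
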