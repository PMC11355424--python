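"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(*parts) -> int:
    """Stable sub-seed from a master seed and stage/method identifiers.

    Hash-based so adding a stage or method never perturbs the seeds of the
    others. Always < 2**31.
    """
    key = ":".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)
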