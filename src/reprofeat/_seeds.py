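"""Deterministic seed derivation.

Every stochastic component draws from a seed derived from a single root seed
plus a component name and index, so adding a new component never perturbs
the draws of existing ones.
"""

from __future__ import annotations

import hashlib


def derive_seed(root: int, *parts: object) -> int:
    """Derive a child seed from ``root`` and a path of labels/indices.

    The derivation hashes the textual path, so it is stable across runs,
    platforms and Python hash randomization. The result fits in a signed
    32-bit integer as required by numpy's legacy seeding and sklearn's
    ``random_state``.
    """
    key = repr((int(root),) + tuple(parts)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
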