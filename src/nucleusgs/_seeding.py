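"""Named, replayable random streams.

All randomness in the package flows from a single root seed. Each stage
asks for a child stream by name, so any stage can be replayed in isolation
without re-running the stages before it.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "stream"]


def _name_key(name: object) -> int:
    digest = hashlib.blake2b(str(name).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def child_seed(root: int, *names: object) -> np.random.SeedSequence:
    """Deterministic child seed sequence for a named stage under ``root``."""
    return np.random.SeedSequence([int(root) & 0x7FFFFFFF, *[_name_key(n) for n in names]])


def stream(root: int, *names: object) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the named stage under ``root``."""
    return np.random.default_rng(child_seed(root, *names))
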