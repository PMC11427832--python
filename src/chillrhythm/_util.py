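"""Seeding, logging and provenance helpers."""
from __future__ import annotations

import hashlib
import json
import logging

import numpy as np

logger = logging.getLogger("chillrhythm")

#: Fixed order of child RNG streams spawned from the root seed.  Partial
#: regeneration of one table is stable as long as this order is not edited.
STREAM_ORDER = (
    "expression_params",
    "expression_noise",
    "lipid_params",
    "lipid_noise",
    "permutation",
)


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Return the child generator for a named stream of the root ``seed``.

    One root seed fans out into independent streams (one per table / stage)
    via :class:`numpy.random.SeedSequence` spawning, so regenerating e.g.
    only the lipid table does not disturb the expression table.
    """
    if stream not in STREAM_ORDER:
        raise KeyError(f"unknown RNG stream {stream!r}; known: {STREAM_ORDER}")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(STREAM_ORDER))
    return np.random.default_rng(children[STREAM_ORDER.index(stream)])


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration snapshot."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
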