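"""Shared helpers: complement tables, seeded RNG streams, canonical hashing."""

from __future__ import annotations

import hashlib
import json
import zlib
from typing import Any

import numpy as np

_DNA_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
_RNA_COMP = str.maketrans("ACGUTNacgutn", "UGCAANugcaan")


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space (U is treated as T)."""
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rng_for(seed: int, *tags: object) -> np.random.Generator:
    """Independent, reproducible RNG stream for (seed, tags).

    Tags are hashed with crc32 so that streams for different library /
    stage identities never collide or depend on call order. All derived
    entropy words stay below 2**31.
    """
    words = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        words.append(zlib.crc32(str(tag).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def canonical_json(obj: Any) -> str:
    """Deterministic JSON rendering (sorted keys, numpy scalars unwrapped)."""
    return json.dumps(_jsonable(obj), sort_keys=True, separators=(",", ":"))


def sha256_of(obj: Any) -> str:
    return hashlib.sha256(canonical_json(obj).encode()).hexdigest()
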