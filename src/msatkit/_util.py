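"""Small shared helpers: DNA string ops, rounding, named random streams."""

from __future__ import annotations

import zlib

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_RC)[::-1]


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves going up (103.5 -> 104).

    Python's built-in round() uses banker's rounding; fragment sizes and
    coverage bounds follow the conventional half-up rule instead.
    """
    return int(np.floor(x + 0.5))


def stream_rng(seed: int, *names: str) -> np.random.Generator:
    """Independent generator for a named stream under one master seed.

    Each (seed, names...) pair maps to its own SeedSequence, so adding a new
    stream to a simulator never perturbs the draws of existing streams.
    """
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *keys]))
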