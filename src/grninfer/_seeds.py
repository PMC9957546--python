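"""Deterministic seed derivation.

A single workflow seed fans out to independent per-method (and per-target)
seeds via a splitmix64-style hash keyed by string labels, so adding or
removing one method never shifts the random stream of another.
"""

from __future__ import annotations

_MASK = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    return z ^ (z >> 31)


def derive_seed(base: int, *keys: str) -> int:
    """Derive a sub-seed (< 2**31) from a base seed and string labels."""
    state = _splitmix64(int(base) & _MASK)
    for key in keys:
        for byte in str(key).encode("utf-8"):
            state = _splitmix64(state ^ byte)
    return state % (2**31)
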