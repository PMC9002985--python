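"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def round_half_away(x, ndigits: int = 0):
    """Round half away from zero (print-style rounding, unlike banker's).

    Works elementwise on arrays; returns floats.
    """
    scale = 10.0 ** ndigits
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale
    return float(out) if out.ndim == 0 else out


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a child seed below 2**31 from an existing generator."""
    return int(rng.integers(0, 2**31 - 1))


def rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
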