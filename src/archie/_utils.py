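"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def normalize_chrom(label: object) -> str:
    """Normalize a chromosome label for comparison: strip 'chr' prefix, lowercase."""
    s = str(label).strip().lower()
    if s.startswith("chr"):
        s = s[3:]
    return s


def as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) deterministically from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
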