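"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["zscore", "rng_for"]


def zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD). Zero-variance input maps to zeros."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def rng_for(seed: int, *key: int) -> np.random.Generator:
    """Deterministic random substream for a (seed, key...) pair.

    Substreams are derived with explicit spawn keys, so a subject's stream
    never depends on how many other subjects were generated before it.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))
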