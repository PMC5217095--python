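"""Shared helpers: deterministic RNG substreams and FDR adjustment."""

from __future__ import annotations

import zlib

import numpy as np
from statsmodels.stats.multitest import multipletests


def substream(seed: int, *keys) -> np.random.Generator:
    """Derive a reproducible random generator from a master seed and labels.

    Each distinct label tuple yields an independent stream, so adding a new
    randomized analysis never perturbs the draws of existing ones.
    """
    spawn = tuple(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values for a vector of p-values.

    NaN entries (undefined tests) are excluded from the adjustment and
    returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def perm_pvalue(n_exceed: int, n_perm: int) -> float:
    """Permutation p-value with the plus-one rule (never exactly zero)."""
    return (1 + n_exceed) / (1 + n_perm)
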