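"""Shared helpers: seeding, validation."""

from __future__ import annotations

import hashlib

import numpy as np

MISSING = -1  # sentinel for a missing genotype call


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from a master seed.

    Every stochastic stage of the pipeline draws its RNG from
    ``derive_seed(master, stage_name)`` so that one master seed fixes all
    downstream randomness without coupling the stages' streams.
    """
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def rng_for(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, stage))


def check_symmetric(m: np.ndarray, name: str = "matrix", tol: float = 1e-9) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=tol, equal_nan=True):
        raise ValueError(f"{name} is not symmetric")
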