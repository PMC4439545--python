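"""Small shared helpers (seed derivation, validation)."""

from __future__ import annotations

import numpy as np


def derive_seed(*keys: int) -> int:
    """Deterministically derive a child seed from a tuple of integer keys.

    Used so that every stochastic stage (simulation realization, GMM fit,
    permutation test, ...) has a reproducible seed derived from one base
    seed plus its structural position.
    """
    ss = np.random.SeedSequence([int(k) for k in keys])
    return int(ss.generate_state(1)[0])


def check_positive(value: float, name: str) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")
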