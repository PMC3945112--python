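"""Integerisation of fractional adjusted counts.

Two schemes: flooring (deterministic; a generalisation of de-duplication)
and randomized rounding, where a value t rounds up with probability equal to
its fractional part, making the rounded count unbiased for t.  Randomized
rounding generates replicate datasets; roughly thirty replicates are enough
for downstream performance to saturate, which is the default.

Randomness is counter-based: replicate r uses the Philox stream keyed by
``(seed, r)`` applied to the records in canonical (chrom, pos) order, so a
given (replicate, position) draw does not depend on traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import PerBaseCounts

__all__ = ["RoundingConfig", "floor_round", "randomized_round", "generate_replicates"]


@dataclass(frozen=True)
class RoundingConfig:
    scheme: str = "randomized"
    replicates: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("floor", "randomized"):
            raise ValueError(f"unknown rounding scheme {self.scheme!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.scheme == "floor" and self.replicates > 1:
            raise ValueError("flooring is deterministic; replicates must be 1")


def floor_round(t):
    """Floor of the adjusted value(s)."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("adjusted counts must be >= 0")
    out = np.floor(t).astype(np.int64)
    return out if out.ndim else int(out)


def randomized_round(t, rng: np.random.Generator):
    """Unbiased randomized rounding: ``floor(t) + Bernoulli(t - floor(t))``."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("adjusted counts must be >= 0")
    fl = np.floor(t)
    frac = t - fl
    up = rng.random(t.shape) < frac
    out = (fl + up).astype(np.int64)
    return out if out.ndim else int(out)


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(replicate),))
    return np.random.Generator(np.random.Philox(ss))


def generate_replicates(counts: PerBaseCounts,
                        config: RoundingConfig) -> list[PerBaseCounts]:
    """Rounded integer datasets from fractional adjusted counts.

    Floor: a single dataset.  Randomized: ``config.replicates`` independent
    datasets, reproducible from ``config.seed`` (replicate r draws from its
    own substream, so regenerating any single replicate is cheap).
    """
    if config.scheme == "floor":
        return [counts.with_values(floor_round(counts.value).astype(np.float64))]
    out = []
    for r in range(config.replicates):
        rng = _replicate_rng(config.seed, r)
        rounded = randomized_round(counts.value, rng)
        out.append(counts.with_values(rounded.astype(np.float64)))
    return out
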