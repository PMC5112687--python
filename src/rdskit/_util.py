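"""Shared numeric helpers: display rounding and seeded RNG sub-streams."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["round_half_away", "percent", "rng_from", "spawn_rngs"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (so 6.95 -> 7.0, -6.95 -> -7.0).

    Python's built-in ``round`` is banker's rounding; survey tables are
    conventionally rounded half-away-from-zero, and the published percentages
    this package reproduces only match under that convention.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent(numerator: float, denominator: float) -> float:
    """100 * a / b at full precision (rounding is applied only for display)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return 100.0 * numerator / denominator


def rng_from(seed, *key: int) -> np.random.Generator:
    """Generator for the sub-stream ``key`` of master ``seed``.

    Every stochastic stage (population wiring, recruitment, bootstrap,
    subsampling) draws from its own sub-stream so that adding replicates to
    one stage never perturbs another.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def spawn_rngs(seed, n: int, *key: int) -> list[np.random.Generator]:
    """``n`` independent generators below sub-stream ``key`` of ``seed``."""
    ss = np.random.SeedSequence(seed, spawn_key=key)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
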