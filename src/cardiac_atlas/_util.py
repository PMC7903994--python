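"""Small shared helpers: fixed rounding conventions, stage labels, seeding."""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

logger = logging.getLogger("cardiac_atlas")

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"]


def roman(i: int) -> str:
    """Stage label for 0-based index ``i`` (stages are named I, II, ...)."""
    if not 0 <= i < len(_ROMAN):
        raise ValueError(f"stage index out of range: {i}")
    return _ROMAN[i]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention used for printed percentages).

    Python's builtin ``round`` is banker's rounding; percentages in composition
    tables are fixed to half-up so e.g. 0.125 -> 0.13 at 2 decimals.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Derive an independent, reproducible stream from the top-level seed.

    Every source of randomness in the package obtains its generator through
    this function, so a pipeline run and an isolated module call with the same
    top-level seed use identical streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def natural_time_rank(labels) -> dict:
    """Map time-point labels to ordinal ranks.

    Labels carrying digits (``day0`` ... ``day10``) are ordered numerically;
    otherwise lexicographic order is used.
    """
    import re

    uniq = list(dict.fromkeys(labels))

    def _key(s):
        m = re.search(r"(\d+)", str(s))
        return (0, int(m.group(1))) if m else (1, str(s))

    ordered = sorted(uniq, key=_key)
    return {lab: i for i, lab in enumerate(ordered)}
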