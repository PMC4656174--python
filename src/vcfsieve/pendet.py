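"""Penetrance/detectance framework.

For a cohort of ``n_s`` cases and ``c`` controls, the affected samples split
into ``n_c`` (sharing the common genetic cause) and ``n_d`` (phenocopies or a
different cause, ``n_c + n_d = n_s``); the controls split into ``c_g``
(non-penetrant carriers of the "sick" genotype) and ``c_c`` (genetically
healthy, ``c_g + c_c = c``).  Then

    penetrance = n_c / (n_c + c_g)        detectance = n_c / (n_c + n_d)

A priori only ``n_s`` and ``c`` are known, so the feasible levels are
enumerated by varying ``n_d`` over 0..n_s-1 and ``c_g`` over 0..c.  A chosen
(penetrance, detectance) pair is a LOWER limit: it converts to integer
retention thresholds

    n_c = ceil(detectance * n_s)          c_g = floor(n_c / penetrance - n_c)

meaning "present in at least n_c cases and at most c_g controls", so every
variant whose achieved penetrance and detectance are at least as high as
requested is retained.  For levels chosen off the enumerated grids the
ceil/floor rounding is the unique rule preserving that guarantee; the
achieved levels are reported back on the returned thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

_SNAP = 1e-9  # absorb float noise so grid fractions round exactly


def _ceil(x: float) -> int:
    return math.ceil(x - _SNAP)


def _floor(x: float) -> int:
    return math.floor(x + _SNAP)


@dataclass(frozen=True)
class PenDetThresholds:
    """Retention thresholds: >= n_c cases and <= c_g controls.

    ``penetrance``/``detectance`` are the requested lower limits; the
    achieved levels implied by the integer thresholds are available via
    :meth:`achieved_penetrance` and :meth:`achieved_detectance`.
    """

    penetrance: float
    detectance: float
    n_c: int
    c_g: int
    n_s: int

    def achieved_penetrance(self) -> float:
        return self.n_c / (self.n_c + self.c_g)

    def achieved_detectance(self) -> float:
        return self.n_c / self.n_s


def enumerate_detectance(n_s: int) -> List[Tuple[int, float]]:
    """All feasible (n_d, detectance) pairs for ``n_s`` cases.

    ``n_d`` ranges over 0..n_s-1 (at least one case must share the cause);
    detectance = (n_s - n_d) / n_s, returned in decreasing order so the
    first entry is always full detectance.
    """
    if n_s < 1:
        raise ValueError(f"need at least one case, got n_s={n_s}")
    return [(n_d, (n_s - n_d) / n_s) for n_d in range(n_s)]


def enumerate_penetrance(n_c: int, c: int) -> List[Tuple[int, float]]:
    """All feasible (c_g, penetrance) pairs given ``n_c`` sharing cases and
    ``c`` controls; c_g ranges over 0..c, penetrance = n_c / (n_c + c_g),
    decreasing."""
    if n_c < 1:
        raise ValueError(f"need at least one sharing case, got n_c={n_c}")
    if c < 0:
        raise ValueError(f"control count must be >= 0, got c={c}")
    return [(c_g, n_c / (n_c + c_g)) for c_g in range(c + 1)]


def thresholds(
    penetrance: float, detectance: float, n_s: int, c: int
) -> PenDetThresholds:
    """Convert chosen lower-limit penetrance/detectance into integer thresholds."""
    if not 0 < penetrance <= 1:
        raise ValueError(f"penetrance must be in (0, 1], got {penetrance}")
    if not 0 < detectance <= 1:
        raise ValueError(f"detectance must be in (0, 1], got {detectance}")
    if n_s < 1:
        raise ValueError(f"need at least one case, got n_s={n_s}")
    if c < 0:
        raise ValueError(f"control count must be >= 0, got c={c}")
    n_c = _ceil(detectance * n_s)
    n_c = max(1, min(n_c, n_s))
    c_g = _floor(n_c / penetrance - n_c)
    c_g = max(0, min(c_g, c))
    return PenDetThresholds(penetrance, detectance, n_c=n_c, c_g=c_g, n_s=n_s)


def explicit_thresholds(min_cases: int, max_controls: int, n_s: int) -> PenDetThresholds:
    """Bypass the fraction machinery with explicit integer thresholds.

    ``min_cases`` may exceed ``n_s``: the filter is then unsatisfiable and
    retains nothing, which is occasionally useful as an explicit "off"
    setting and keeps threshold tightening expressible at full detectance.
    """
    if min_cases < 1:
        raise ValueError(f"min_cases must be >= 1, got {min_cases}")
    if max_controls < 0:
        raise ValueError(f"max_controls must be >= 0, got {max_controls}")
    return PenDetThresholds(
        penetrance=min_cases / (min_cases + max_controls),
        detectance=min(1.0, min_cases / n_s),
        n_c=min_cases,
        c_g=max_controls,
        n_s=n_s,
    )
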