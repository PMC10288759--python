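"""Bundled nearest-neighbor energy model.

This is deliberately a *coarse* model: helix stability comes from
stacking between adjacent base pairs, destabilisation from loop
penalties.  It is not parameterised to Turner accuracy — production
ranking should go through the external RNAfold adapter — but it is
complete, deterministic, offline, and editable, which is what the
screening pipeline and its tests need.

Model terms (kcal/mol):

* stack(p, q): energy of pair type q stacked directly inside pair type
  p; generated from per-pair strengths (GC 2.0, AU 1.0, GU 0.5) as
  ``-0.8 * (s_p + s_q)`` unless overridden.
* hairpin(s) = h0 + h1 * ln(s / min_loop) for loop size s >= min_loop.
* interior(s) = i0 + i1 * ln(s) for s unpaired in an interior/bulge
  loop, 1 <= s <= max_interior (larger interior loops are disallowed).
* multiloop = ml_close + ml_branch per branch (closing pair included) +
  ml_unpaired per unpaired loop position.

The exterior (free ends) contributes nothing, so the open chain always
scores 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import FoldingError

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Allowed pair types in a fixed order (index used by the DP kernels).
PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_INDEX = {p: k for k, p in enumerate(PAIR_TYPES)}

_STRENGTH = {"AU": 1.0, "UA": 1.0, "CG": 2.0, "GC": 2.0, "GU": 0.5, "UG": 0.5}


def _default_stack() -> dict[tuple[str, str], float]:
    return {
        (p, q): round(-0.8 * (_STRENGTH[p] + _STRENGTH[q]), 3)
        for p in PAIR_TYPES
        for q in PAIR_TYPES
    }


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the bundled nearest-neighbor model."""

    min_loop: int = 3
    max_interior: int = 30
    hairpin_a: float = 4.5
    hairpin_b: float = 1.6
    interior_a: float = 1.6
    interior_b: float = 1.3
    ml_close: float = 3.4
    ml_branch: float = 0.4
    ml_unpaired: float = 0.1
    stack: dict = field(default_factory=_default_stack)

    def __post_init__(self) -> None:
        missing = [k for k in ((p, q) for p in PAIR_TYPES for q in PAIR_TYPES)
                   if k not in self.stack]
        if missing:
            raise FoldingError(f"stack table incomplete: missing {missing[:3]}...")
        for term in (self.hairpin_a, self.hairpin_b, self.interior_a,
                     self.interior_b, self.ml_close, self.ml_branch,
                     self.ml_unpaired):
            if term < 0:
                raise FoldingError("loop penalties must be non-negative")

    def hairpin(self, size: int) -> float:
        if size < self.min_loop:
            return math.inf
        return self.hairpin_a + self.hairpin_b * math.log(size / self.min_loop)

    def interior(self, size: int) -> float:
        if size < 1 or size > self.max_interior:
            return math.inf
        return self.interior_a + self.interior_b * math.log(size)

    # -- kernel-facing packed arrays ----------------------------------

    def pair_matrix(self) -> np.ndarray:
        """4x4 int8 matrix: pair-type index for (base_i, base_j), -1 if unpairable."""
        m = -np.ones((4, 4), dtype=np.int8)
        for p, k in _PAIR_INDEX.items():
            m[BASE_INDEX[p[0]], BASE_INDEX[p[1]]] = k
        return m

    def stack_array(self) -> np.ndarray:
        arr = np.zeros((6, 6), dtype=np.float64)
        for (p, q), e in self.stack.items():
            arr[_PAIR_INDEX[p], _PAIR_INDEX[q]] = e
        return arr

    def loop_arrays(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Precomputed hairpin/interior penalties for loop sizes 0..n."""
        sizes = np.arange(n + 1)
        hp = np.full(n + 1, np.inf)
        if n >= self.min_loop:
            s = sizes[self.min_loop:]
            hp[self.min_loop:] = self.hairpin_a + self.hairpin_b * np.log(
                s / self.min_loop
            )
        it = np.full(n + 1, np.inf)
        top = min(n, self.max_interior)
        if top >= 1:
            s = sizes[1 : top + 1]
            it[1 : top + 1] = self.interior_a + self.interior_b * np.log(s)
        return hp, it

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "min_loop": self.min_loop,
            "max_interior": self.max_interior,
            "hairpin_a": self.hairpin_a,
            "hairpin_b": self.hairpin_b,
            "interior_a": self.interior_a,
            "interior_b": self.interior_b,
            "ml_close": self.ml_close,
            "ml_branch": self.ml_branch,
            "ml_unpaired": self.ml_unpaired,
            "stack": {f"{p}/{q}": e for (p, q), e in sorted(self.stack.items())},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyModel":
        stack = {tuple(k.split("/")): v for k, v in d.get("stack", {}).items()}
        kw = {k: v for k, v in d.items() if k != "stack"}
        if stack:
            kw["stack"] = stack
        return cls(**kw)


DEFAULT_MODEL = EnergyModel()


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.int8)
    except KeyError as e:
        raise FoldingError(f"invalid RNA base {e.args[0]!r}") from None


def pair_type(a: str, b: str) -> int:
    """Pair-type index of bases (a, b), or -1 if they cannot pair."""
    return _PAIR_INDEX.get(a + b, -1)


def score_structure(seq: str, pairs, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Energy of a given nested structure by direct loop decomposition.

    Serves as the independent scorer for the brute-force oracle: it walks
    the loop tree of the pair set without any dynamic programming.
    Returns ``inf`` for structures the model disallows (short hairpins,
    oversized interior loops, unpairable bases).
    """
    n = len(seq)
    pairs = sorted(pairs)
    for i, j in pairs:
        if pair_type(seq[i], seq[j]) < 0:
            return math.inf

    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)

    total = 0.0
    for parent, kids in children.items():
        if parent is None:
            continue  # exterior loop is free
        i, j = parent
        inside = (j - i - 1) - sum(b - a + 1 for a, b in kids)
        if not kids:
            total += model.hairpin(j - i - 1)
        elif len(kids) == 1:
            (p, q) = kids[0]
            if inside == 0:
                pt = pair_type(seq[i], seq[j])
                qt = pair_type(seq[p], seq[q])
                total += model.stack[(PAIR_TYPES[pt], PAIR_TYPES[qt])]
            else:
                total += model.interior(inside)
        else:
            total += (
                model.ml_close
                + model.ml_branch * (len(kids) + 1)
                + model.ml_unpaired * inside
            )
        if not math.isfinite(total):
            return math.inf
    return total
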