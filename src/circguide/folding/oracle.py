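"""Brute-force enumeration oracle for testing the DP engines.

Enumerates every nested, minimum-loop-respecting structure of a short
sequence by direct recursion (no dynamic programming tables), so it is
an independent check of both builtin engines: the maximum pair count and
the minimum of :func:`~circguide.folding.energy.score_structure` over
the enumeration must match the engines' answers.
"""

from __future__ import annotations

from ..errors import FoldingError
from .energy import DEFAULT_MODEL, EnergyModel, pair_type, score_structure

MAX_ORACLE_LEN = 16


def enumerate_structures(seq: str, min_loop: int = 3,
                         _guard: int = MAX_ORACLE_LEN) -> list[frozenset]:
    """All nested structures (as frozensets of (i, j) pairs) of ``seq``.

    Guarded to short sequences; the structure count grows exponentially.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n > _guard:
        raise FoldingError(
            f"enumeration limited to length {_guard}, got {n}"
        )

    def rec(i: int, j: int) -> list[frozenset]:
        # structures of the inclusive region [i, j]
        if j - i < min_loop + 1:
            return [frozenset()]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if pair_type(seq[i], seq[k]) < 0:
                continue
            inner = rec(i + 1, k - 1)
            outer = rec(k + 1, j) if k < j else [frozenset()]
            for a in inner:
                for b in outer:
                    out.append(a | b | {(i, k)})
        return out

    if n == 0:
        return [frozenset()]
    return rec(0, n - 1)


def max_pairs_brute(seq: str, min_loop: int = 3, circular: bool = False) -> int:
    """Maximum pair count by exhaustive recursion over all structures.

    Deliberately memo-free (no tables shared with the DP under test);
    the recursion visits every nested structure once.
    """
    seq = seq.upper().replace("T", "U")

    def rec(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if pair_type(seq[i], seq[k]) < 0:
                continue
            cand = 1 + rec(i + 1, k - 1) + (rec(k + 1, j) if k < j else 0)
            if cand > best:
                best = cand
        return best

    if not circular:
        return rec(0, len(seq) - 1) if seq else 0
    best = 0
    for c in range(len(seq)):
        rot = seq[c:] + seq[:c]
        best = max(best, max_pairs_brute(rot, min_loop))
    return best


def min_energy_brute(seq: str, model: EnergyModel = DEFAULT_MODEL,
                     circular: bool = False) -> float:
    """Minimum structure energy by exhaustive enumeration + direct scoring."""
    seq = seq.upper().replace("T", "U")
    if not circular:
        return min(
            min(score_structure(seq, s, model)
                for s in enumerate_structures(seq, model.min_loop)),
            0.0,
        )
    best = 0.0
    for c in range(len(seq)):
        rot = seq[c:] + seq[:c]
        best = min(best, min_energy_brute(rot, model))
    return best


def count_structures(seq: str, min_loop: int = 3) -> int:
    """Independent recursive count of nested structures (no enumeration)."""
    seq = seq.upper().replace("T", "U")

    def rec(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 1
        total = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if pair_type(seq[i], seq[k]) < 0:
                continue
            total += rec(i + 1, k - 1) * (rec(k + 1, j) if k < j else 1)
        return total

    return rec(0, len(seq) - 1) if seq else 1
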