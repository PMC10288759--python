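"""Secondary-structure container and dot-bracket utilities.

Structures are nested (pseudoknot-free) base-pair sets represented both
as a dot-bracket string and as a pair table (partner index per position,
-1 for unpaired).  For circular folds the optimal structure may cross
the arbitrary origin of the input; such structures are reported in a
rotated frame (``origin`` records the rotation) in which the dot-bracket
is properly nested, while the pair table always uses input coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import FoldingError


def pairs_to_pair_table(pairs, n: int) -> list[int]:
    pt = [-1] * n
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise FoldingError(f"pair ({i}, {j}) outside sequence of length {n}")
        if pt[i] != -1 or pt[j] != -1:
            raise FoldingError(f"position in pair ({i}, {j}) paired twice")
        pt[i], pt[j] = j, i
    return pt


def pair_table_to_pairs(pt) -> list[tuple[int, int]]:
    return [(i, j) for i, j in enumerate(pt) if j > i]


def pairs_to_dotbracket(pairs, n: int) -> str:
    """Render a nested pair set as dot-bracket; raises if pairs cross."""
    db = ["."] * n
    stack: list[int] = []
    opens = {i: j for i, j in pairs}
    closes = {j: i for i, j in pairs}
    for k in range(n):
        if k in opens:
            db[k] = "("
            stack.append(opens[k])
        elif k in closes:
            if not stack or stack[-1] != k:
                raise FoldingError("pair set is not nested (pseudoknot)")
            stack.pop()
            db[k] = ")"
    return "".join(db)


def dotbracket_to_pairs(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, c in enumerate(db):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise FoldingError(f"unbalanced ')' at position {k}")
            pairs.append((stack.pop(), k))
        elif c != ".":
            raise FoldingError(f"invalid dot-bracket character {c!r} at {k}")
    if stack:
        raise FoldingError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


@dataclass(frozen=True)
class SecondaryStructure:
    """A folded structure: dot-bracket, free energy and pair table.

    ``dG`` is in kcal/mol for energy-model engines; the maximum-pair
    engine reports the negated pair count in pseudo-units (flagged by its
    ``engine_id``).  ``origin`` is the rotation offset of the dot-bracket
    frame for circular folds (0 for linear folds).
    """

    sequence: str
    dotbracket: str
    dG: float
    circular: bool = False
    engine_id: str = "builtin"
    origin: int = 0
    pair_table: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if len(self.dotbracket) != n:
            raise FoldingError("dot-bracket length does not match sequence")
        local = dotbracket_to_pairs(self.dotbracket)
        if self.pair_table is None:
            # derive input-frame pair table from the (possibly rotated) frame
            pairs = [
                tuple(sorted(((i + self.origin) % n, (j + self.origin) % n)))
                for i, j in local
            ]
            object.__setattr__(
                self, "pair_table", tuple(pairs_to_pair_table(pairs, n))
            )

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs in input coordinates, (i, j) with i < j."""
        return pair_table_to_pairs(self.pair_table)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def validate(self, min_loop: int = 3) -> None:
        """Check bracket nesting and minimum hairpin loop size."""
        local = dotbracket_to_pairs(self.dotbracket)  # raises if unbalanced
        for i, j in local:
            if j - i - 1 < min_loop:
                raise FoldingError(
                    f"hairpin loop of pair ({i}, {j}) shorter than {min_loop}"
                )


def open_chain(seq: str, circular: bool = False, engine_id: str = "builtin") -> SecondaryStructure:
    return SecondaryStructure(
        sequence=seq, dotbracket="." * len(seq), dG=0.0,
        circular=circular, engine_id=engine_id,
    )
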