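"""Builtin structure-prediction engines.

Two deterministic engines are bundled:

* :class:`MfeEngine` — minimum free energy under the bundled
  nearest-neighbor model (:mod:`circguide.folding.energy`), the primary
  screening engine.
* :class:`MaxPairEngine` — Nussinov-style maximum base-pair structure,
  the builtin confirmation engine (reports -pair count as a pseudo-dG).

Both support circular folding via the doubled-sequence reduction: the
optimum over all rotations of the linear fold, with the face containing
the chosen origin treated as the (free) exterior loop.  Tie-breaking is
lexicographic on pair indices — prefer pairing the smallest i, then the
smallest partner j — so outputs are byte-identical across runs.
"""

from __future__ import annotations

import numpy as np

from ..errors import FoldingError
from . import _kernels as K
from .energy import DEFAULT_MODEL, EnergyModel, encode
from .structure import SecondaryStructure, open_chain, pairs_to_dotbracket

_EPS = 1e-7


def _check_seq(seq: str) -> str:
    if not seq:
        raise FoldingError("cannot fold an empty sequence")
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------
# maximum base pairs (Nussinov)
# ---------------------------------------------------------------------

def _nuss_traceback(enc, pmat, N, min_loop, lo, hi):
    """Lexicographically-first maximum-pair structure on [lo, hi] incl."""
    pairs: list[tuple[int, int]] = []
    stack = [(lo, hi)]
    while stack:
        i, j = stack.pop()
        while i < j and j - i > min_loop:
            target = N[i, j]
            if target == 0:
                break
            k_found = -1
            for k in range(i + min_loop + 1, j + 1):
                if pmat[enc[i], enc[k]] >= 0:
                    inner = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    rest = N[k + 1, j] if k + 1 <= j else 0
                    if 1 + inner + rest == target:
                        k_found = k
                        break
            if k_found < 0:
                i += 1  # i unpaired in every optimal structure
                continue
            pairs.append((i, k_found))
            if k_found + 1 <= j:
                stack.append((k_found + 1, j))
            i, j = i + 1, k_found - 1
    return pairs


class MaxPairEngine:
    """Nussinov maximum base-pair folding (builtin confirmation engine)."""

    def __init__(self, min_loop: int = 3):
        self.min_loop = min_loop
        self.engine_id = "builtin-maxpair"

    def fold(self, seq: str, circular: bool = False) -> SecondaryStructure:
        seq = _check_seq(seq)
        n = len(seq)
        enc = encode(seq)
        pmat = DEFAULT_MODEL.pair_matrix()
        if n <= self.min_loop + 1:
            return open_chain(seq, circular, self.engine_id)
        if not circular:
            N = K.nussinov_fill(enc, pmat, self.min_loop, n)
            pairs = _nuss_traceback(enc, pmat, N, self.min_loop, 0, n - 1)
            db = pairs_to_dotbracket(pairs, n)
            return SecondaryStructure(
                sequence=seq, dotbracket=db, dG=-float(len(pairs)),
                circular=False, engine_id=self.engine_id,
            )
        enc2 = np.concatenate([enc, enc])
        N2 = K.nussinov_fill(enc2, pmat, self.min_loop, n - 1)
        cut, best = K.best_circular_cut_pairs(N2, n)
        if best <= 0:
            return open_chain(seq, True, self.engine_id)
        pairs = _nuss_traceback(enc2, pmat, N2, self.min_loop, cut, cut + n - 1)
        local = [(i - cut, j - cut) for i, j in pairs]
        db = pairs_to_dotbracket(local, n)
        return SecondaryStructure(
            sequence=seq, dotbracket=db, dG=-float(len(pairs)),
            circular=True, engine_id=self.engine_id, origin=cut,
        )


# ---------------------------------------------------------------------
# minimum free energy (bundled nearest-neighbor model)
# ---------------------------------------------------------------------

class MfeEngine:
    """Minimum free energy folding under the bundled energy model."""

    def __init__(self, model: EnergyModel | None = None):
        self.model = model or DEFAULT_MODEL
        self.engine_id = "builtin-mfe"

    # -- DP plumbing ---------------------------------------------------

    def _fill(self, enc, max_span: int):
        m = self.model
        hp, it = m.loop_arrays(enc.shape[0])
        return K.zuker_fill(
            enc, m.pair_matrix(), m.stack_array(), hp, it,
            m.ml_close, m.ml_branch, m.ml_unpaired,
            m.min_loop, m.max_interior, max_span,
        )

    def _trace_exterior(self, enc, tabs, E, lo, hi):
        V, WM, WM2 = tabs
        pairs: list[tuple[int, int]] = []
        i = lo
        while i < hi:
            done = False
            for j in range(i + self.model.min_loop + 1, hi):
                if V[i, j] < K.INF and abs(
                    V[i, j] + E[j + 1 - lo] - E[i - lo]
                ) < _EPS:
                    self._trace_v(enc, tabs, i, j, pairs)
                    i = j + 1
                    done = True
                    break
            if not done:
                i += 1
        return pairs

    def _trace_v(self, enc, tabs, i, j, pairs):
        V, WM, WM2 = tabs
        m = self.model
        pmat = m.pair_matrix()
        stack = m.stack_array()
        tasks = [("V", i, j)]
        while tasks:
            kind, i, j = tasks.pop()
            if kind == "V":
                pairs.append((i, j))
                target = V[i, j]
                if abs(m.hairpin(j - i - 1) - target) < _EPS:
                    continue
                found = False
                pt = pmat[enc[i], enc[j]]
                for d1 in range(0, m.max_interior + 1):
                    p = i + 1 + d1
                    if p >= j:
                        break
                    for d2 in range(0, m.max_interior - d1 + 1):
                        q = j - 1 - d2
                        if q <= p:
                            break
                        qt = pmat[enc[p], enc[q]]
                        if qt < 0 or V[p, q] >= K.INF:
                            continue
                        cost = (stack[pt, qt] if d1 == 0 and d2 == 0
                                else m.interior(d1 + d2))
                        if abs(V[p, q] + cost - target) < _EPS:
                            tasks.append(("V", p, q))
                            found = True
                            break
                    if found:
                        break
                if found:
                    continue
                if j - i >= 2 and abs(
                    WM2[i + 1, j - 1] + m.ml_close + m.ml_branch - target
                ) < _EPS:
                    tasks.append(("M2", i + 1, j - 1))
                    continue
                raise FoldingError("traceback failed in V (inconsistent tables)")
            elif kind == "M":
                while i <= j:
                    if abs(V[i, j] + m.ml_branch - WM[i, j]) < _EPS:
                        tasks.append(("V", i, j))
                        break
                    if i < j and abs(WM[i + 1, j] + m.ml_unpaired - WM[i, j]) < _EPS:
                        i += 1
                        continue
                    if i < j and abs(WM[i, j - 1] + m.ml_unpaired - WM[i, j]) < _EPS:
                        j -= 1
                        continue
                    if abs(WM2[i, j] - WM[i, j]) < _EPS:
                        tasks.append(("M2", i, j))
                        break
                    if i == j:
                        break  # lone unpaired position
                    raise FoldingError("traceback failed in WM")
            else:  # M2
                found = False
                for k in range(i, j):
                    if abs(WM[i, k] + WM[k + 1, j] - WM2[i, j]) < _EPS:
                        tasks.append(("M", k + 1, j))
                        tasks.append(("M", i, k))
                        found = True
                        break
                if not found:
                    raise FoldingError("traceback failed in WM2")

    # -- public API ----------------------------------------------------

    def fold(self, seq: str, circular: bool = False) -> SecondaryStructure:
        seq = _check_seq(seq)
        n = len(seq)
        enc = encode(seq)
        if n <= self.model.min_loop + 1:
            return open_chain(seq, circular, self.engine_id)
        if not circular:
            tabs = self._fill(enc, n)
            E = K.exterior_fill(tabs[0], 0, n)
            if E[0] >= -_EPS:
                return open_chain(seq, False, self.engine_id)
            pairs = self._trace_exterior(enc, tabs, E, 0, n)
            db = pairs_to_dotbracket(pairs, n)
            return SecondaryStructure(
                sequence=seq, dotbracket=db, dG=round(float(E[0]), 6),
                circular=False, engine_id=self.engine_id,
            )
        enc2 = np.concatenate([enc, enc])
        tabs = self._fill(enc2, n - 1)
        cut, best = K.best_circular_cut(tabs[0], n)
        if best >= -_EPS:
            return open_chain(seq, True, self.engine_id)
        E = K.exterior_fill(tabs[0], cut, cut + n)
        pairs = self._trace_exterior(enc2, tabs, E, cut, cut + n)
        local = [(i - cut, j - cut) for i, j in pairs]
        db = pairs_to_dotbracket(local, n)
        return SecondaryStructure(
            sequence=seq, dotbracket=db, dG=round(float(best), 6),
            circular=True, engine_id=self.engine_id, origin=cut,
        )


# ---------------------------------------------------------------------
# functional front-ends and the engine registry
# ---------------------------------------------------------------------

def fold(seq: str, circular: bool = False,
         model: EnergyModel | None = None) -> SecondaryStructure:
    """Minimum-free-energy structure of ``seq`` under the bundled model."""
    return MfeEngine(model).fold(seq, circular=circular)


def fold_maxpair(seq: str, circular: bool = False,
                 min_loop: int = 3) -> SecondaryStructure:
    """Maximum base-pair (Nussinov) structure of ``seq``."""
    return MaxPairEngine(min_loop).fold(seq, circular=circular)


def get_engine(name: str, model: EnergyModel | None = None):
    """Engine registry: ``builtin-mfe``, ``builtin-maxpair``, ``rnafold``."""
    if name == "builtin-mfe":
        return MfeEngine(model)
    if name == "builtin-maxpair":
        return MaxPairEngine((model or DEFAULT_MODEL).min_loop)
    if name == "rnafold":
        from .external import RNAfoldEngine

        return RNAfoldEngine()
    raise FoldingError(f"unknown folding engine {name!r}")
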