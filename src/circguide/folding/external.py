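"""External engine adapter (ViennaRNA ``RNAfold``).

The study's production predictors were RNAfold and mFold; the adapter
lets the screening pipeline use an installed ``RNAfold`` binary as
primary or confirmation engine.  A missing engine raises
:class:`~circguide.errors.EngineUnavailableError` — there is never a
silent fallback to the builtin model.
"""

from __future__ import annotations

import re
import shutil
import subprocess

from ..errors import EngineOutputError, EngineUnavailableError
from .structure import SecondaryStructure

_ENERGY_RE = re.compile(r"^([.()]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def parse_engine_output(line: str, seq: str, circular: bool = False,
                        engine_id: str = "external") -> SecondaryStructure:
    """Parse one ``<dotbracket> (<energy>)`` line into a structure.

    This is the adapter's whole output contract; RNAfold, mFold-style
    wrappers and recorded outputs all reduce to it.
    """
    m = _ENERGY_RE.match(line.strip())
    if not m:
        raise EngineOutputError(f"unparseable engine output line: {line!r}")
    db, energy = m.group(1), float(m.group(2))
    if len(db) != len(seq):
        raise EngineOutputError(
            f"engine structure length {len(db)} != sequence length {len(seq)}"
        )
    return SecondaryStructure(
        sequence=seq.upper().replace("T", "U"), dotbracket=db, dG=energy,
        circular=circular, engine_id=engine_id,
    )


class RNAfoldEngine:
    """Adapter around the ``RNAfold`` command-line binary."""

    def __init__(self, binary: str = "RNAfold"):
        path = shutil.which(binary)
        if path is None:
            raise EngineUnavailableError(
                f"external engine {binary!r} not found on PATH"
            )
        self.binary = path
        try:
            out = subprocess.run(
                [path, "--version"], capture_output=True, text=True, check=True
            ).stdout.strip()
        except (OSError, subprocess.CalledProcessError) as e:
            raise EngineUnavailableError(f"cannot run {binary!r}: {e}") from e
        self.engine_id = out or "RNAfold"

    def fold(self, seq: str, circular: bool = False) -> SecondaryStructure:
        args = [self.binary, "--noPS"]
        if circular:
            args.append("--circ")
        proc = subprocess.run(
            args, input=seq + "\n", capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise EngineOutputError(
                f"RNAfold failed (exit {proc.returncode}): {proc.stderr.strip()}"
            )
        lines = [l for l in proc.stdout.splitlines() if l.strip()]
        if len(lines) < 2:
            raise EngineOutputError(f"unexpected RNAfold output: {proc.stdout!r}")
        return parse_engine_output(
            lines[-1], seq, circular=circular, engine_id=self.engine_id
        )
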