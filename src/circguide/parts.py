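"""Sequence parts and the parts registry.

A cgRNA expression cassette is assembled from named *parts*: ribozymes,
ligation sequences, guide scaffolds (the Cas12a/CasRx direct repeat),
flexible linkers, the fluorogenic F30/Broccoli module, and so on.  The
exact biological sequences (Twister P3 U2A / P1 ribozymes, Tornado
ligation stems, per-nuclease direct repeats) are supplied by the user as
a registry config; the package ships synthetic fixture parts of the
documented lengths for testing and examples.

A part may carry a reference *motif*: the dot-bracket structure over its
own footprint that must be preserved when the full cassette folds.  A
ribozyme part may also carry a ``cleavage_offset`` (0-based position
within the part at which self-cleavage occurs) used when deriving the
ligated circle from a circular precursor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import AlphabetError, PartError

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

#: Roles a part can play inside a cassette.
ROLES = frozenset(
    {
        "promoter",
        "ribozyme_5p",
        "ribozyme_3p",
        "ligation_5p",
        "ligation_3p",
        "spacer_region_5p",
        "spacer_region_3p",
        "f30_junction",
        "broccoli",
        "scaffold",
        "spacer",
        "linker_5p",
        "linker_3p",
        "extension_5p",
        "extension_3p",
    }
)

#: Roles whose canonical length is fixed by the cassette design.
EXPECTED_LENGTHS = {
    "spacer_region_5p": 42,
    "spacer_region_3p": 41,
}


def check_alphabet(seq: str, alphabet: frozenset[str] = DNA_ALPHABET) -> str:
    seq = seq.upper()
    bad = set(seq) - alphabet
    if bad:
        raise AlphabetError(
            f"sequence contains characters outside {''.join(sorted(alphabet))}: "
            f"{''.join(sorted(bad))}"
        )
    return seq


@dataclass(frozen=True)
class Part:
    """A named cassette component.

    Parameters
    ----------
    name : str
        Unique identifier inside a registry.
    role : str
        One of :data:`ROLES`.
    sequence : str
        DNA sequence (cassette space); may be empty only for extensions.
    motif : str or None
        Reference dot-bracket over this part's footprint, if the part has
        a structure that must be preserved in the folded cassette.
    cleavage_offset : int or None
        For ribozymes: 0-based offset within the part where autocatalytic
        cleavage occurs.  Defaults (resolved at use time) to the boundary
        facing the ligation sequence.
    """

    name: str
    role: str
    sequence: str
    motif: str | None = None
    cleavage_offset: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PartError(f"unknown part role {self.role!r} for part {self.name!r}")
        seq = check_alphabet(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not seq and not self.role.startswith("extension"):
            raise PartError(f"part {self.name!r} ({self.role}) has an empty sequence")
        if self.motif is not None and len(self.motif) != len(seq):
            raise PartError(
                f"part {self.name!r}: motif length {len(self.motif)} does not match "
                f"sequence length {len(seq)}"
            )
        if self.cleavage_offset is not None and not (
            0 <= self.cleavage_offset <= len(seq)
        ):
            raise PartError(
                f"part {self.name!r}: cleavage offset {self.cleavage_offset} outside "
                f"[0, {len(seq)}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class PartRegistry:
    """Mapping of part name -> :class:`Part` with role-based lookup."""

    def __init__(self, parts: Iterable[Part] = ()):  # noqa: D107
        self._parts: dict[str, Part] = {}
        for p in parts:
            self.add(p)

    def add(self, part: Part) -> None:
        if part.name in self._parts:
            raise PartError(f"duplicate part name {part.name!r}")
        self._parts[part.name] = part

    def __getitem__(self, name: str) -> Part:
        try:
            return self._parts[name]
        except KeyError:
            raise PartError(f"no part named {name!r} in registry") from None

    def __contains__(self, name: str) -> bool:
        return name in self._parts

    def __iter__(self):
        return iter(self._parts.values())

    def __len__(self) -> int:
        return len(self._parts)

    def by_role(self, role: str, name: str | None = None) -> Part:
        """Resolve the part for a role, optionally preferring ``name``.

        Raises :class:`PartError` if no part has the role, or if several do
        and no name disambiguates.
        """
        if name is not None and name in self:
            part = self[name]
            if part.role != role:
                raise PartError(
                    f"part {name!r} has role {part.role!r}, expected {role!r}"
                )
            return part
        hits = [p for p in self._parts.values() if p.role == role]
        if not hits:
            raise PartError(f"registry has no part with role {role!r}")
        if len(hits) > 1:
            names = ", ".join(sorted(p.name for p in hits))
            raise PartError(
                f"registry has multiple parts with role {role!r} ({names}); "
                "specify one by name"
            )
        return hits[0]

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        out: dict[str, dict] = {}
        for p in sorted(self._parts.values(), key=lambda p: p.name):
            entry: dict = {"role": p.role, "sequence": p.sequence}
            if p.motif is not None:
                entry["motif"] = p.motif
            if p.cleavage_offset is not None:
                entry["cleavage_offset"] = p.cleavage_offset
            out[p.name] = entry
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping]) -> "PartRegistry":
        reg = cls()
        for name, entry in data.items():
            reg.add(
                Part(
                    name=name,
                    role=entry["role"],
                    sequence=entry.get("sequence", ""),
                    motif=entry.get("motif"),
                    cleavage_offset=entry.get("cleavage_offset"),
                )
            )
        return reg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def load(cls, path: str | Path) -> "PartRegistry":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise PartError(f"parts file {path} is not a mapping of part entries")
        return cls.from_dict(data)
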