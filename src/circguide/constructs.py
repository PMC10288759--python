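"""Cassette assembly: guide RNA expression constructs and their grammars.

The cassette topologies modelled here follow the Tornado-style circular
guide RNA design: a Pol III (U6+27) transcript carrying the guide flanked
by Twister ribozymes whose autocatalytic cleavage leaves termini that the
endogenous ligase RtcB joins into a circle.  Linear controls (mature
U6+27 guides, unprocessed "Pre" guides with the spacer between two
scaffold copies, and 5'/3'-extended guides) use the same part registry.

Coordinates are 0-based half-open throughout; circular RNAs are
canonicalised to start at the 5' ligation junction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import GrammarError
from .parts import PartRegistry, check_alphabet

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    """Transcribe a DNA string to RNA (T -> U)."""
    return check_alphabet(seq).replace("T", "U")


@dataclass(frozen=True)
class Feature:
    """A (part, role, start, end) annotation on a construct sequence."""

    part: str
    role: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpacerSet:
    """Ordered list of (target name, spacer sequence) for one cassette.

    Spacer length bounds default to 20-23 nt and are configurable per Cas
    system at construction time.
    """

    spacers: tuple[tuple[str, str], ...]
    cas_system: str = "LbCas12a"
    min_len: int = 20
    max_len: int = 23

    def __post_init__(self) -> None:
        if not self.spacers:
            raise GrammarError("a SpacerSet needs at least one spacer")
        checked = []
        for name, seq in self.spacers:
            seq = check_alphabet(seq)
            if not (self.min_len <= len(seq) <= self.max_len):
                raise GrammarError(
                    f"spacer {name!r} has length {len(seq)}, outside "
                    f"[{self.min_len}, {self.max_len}]"
                )
            checked.append((name, seq))
        object.__setattr__(self, "spacers", tuple(checked))

    def __len__(self) -> int:
        return len(self.spacers)

    @classmethod
    def single(cls, name: str, seq: str, **kw) -> "SpacerSet":
        return cls(spacers=((name, seq),), **kw)


@dataclass(frozen=True)
class LinkerPair:
    """5' and 3' linkers: a fixed core plus a variable random extension.

    The screened libraries use a 10-nt polyAC core with 5-7 random extra
    bases on each side, i.e. total linker lengths of 15-17 nt.  Each
    linker is stored core-first: the extension sits at the linker's 3'
    end (adjacent to the guide scaffold on the 5' side and to the
    ligation sequence on the 3' side).
    """

    ext5: str
    ext3: str
    core: str = "ACACACACAC"
    min_ext: int = 5
    max_ext: int = 7

    def __post_init__(self) -> None:
        object.__setattr__(self, "core", check_alphabet(self.core))
        object.__setattr__(self, "ext5", check_alphabet(self.ext5))
        object.__setattr__(self, "ext3", check_alphabet(self.ext3))
        for label, ext in (("5'", self.ext5), ("3'", self.ext3)):
            if not (self.min_ext <= len(ext) <= self.max_ext):
                raise GrammarError(
                    f"{label} linker extension length {len(ext)} outside "
                    f"[{self.min_ext}, {self.max_ext}]"
                )

    @property
    def linker5(self) -> str:
        return self.core + self.ext5

    @property
    def linker3(self) -> str:
        return self.core + self.ext3

    @property
    def core_length(self) -> int:
        return len(self.core)


@dataclass(frozen=True)
class Construct:
    """An assembled cassette: sequence plus tiled feature annotations.

    ``leader`` holds the 27-nt U6+27 transcript leader for variants that
    carry it; the leader is not a cassette feature — it is prepended at
    transcription and (for circular variants) removed with the 5'
    ribozyme fragment during circularisation.
    """

    name: str
    topology: str  # linear_gRNA | pre_gRNA | circular_precursor | circular_rna
    sequence: str
    features: tuple[Feature, ...]
    cas_system: str = "LbCas12a"
    leader: str | None = None
    is_rna: bool = False

    def __post_init__(self) -> None:
        if self.topology not in {
            "linear_gRNA",
            "pre_gRNA",
            "circular_precursor",
            "circular_rna",
        }:
            raise GrammarError(f"unknown topology {self.topology!r}")
        pos = 0
        for f in self.features:
            if f.start != pos:
                raise GrammarError(
                    f"features of {self.name!r} do not tile: expected start {pos}, "
                    f"got {f.start} for {f.part!r}"
                )
            pos = f.end
        if pos != len(self.sequence):
            raise GrammarError(
                f"features of {self.name!r} cover [0, {pos}) but sequence has "
                f"length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_seq(self, feature: Feature) -> str:
        return self.sequence[feature.start : feature.end]

    def features_named(self, part: str) -> list[Feature]:
        return [f for f in self.features if f.part == part]

    def features_with_role(self, role: str) -> list[Feature]:
        return [f for f in self.features if f.role == role]


_CORE_SP1 = [
    "ligation_5p",
    "spacer_region_5p",
    "scaffold",
    "spacer",
    "scaffold",
    "spacer_region_3p",
    "ligation_3p",
]
_CORE_SP1_F30 = [
    "ligation_5p",
    "spacer_region_5p",
    "f30_junction",
    "broccoli",
    "scaffold",
    "spacer",
    "scaffold",
    "spacer_region_3p",
    "ligation_3p",
]
_CORE_LINKER = [
    "ligation_5p",
    "linker_5p",
    "scaffold",
    "spacer",
    "scaffold",
    "linker_3p",
    "ligation_3p",
]

#: Variant grammars as role sequences.  ``@array`` expands to the
#: multiplex unit: (scaffold, spacer) per spacer plus a trailing scaffold.
VARIANTS: dict[str, dict] = {
    "U6+27": {"roles": ["promoter", "scaffold", "spacer"], "leader": True,
              "topology": "linear_gRNA"},
    "U6": {"roles": ["promoter", "scaffold", "spacer"], "leader": False,
           "topology": "linear_gRNA"},
    "Pre": {"roles": ["promoter", "scaffold", "spacer", "scaffold"], "leader": True,
            "topology": "pre_gRNA"},
    "L-Sp1-F30": {"roles": ["promoter"] + _CORE_SP1_F30, "leader": True,
                  "topology": "linear_gRNA"},
    "L-Sp1": {"roles": ["promoter"] + _CORE_SP1, "leader": True,
              "topology": "linear_gRNA"},
    "C-Sp1-F30": {"roles": ["promoter", "ribozyme_5p"] + _CORE_SP1_F30
                  + ["ribozyme_3p"], "leader": True, "topology": "circular_precursor"},
    "C-Sp1": {"roles": ["promoter", "ribozyme_5p"] + _CORE_SP1 + ["ribozyme_3p"],
              "leader": True, "topology": "circular_precursor"},
    "C-linker": {"roles": ["promoter", "ribozyme_5p"] + _CORE_LINKER
                 + ["ribozyme_3p"], "leader": True, "topology": "circular_precursor",
                 "needs_linkers": True},
    "C-linker-d27": {"roles": ["promoter", "ribozyme_5p"] + _CORE_LINKER
                     + ["ribozyme_3p"], "leader": False,
                     "topology": "circular_precursor", "needs_linkers": True},
    "gRNA+9": {"roles": ["promoter", "extension_5p", "scaffold", "spacer"],
               "leader": False, "topology": "linear_gRNA",
               "part_names": {"extension_5p": "ext9"}},
    "gRNA+59": {"roles": ["promoter", "extension_5p", "scaffold", "spacer"],
                "leader": False, "topology": "linear_gRNA",
                "part_names": {"extension_5p": "ext59"}},
    "gRNA+T4AT4": {"roles": ["promoter", "scaffold", "spacer", "extension_3p"],
                   "leader": False, "topology": "linear_gRNA",
                   "part_names": {"extension_3p": "ext_t4at4"}},
    "multiplex-linear": {"roles": ["promoter", "@array"], "leader": True,
                         "topology": "pre_gRNA", "multiplex": True},
    "multiplex-circular": {"roles": ["promoter", "ribozyme_5p", "ligation_5p",
                                     "linker_5p", "@array", "linker_3p",
                                     "ligation_3p", "ribozyme_3p"],
                           "leader": True, "topology": "circular_precursor",
                           "multiplex": True, "needs_linkers": True},
}

# "C-L1" ... "C-L8" and "C-L7-d27" style names resolve to the generic
# linker grammar; the number only labels the screened linker pair.
_ALIAS_RE = re.compile(r"^C-L\d+(-d27)?$")


def normalize_variant(variant: str) -> str:
    if variant in VARIANTS:
        return variant
    m = _ALIAS_RE.match(variant)
    if m:
        return "C-linker-d27" if m.group(1) else "C-linker"
    raise GrammarError(f"unknown cassette variant {variant!r}")


def assemble_construct(
    spacers: SpacerSet,
    variant: str,
    parts: PartRegistry,
    linkers: LinkerPair | None = None,
    name: str | None = None,
) -> Construct:
    """Assemble a cassette of the requested variant.

    Parameters
    ----------
    spacers : SpacerSet
        One spacer for single-guide variants; two or more for multiplex
        arrays (which repeat the scaffold/spacer unit).
    variant : str
        Variant identifier (e.g. ``"Pre"``, ``"C-Sp1"``, ``"C-L7"``,
        ``"multiplex-circular"``).
    parts : PartRegistry
        Registry providing every part the variant grammar requires.
    linkers : LinkerPair, optional
        Required by linker-bearing circular variants.

    Returns
    -------
    Construct
        Feature-tiled cassette (DNA, cassette space).
    """
    key = normalize_variant(variant)
    spec = VARIANTS[key]
    if spec.get("multiplex"):
        if len(spacers) < 2:
            raise GrammarError(
                f"variant {variant!r} is a multiplex array and needs >= 2 spacers"
            )
    elif len(spacers) != 1:
        raise GrammarError(
            f"variant {variant!r} takes exactly one spacer, got {len(spacers)}"
        )
    if spec.get("needs_linkers") and linkers is None:
        raise GrammarError(f"variant {variant!r} requires a LinkerPair")

    part_names = spec.get("part_names", {})
    roles: list[str] = []
    for role in spec["roles"]:
        if role == "@array":
            for _ in spacers.spacers:
                roles.extend(["scaffold", "spacer"])
            roles.append("scaffold")
        else:
            roles.append(role)

    features: list[Feature] = []
    chunks: list[str] = []
    pos = 0
    spacer_iter = iter(spacers.spacers)

    def emit(label: str, role: str, seq: str) -> None:
        nonlocal pos
        features.append(Feature(label, role, pos, pos + len(seq)))
        chunks.append(seq)
        pos += len(seq)

    for role in roles:
        if role == "spacer":
            sp_name, sp_seq = next(spacer_iter)
            emit(f"spacer:{sp_name}", "spacer", sp_seq)
        elif role == "linker_5p":
            emit("linker_5p", role, linkers.linker5)
        elif role == "linker_3p":
            emit("linker_3p", role, linkers.linker3)
        else:
            part = parts.by_role(role, name=part_names.get(role))
            emit(part.name, role, part.sequence)

    leader = None
    if spec["leader"]:
        leader = parts.by_role("extension_5p", name="leader27").sequence
    return Construct(
        name=name or f"{variant}:{spacers.spacers[0][0]}",
        topology=spec["topology"],
        sequence="".join(chunks),
        features=tuple(features),
        cas_system=spacers.cas_system,
        leader=leader,
    )


def assemble_array(
    spacers: SpacerSet,
    variant: str,
    parts: PartRegistry,
    linkers: LinkerPair | None = None,
    name: str | None = None,
) -> Construct:
    """Assemble a multiplexed (>= 2 spacers) linear or circular array."""
    key = normalize_variant(variant)
    if not VARIANTS[key].get("multiplex"):
        raise GrammarError(f"variant {variant!r} is not a multiplex array grammar")
    return assemble_construct(spacers, variant, parts, linkers=linkers, name=name)


def predict_circle(
    precursor: Construct, parts: PartRegistry | None = None
) -> Construct:
    """Derive the ligated circle from a circular precursor cassette.

    The two Twister ribozymes cleave at their configured offsets and RtcB
    joins the resulting termini.  Offsets default to the boundary facing
    the ligation sequence (the whole ribozyme is removed).  The returned
    construct is canonicalised to start at the 5' ligation junction;
    retained ribozyme residues (non-default offsets) wrap to the 3' end.
    """
    if precursor.topology != "circular_precursor":
        raise GrammarError(
            f"predict_circle needs a circular_precursor, got {precursor.topology!r}"
        )
    rz5 = next(iter(precursor.features_with_role("ribozyme_5p")), None)
    rz3 = next(iter(precursor.features_with_role("ribozyme_3p")), None)
    if rz5 is None or rz3 is None:
        raise GrammarError("precursor lacks ribozyme features")

    off5 = off3 = None
    if parts is not None:
        if rz5.part in parts:
            off5 = parts[rz5.part].cleavage_offset
        if rz3.part in parts:
            off3 = parts[rz3.part].cleavage_offset
    if off5 is None:
        off5 = len(rz5)  # cleave at the ribozyme/ligation boundary
    if off3 is None:
        off3 = 0
    a = rz5.start + off5
    b = rz3.start + off3
    if not a < b:
        raise GrammarError("cleavage offsets leave an empty circle")

    # Canonical start: the 5' ligation junction (first feature boundary
    # at or after the 5' cleavage point).
    junction = next((f.start for f in precursor.features if f.start >= a), a)
    circ_seq = precursor.sequence[junction:b] + precursor.sequence[a:junction]

    feats: list[Feature] = []
    pos = 0

    def clip_emit(f: Feature, lo: int, hi: int) -> None:
        nonlocal pos
        s, e = max(f.start, lo), min(f.end, hi)
        if s < e:
            feats.append(Feature(f.part, f.role, pos, pos + (e - s)))
            pos += e - s

    for f in precursor.features:
        clip_emit(f, junction, b)
    for f in precursor.features:
        clip_emit(f, a, junction)

    return Construct(
        name=precursor.name + ":circle",
        topology="circular_rna",
        sequence=circ_seq,
        features=tuple(feats),
        cas_system=precursor.cas_system,
        leader=None,
    )


def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation — equivalence key for circles."""
    doubled = seq + seq
    return min(doubled[i : i + len(seq)] for i in range(len(seq)))


def transcript_construct(construct: Construct) -> Construct:
    """The RNA transcript of a cassette, with shifted feature coordinates.

    The promoter is dropped; leader-bearing variants gain a ``leader27``
    feature at the 5' end.  Part names are preserved so structure motifs
    stay anchored on the transcript.
    """
    if construct.is_rna:
        return construct
    feats = [f for f in construct.features if f.role != "promoter"]
    promoter_len = sum(len(f) for f in construct.features if f.role == "promoter")
    leader = construct.leader or ""
    shift = len(leader) - promoter_len
    out_feats = [Feature(f.part, f.role, f.start + shift, f.end + shift)
                 for f in feats]
    if leader:
        out_feats = [Feature("leader27", "extension_5p", 0, len(leader))] + out_feats
    body = construct.sequence[promoter_len:]
    return Construct(
        name=construct.name + ":rna",
        topology=construct.topology,
        sequence=dna_to_rna(leader + body),
        features=tuple(out_feats),
        cas_system=construct.cas_system,
        leader=None,
        is_rna=True,
    )


def transcribe(x: Construct | str) -> str:
    """Transcribe a construct (promoter excluded, leader prepended for
    U6+27 variants) or a plain DNA string to RNA."""
    if isinstance(x, str):
        return dna_to_rna(x)
    return transcript_construct(x).sequence
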